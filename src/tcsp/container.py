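"""The ``numeric_container`` save format: arrays + metadata in one HDF5 file.

Every object the package persists between CLI invocations (recordings,
epoch sets, fitted models, calibration results) goes through this module.
Datasets are written with ``track_times=False`` so that two writes of the
same content produce byte-identical files — a property the pipeline's
leakage guard relies on.
"""

from __future__ import annotations

import numpy as np
import h5py

__all__ = ["save_container", "load_container", "container_bytes"]

_ATTR_PREFIX = "meta_"


def _write_group(grp: h5py.Group, payload: dict) -> None:
    for key, value in sorted(payload.items()):
        if isinstance(value, dict):
            sub = grp.create_group(key)
            _write_group(sub, value)
        elif isinstance(value, np.ndarray):
            grp.create_dataset(key, data=value, track_times=False)
        elif isinstance(value, (list, tuple)) and value and isinstance(value[0], str):
            grp.create_dataset(
                key, data=np.asarray(value, dtype=h5py.string_dtype()),
                track_times=False,
            )
        elif value is None:
            grp.attrs[_ATTR_PREFIX + key] = "__none__"
        elif isinstance(value, (str, bytes, int, float, np.integer, np.floating, bool)):
            grp.attrs[_ATTR_PREFIX + key] = value
        else:
            arr = np.asarray(value)
            grp.create_dataset(key, data=arr, track_times=False)


def _read_group(grp: h5py.Group) -> dict:
    out: dict = {}
    for key, value in grp.items():
        if isinstance(value, h5py.Group):
            out[key] = _read_group(value)
        else:
            data = value[()]
            if data.dtype.kind == "O" or h5py.check_string_dtype(value.dtype):
                data = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in np.atleast_1d(data)
                ]
            out[key] = data
    for key, value in grp.attrs.items():
        if key.startswith(_ATTR_PREFIX):
            if isinstance(value, str) and value == "__none__":
                value = None
            if isinstance(value, bytes):
                value = value.decode()
            if isinstance(value, np.generic):
                value = value.item()
            out[key[len(_ATTR_PREFIX):]] = value
    return out


def save_container(path, payload: dict, kind: str = "generic") -> None:
    """Write a nested dict of arrays / scalars / strings to ``path``.

    ``kind`` tags the payload (``recording``, ``epochs``, ``csp_model`` ...)
    so loaders can sanity-check what they are given.
    """
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["container_kind"] = kind
        f.attrs["container_version"] = 1
        _write_group(f, payload)


def load_container(path, expect_kind: str | None = None) -> dict:
    """Read a container written by :func:`save_container`."""
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("container_kind", "generic")
        if isinstance(kind, bytes):
            kind = kind.decode()
        if expect_kind is not None and kind != expect_kind:
            raise ValueError(
                f"container at {path} holds {kind!r}, expected {expect_kind!r}"
            )
        payload = _read_group(f)
    payload["__kind__"] = kind
    return payload


def container_bytes(payload: dict, kind: str = "generic") -> bytes:
    """Serialize a payload to the in-memory byte image of its container file.

    Used to compare fitted models bit-wise without touching disk.
    """
    import io

    buf = io.BytesIO()
    with h5py.File(buf, "w", track_order=False) as f:
        f.attrs["container_kind"] = kind
        f.attrs["container_version"] = 1
        _write_group(f, payload)
    return buf.getvalue()
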