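"""Reading, preprocessing and epoching of multichannel EEG recordings.

Supported on-disk formats:

* ``edf`` — European Data Format, read through :mod:`mne`; cue markers are
  taken from EDF+ annotations (or, failing that, from a ``TRIG`` channel).
* ``competition_matrix`` — the matrix-container layout used by the BCI
  Competition III Dataset IVa distribution (``cnt``/``mrk``/``nfo`` keys in
  a MATLAB file, or the same keys in an ``.npz``).
* ``numeric_container`` — the package's own HDF5 layout
  (see :mod:`tcsp.container`).

The preprocessing chain is the standard motor-imagery front end: zero-phase
FIR band-pass, integer down-sampling, common average reference (CAR), then
cue-locked epoch extraction and class-stratified train/calibration/test
splitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from tcsp import container

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording", "EpochSet", "SplitScheme",
    "read_recording", "preprocess", "extract_epochs", "make_splits",
    "save_recording", "save_epochs", "load_epochs", "write_edf",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """A continuous multichannel recording with cue markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    rate : float
        Sampling rate in samples/s.
    channel_labels : list of str
        Electrode names, one per signal row.
    events : list of (int, int)
        ``(sample_index, class_label)`` cue markers; labels are 1 or 2.
    """

    signal: np.ndarray
    rate: float
    channel_labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one channel label per signal row required")
        n = self.signal.shape[1]
        self.events = [(int(s), int(c)) for s, c in self.events]
        for s, c in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event sample {s} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EpochSet:
    """Cue-locked trials: ``data[i]`` is the channels x samples matrix E^i."""

    data: np.ndarray            # (n_trials, n_channels, n_samples)
    labels: np.ndarray          # (n_trials,) values in {1, 2}
    rate: float
    window_start: float         # seconds relative to cue

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValueError(f"labels must be in {{1, 2}}, got extra {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return EpochSet(self.data[idx], self.labels[idx], self.rate, self.window_start)


@dataclass
class SplitScheme:
    """One fold of the nested train/calibration/test cross-validation."""

    fold_id: int
    train_idx: np.ndarray
    calib_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.calib_idx = np.asarray(self.calib_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        parts = [set(self.train_idx), set(self.calib_idx), set(self.test_idx)]
        if (parts[0] & parts[1]) or (parts[0] & parts[2]) or (parts[1] & parts[2]):
            raise ValueError("train/calib/test partitions must be disjoint")
        if any(len(p) == 0 for p in parts):
            raise ValueError("every partition must be non-empty")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_FORMAT_SUFFIXES = {
    ".edf": "edf",
    ".mat": "competition_matrix",
    ".npz": "competition_matrix",
    ".h5": "numeric_container",
    ".hdf5": "numeric_container",
}


def read_recording(path, fmt: str | None = None) -> RawRecording:
    """Load a recording from disk.

    ``fmt`` is one of ``edf``, ``competition_matrix``, ``numeric_container``;
    if omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        try:
            fmt = _FORMAT_SUFFIXES[path.suffix.lower()]
        except KeyError:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "competition_matrix":
        return _read_competition_matrix(path)
    if fmt == "numeric_container":
        return load_recording(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edf(path) -> RawRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne returns volts
    rate = float(raw.info["sfreq"])

    events: list[tuple[int, int]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        digits = "".join(ch for ch in str(desc) if ch.isdigit())
        if digits:
            events.append((int(round(onset * rate)), int(digits)))
    if "TRIG" in labels:
        trig_row = labels.index("TRIG")
        trig = data[trig_row]
        if not events:
            marks = np.flatnonzero(np.round(trig) > 0)
            events = [(int(s), int(round(trig[s]))) for s in marks]
        data = np.delete(data, trig_row, axis=0)
        labels = [l for l in labels if l != "TRIG"]
    if not events:
        raise ValueError(f"{path}: no annotations or TRIG channel with cue markers")
    events.sort()
    return RawRecording(data, rate, labels, events)


def _read_competition_matrix(path) -> RawRecording:
    path = Path(path)
    if path.suffix.lower() == ".npz":
        blob = dict(np.load(path, allow_pickle=True))
        cnt = np.asarray(blob["cnt"], dtype=float)
        rate = float(np.asarray(blob["rate"]).ravel()[0])
        pos = np.asarray(blob["pos"], dtype=int).ravel()
        y = np.asarray(blob["y"], dtype=float).ravel()
        clab = [str(c) for c in np.asarray(blob["clab"]).ravel()]
    else:
        from scipy.io import loadmat

        blob = loadmat(path, squeeze_me=True, struct_as_record=False)
        cnt = np.asarray(blob["cnt"], dtype=float)
        mrk = blob["mrk"]
        nfo = blob["nfo"]
        rate = float(np.atleast_1d(getattr(nfo, "fs", getattr(mrk, "fs", 0))).ravel()[0])
        pos = np.asarray(mrk.pos, dtype=int).ravel()
        y = np.asarray(mrk.y, dtype=float).ravel()
        clab = [str(c) for c in np.atleast_1d(nfo.clab)]
    # Dataset IVa stores cnt as samples x channels in 0.1 uV units when int16;
    # float fixtures are taken as uV as-is.
    signal = cnt.T.astype(float)
    labels = y.copy()
    # competition labels: 1/2, with NaN for unlabeled test trials (dropped)
    events = [
        (int(p), int(l)) for p, l in zip(pos, labels) if np.isfinite(l) and l in (1, 2)
    ]
    events.sort()
    if not events:
        raise ValueError(f"{path}: marker table holds no labeled events")
    return RawRecording(signal, rate, clab, events)


# ---------------------------------------------------------------------------
# numeric_container round trip
# ---------------------------------------------------------------------------

def save_recording(path, rec: RawRecording, ground_truth: dict | None = None) -> None:
    payload = {
        "signal": rec.signal,
        "rate": float(rec.rate),
        "channel_labels": list(rec.channel_labels),
        "event_samples": np.asarray([e[0] for e in rec.events], dtype=np.int64),
        "event_labels": np.asarray([e[1] for e in rec.events], dtype=np.int64),
    }
    if ground_truth is not None:
        payload["ground_truth"] = ground_truth
    container.save_container(path, payload, kind="recording")


def load_recording(path) -> RawRecording:
    payload = container.load_container(path, expect_kind="recording")
    events = list(zip(payload["event_samples"].tolist(),
                      payload["event_labels"].tolist()))
    return RawRecording(
        payload["signal"], float(payload["rate"]),
        list(payload["channel_labels"]), events,
    )


def save_epochs(path, epochs: EpochSet, channel_labels: list[str] | None = None) -> None:
    payload = {
        "data": epochs.data,
        "labels": epochs.labels.astype(np.int64),
        "rate": float(epochs.rate),
        "window_start": float(epochs.window_start),
    }
    if channel_labels is not None:
        payload["channel_labels"] = list(channel_labels)
    container.save_container(path, payload, kind="epochs")


def load_epochs(path) -> EpochSet:
    payload = container.load_container(path, expect_kind="epochs")
    return EpochSet(payload["data"], payload["labels"],
                    float(payload["rate"]), float(payload["window_start"]))


# ---------------------------------------------------------------------------
# EDF export (16-bit EDF+C with an annotations signal for cue markers)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: RawRecording) -> None:
    """Write a recording as EDF+C; events become EDF+ annotations.

    One data record per second; signals are scaled to the full 16-bit
    digital range per channel, so the round trip is exact only up to
    that quantization.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(rate))  # samples per record per signal
    n_rec = int(math.ceil(rec.n_samples / spr))
    n_sig = rec.n_channels + 1  # + annotations

    # annotation TALs, grouped per record
    tals: list[bytes] = []
    per_record: dict[int, list[bytes]] = {}
    for sample, label in rec.events:
        onset = sample / rate
        r = min(int(onset), n_rec - 1)
        per_record.setdefault(r, []).append(
            f"+{onset:.4f}\x14class {label}\x14\x00".encode("ascii")
        )
    for r in range(n_rec):
        body = f"+{r}\x14\x14\x00".encode("ascii") + b"".join(per_record.get(r, []))
        tals.append(body)
    ann_bytes = max(len(t) for t in tals)
    ann_spr = (ann_bytes + 1) // 2 + 4  # 2 bytes per annotation "sample", slack

    phys_min, phys_max, scale, offset = [], [], [], []
    for ch in range(rec.n_channels):
        lo = float(np.min(rec.signal[ch])) if rec.n_samples else -1.0
        hi = float(np.max(rec.signal[ch])) if rec.n_samples else 1.0
        amp = max(abs(lo), abs(hi), 1e-6)
        phys_min.append(-amp)
        phys_max.append(amp)
        scale.append(32767.0 / amp)
        offset.append(0.0)

    with open(path, "wb") as f:
        header = b""
        header += _edf_field("0", 8)
        header += _edf_field("X X X X", 80)
        header += _edf_field("Startdate 01-JAN-2000 X X X", 80)
        header += _edf_field("01.01.00", 8)
        header += _edf_field("00.00.00", 8)
        header += _edf_field(256 * (1 + n_sig), 8)
        header += _edf_field("EDF+C", 44)
        header += _edf_field(n_rec, 8)
        header += _edf_field(1, 8)
        header += _edf_field(n_sig, 4)

        labels16 = [lab[:16] for lab in rec.channel_labels] + ["EDF Annotations"]
        header += b"".join(_edf_field(l, 16) for l in labels16)
        header += b"".join(_edf_field("", 80) for _ in range(n_sig))
        header += b"".join(_edf_field("uV", 8) for _ in range(rec.n_channels))
        header += _edf_field("", 8)
        for vals in (phys_min, phys_max):
            header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in vals)
            header += _edf_field(-1 if vals is phys_min else 1, 8)
        header += b"".join(_edf_field(-32767, 8) for _ in range(rec.n_channels))
        header += _edf_field(-32768, 8)
        header += b"".join(_edf_field(32767, 8) for _ in range(rec.n_channels))
        header += _edf_field(32767, 8)
        header += b"".join(_edf_field("", 80) for _ in range(n_sig))
        header += b"".join(_edf_field(spr, 8) for _ in range(rec.n_channels))
        header += _edf_field(ann_spr, 8)
        header += b"".join(_edf_field("", 32) for _ in range(n_sig))
        f.write(header)

        padded = np.zeros((rec.n_channels, n_rec * spr))
        padded[:, : rec.n_samples] = rec.signal
        for r in range(n_rec):
            block = padded[:, r * spr:(r + 1) * spr]
            for ch in range(rec.n_channels):
                dig = np.clip(np.round(block[ch] * scale[ch]), -32767, 32767)
                f.write(dig.astype("<i2").tobytes())
            tal = tals[r].ljust(2 * ann_spr, b"\x00")
            f.write(tal)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _design_bandpass(band, rate, n_samples, transition=2.0, min_taps=31):
    """Linear-phase Hamming band-pass; order sized for the transition width.

    The Hamming window gives ~53 dB stop-band attenuation; the tap count is
    set from the classic 3.3/Δf rule for a 2 Hz transition band, capped so
    filtfilt still has enough signal to pad.
    """
    low, high = band
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist")
    numtaps = int(math.ceil(3.3 * rate / transition))
    cap = max(min_taps, (n_samples - 1) // 3 - 1)
    if numtaps > cap:
        logger.warning("band-pass order capped at %d taps for a %d-sample signal",
                       cap, n_samples)
        numtaps = cap
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [low, high], pass_zero=False,
                      window="hamming", fs=rate)


def preprocess(raw: RawRecording, band=(8.0, 32.0),
               target_rate: float = 100.0) -> RawRecording:
    """Zero-phase FIR band-pass, integer down-sample, then CAR.

    The band-pass doubles as the anti-aliasing filter: with the default
    8-32 Hz band everything above the 50 Hz post-decimation Nyquist is
    already in the stop band. Events are re-indexed to the new rate.
    """
    low, high = band
    if not (0 < low < high < raw.rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={raw.rate / 2})")
    if high >= target_rate / 2:
        raise ValueError(f"band {band} exceeds the target Nyquist {target_rate / 2}")
    factor_f = raw.rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate} must divide the recording rate {raw.rate}"
        )

    taps = _design_bandpass(band, raw.rate, raw.n_samples)
    filtered = sps.filtfilt(taps, [1.0], raw.signal, axis=1)
    decimated = filtered[:, ::factor]
    car = decimated - decimated.mean(axis=0, keepdims=True)
    events = [(int(round(s / factor)), c) for s, c in raw.events]
    events = [(min(s, car.shape[1] - 1), c) for s, c in events]
    return RawRecording(car, target_rate, list(raw.channel_labels), events)


def extract_epochs(raw: RawRecording, window=(0.5, 3.0)) -> EpochSet:
    """Cut cue-locked epochs ``[start, end)`` seconds relative to each marker.

    With the defaults at 100 samples/s this yields T = 250 samples per trial.
    """
    start, end = window
    n_samp = int(round((end - start) * raw.rate))
    if n_samp <= 0:
        raise ValueError(f"window {window} yields an empty epoch")
    offenders = []
    trials, labels = [], []
    for sample, label in raw.events:
        a = sample + int(round(start * raw.rate))
        b = a + n_samp
        if a < 0 or b > raw.n_samples:
            offenders.append((sample, label))
            continue
        trials.append(raw.signal[:, a:b])
        labels.append(label)
    if offenders:
        raise ValueError(
            f"epoch window {window} falls outside the recording for events "
            f"{offenders}"
        )
    return EpochSet(np.stack(trials), np.asarray(labels), raw.rate, start)


def make_splits(epochs: EpochSet, n_folds: int = 10,
                ratio=(8, 1, 1), seed: int = 0) -> list[SplitScheme]:
    """Class-stratified nested splits from a seeded shuffle.

    ``ratio`` gives the number of folds used as train / calibration / test;
    the counts must sum to ``n_folds``. Fold k's scheme rotates the fold
    assignment so each fold is the test partition exactly once when the
    test share is a single fold.
    """
    n_train, n_calib, n_test = ratio
    if n_train + n_calib + n_test != n_folds:
        raise ValueError(f"ratio {ratio} must sum to n_folds={n_folds}")
    if min(ratio) < 1:
        raise ValueError("each partition needs at least one fold")
    rng = np.random.default_rng(seed)

    fold_of = np.empty(epochs.n_trials, dtype=int)
    for cls in (1, 2):
        members = np.flatnonzero(epochs.labels == cls)
        if len(members) < n_folds:
            raise ValueError(
                f"class {cls} has {len(members)} trials < n_folds={n_folds}"
            )
        members = rng.permutation(members)
        for pos, trial in enumerate(members):
            fold_of[trial] = pos % n_folds

    schemes = []
    for k in range(n_folds):
        test_folds = {(k + j) % n_folds for j in range(n_test)}
        calib_folds = {(k + n_test + j) % n_folds for j in range(n_calib)}
        train_folds = set(range(n_folds)) - test_folds - calib_folds
        schemes.append(SplitScheme(
            fold_id=k,
            train_idx=np.flatnonzero(np.isin(fold_of, list(train_folds))),
            calib_idx=np.flatnonzero(np.isin(fold_of, list(calib_folds))),
            test_idx=np.flatnonzero(np.isin(fold_of, list(test_folds))),
        ))
    return schemes
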