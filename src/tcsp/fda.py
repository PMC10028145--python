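"""Fisher discriminant analysis: the two-class linear classifier.

The decision function is ``f(y) = U'y + w0`` with
``U ∝ S_w^{-1}(m_1 - m_2)`` (pooled within-class scatter, lightly
ridge-regularized) and the threshold midway between the projected class
means. ``f(y) > 0`` assigns class D1 (label 1), ``f(y) < 0`` class D2;
the measure-zero tie ``f(y) = 0`` goes to D2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from tcsp import container

logger = logging.getLogger(__name__)

__all__ = ["FDAModel", "train_fda", "fda_predict", "save_fda_model", "load_fda_model"]

RIDGE = 1e-6  # scatter ridge, scaled by trace(S_w)/d


@dataclass
class FDAModel:
    weights: np.ndarray       # U
    threshold: float          # w0
    class_map: tuple[int, int] = (1, 2)   # labels mapped to (D1, D2)
    zero_margin: bool = False

    @property
    def dim(self) -> int:
        return len(self.weights)


def train_fda(features: np.ndarray, labels: np.ndarray,
              ridge: float = RIDGE) -> FDAModel:
    """Fit U and w0 from labeled feature vectors (labels in {1, 2})."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != len(y):
        raise ValueError("one label per feature vector required")
    if set(np.unique(y)) != {1, 2}:
        raise ValueError("training labels must contain both classes 1 and 2")
    d = x.shape[1]
    m1 = x[y == 1].mean(axis=0)
    m2 = x[y == 2].mean(axis=0)
    diff = m1 - m2

    if np.allclose(diff, 0):
        logger.warning("coincident class means: zero-margin FDA, predicting D2")
        return FDAModel(np.zeros(d), 0.0, zero_margin=True)

    sw = np.zeros((d, d))
    for cls, m in ((1, m1), (2, m2)):
        c = x[y == cls] - m
        sw += c.T @ c
    tr = np.trace(sw)
    lam = ridge * (tr / d if tr > 0 else float(diff @ diff))
    try:
        u = linalg.solve(sw + lam * np.eye(d), diff, assume_a="pos")
    except linalg.LinAlgError as err:
        raise ValueError(f"within-class scatter is singular beyond ridge rescue: {err}")
    if not np.all(np.isfinite(u)):
        raise ValueError("within-class scatter is singular beyond ridge rescue")
    w0 = -float(u @ (m1 + m2) / 2)
    return FDAModel(u, w0)


def fda_predict(model: FDAModel, features: np.ndarray):
    """Predict labels and decision values.

    Returns ``(labels, scores)`` with ``scores = U'y + w0``; a score of
    exactly 0 is assigned to D2.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.dim:
        raise ValueError(f"features have dim {x.shape[1]}, model expects {model.dim}")
    scores = x @ model.weights + model.threshold
    d1, d2 = model.class_map
    labels = np.where(scores > 0, d1, d2)
    return labels, scores


def save_fda_model(path, model: FDAModel) -> None:
    container.save_container(path, {
        "weights": model.weights, "threshold": float(model.threshold),
        "class_map": np.asarray(model.class_map, dtype=np.int64),
        "zero_margin": bool(model.zero_margin),
    }, kind="fda_model")


def load_fda_model(path) -> FDAModel:
    p = container.load_container(path, expect_kind="fda_model")
    return FDAModel(p["weights"], float(p["threshold"]),
                    tuple(int(v) for v in p["class_map"]), bool(p["zero_margin"]))
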