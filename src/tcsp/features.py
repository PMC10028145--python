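"""Correlation-template (tCSP) features, frequency calibration, and fusion.

The transformed-CSP feature of a trial at frequency point j is the pair of
Pearson correlations between the trial's concatenated time-frequency row
K^{i,j} and the two class templates (the element-wise means of the
training trials' rows). A held-out calibration partition picks the single
subject-specific optimal frequency point F_a: at each grid point an FDA
classifier trained on the training-set correlation pairs is scored on the
calibration set, the per-point accuracies form the subject's row of the
accuracy matrix Q, and F_a maximizes Q (statistically tied points are
resolved by the held-out decision margin, then toward the lowest
frequency; the selection is expressible as a one-hot selector product).
The final feature vector is y_t = rho[F_a], optionally fused with CSP
log-variance features as Y = [y_t, y_c].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from tcsp.timefreq import TFRGrid, ConcatenatedTFR
from tcsp.fda import train_fda, fda_predict
from tcsp import container

logger = logging.getLogger(__name__)

__all__ = [
    "TemplatePair", "CalibrationResult", "FeatureBundle",
    "compute_templates", "correlate_with_templates", "correlation_profiles",
    "calibrate_frequency", "tcsp_features", "select_one_hot", "fuse",
]


@dataclass
class TemplatePair:
    """Class-mean concatenated power templates (J x T_w each)."""

    template_1: np.ndarray
    template_2: np.ndarray
    n_train: int

    def stacked(self) -> np.ndarray:
        return np.stack([self.template_1, self.template_2])


@dataclass
class CalibrationResult:
    """One subject's calibration outcome: Q row, selector, and F_a."""

    q: np.ndarray              # (J,) calibration accuracies
    selector: np.ndarray       # one-hot over J
    f_a_index: int
    f_a_freq: float
    q_at_f_a: float
    margin: np.ndarray | None = None   # (J,) normalized calibration margins


@dataclass
class FeatureBundle:
    """tCSP correlations, CSP log-variance features, and their fusion."""

    y_t: np.ndarray
    y_c: np.ndarray

    @property
    def fused(self) -> np.ndarray:
        return fuse(self.y_t, self.y_c)


def _as_power(h) -> np.ndarray:
    if isinstance(h, ConcatenatedTFR):
        return h.power
    return np.asarray(h, dtype=float)


def compute_templates(train_h, labels) -> TemplatePair:
    """Element-wise class means over the *training* trials (J x T_w).

    ``train_h`` is a (I, J, T_w) array, a ConcatenatedTFR batch, or a list
    of per-trial ConcatenatedTFR objects.
    """
    if isinstance(train_h, (list, tuple)):
        train_h = np.stack([_as_power(h) for h in train_h])
    else:
        train_h = _as_power(train_h)
    labels = np.asarray(labels, dtype=int)
    if train_h.ndim != 3 or train_h.shape[0] != len(labels):
        raise ValueError("expected one (J, T_w) matrix per labeled training trial")
    present = set(np.unique(labels))
    if not {1, 2} <= present:
        raise ValueError(f"both classes required to build templates, got {present}")
    return TemplatePair(
        template_1=train_h[labels == 1].mean(axis=0),
        template_2=train_h[labels == 2].mean(axis=0),
        n_train=len(labels),
    )


def _center_normalize(rows: np.ndarray) -> np.ndarray:
    """Center each last-axis vector and scale to unit norm; zero rows stay zero."""
    centered = rows - rows.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1, keepdims=True)
    flat = norms == 0
    if np.any(flat):
        logger.warning("%d zero-variance row(s): correlation defined as 0",
                       int(flat.sum()))
    return np.divide(centered, norms, out=np.zeros_like(centered), where=~flat)


def correlation_profiles(h, templates: TemplatePair) -> np.ndarray:
    """Pearson correlation of every frequency row with both templates.

    Returns (J, 2) for a single trial or (I, J, 2) for a batch; entries
    are in [-1, 1], with zero-variance rows mapped to correlation 0.
    """
    power = _as_power(h)
    single = power.ndim == 2
    if single:
        power = power[None]
    t_norm = _center_normalize(templates.stacked())          # (2, J, T_w)
    k_norm = _center_normalize(power)                        # (I, J, T_w)
    rho = np.einsum("ijt,njt->ijn", k_norm, t_norm)          # (I, J, 2)
    rho = np.clip(rho, -1.0, 1.0)
    return rho[0] if single else rho


# alias matching the per-trial operation name
correlate_with_templates = correlation_profiles


def _bootstrap_indices(labels: np.ndarray, n_boot: int, rng) -> list[np.ndarray]:
    """Stratified with-replacement resamples of the calibration trials."""
    out = []
    per_class = {c: np.flatnonzero(labels == c) for c in (1, 2)}
    for _ in range(n_boot):
        picks = [rng.choice(idx, size=len(idx), replace=True)
                 for idx in per_class.values()]
        out.append(np.concatenate(picks))
    return out


def calibrate_frequency(train_h, train_labels, calib_h, calib_labels,
                        grid: TFRGrid, n_boot: int = 10, seed: int = 0,
                        strategy: str = "pooled_cv") -> CalibrationResult:
    """Score every frequency point on held-out calibration data and pick F_a.

    strategy="pooled_cv" (default): training and calibration trials are
    pooled and Q[j] is a 10-fold cross-validated accuracy with templates
    refit inside each fold (calibration data then influence the fold
    templates used for scoring, but never the final model). This keeps
    Q stable even when the calibration partition is small — a handful of
    calibration trials quantizes accuracy so coarsely that the argmax is
    unreliable. strategy="bootstrap": templates and the per-point FDA
    come from the training partition only; Q[j] is the mean accuracy
    over ``n_boot`` seeded stratified bootstrap resamples of the
    calibration trials.

    Estimated accuracy is a quantized, noisy criterion: neighbouring
    grid points are correlated through the Morlet bandwidth, so Q
    typically plateaus around its maximum and the raw argmax is decided
    by binomial noise. All points whose Q lies within one binomial
    standard error of the maximum are therefore treated as tied, the tie
    is broken by the scale-normalized FDA decision margin on the
    held-out trials (a continuous criterion that peaks at the truly
    discriminative frequency), and only a residual tie falls back to the
    lowest frequency.
    """
    train_p = _as_power(train_h) if not isinstance(train_h, (list, tuple)) \
        else np.stack([_as_power(h) for h in train_h])
    calib_p = _as_power(calib_h) if not isinstance(calib_h, (list, tuple)) \
        else np.stack([_as_power(h) for h in calib_h])
    train_labels = np.asarray(train_labels, dtype=int)
    calib_labels = np.asarray(calib_labels, dtype=int)
    for cls in (1, 2):
        if np.sum(calib_labels == cls) < 2:
            raise ValueError("calibration needs at least 2 trials per class")
    n_freq = grid.n_points
    rng = np.random.default_rng(seed)

    margins = np.full(n_freq, -np.inf)
    if strategy == "bootstrap":
        templates = compute_templates(train_p, train_labels)
        rho_train = correlation_profiles(train_p, templates)   # (Itr, J, 2)
        rho_calib = correlation_profiles(calib_p, templates)   # (Ica, J, 2)
        boots = _bootstrap_indices(calib_labels, n_boot, rng)
        sign = np.where(calib_labels == 1, 1.0, -1.0)
        n_eval = len(calib_labels)
        q = np.empty(n_freq)
        for j in range(n_freq):
            model = train_fda(rho_train[:, j, :], train_labels)
            pred, scores = fda_predict(model, rho_calib[:, j, :])
            hits = pred == calib_labels
            q[j] = float(np.mean([hits[b].mean() for b in boots]))
            norm = np.linalg.norm(model.weights)
            if norm > 0:
                margins[j] = float(np.mean(sign * scores) / norm)
    elif strategy == "pooled_cv":
        pool_p = np.concatenate([train_p, calib_p])
        pool_y = np.concatenate([train_labels, calib_labels])
        folds = _stratified_folds(pool_y, n_folds=10, rng=rng)
        n_eval = len(pool_y)
        accs = np.zeros((10, n_freq))
        marg = np.zeros((10, n_freq))
        # trial vectors are fold-independent: center/normalize them once
        k_norm = _center_normalize(pool_p)
        class_sum = {c: pool_p[pool_y == c].sum(axis=0) for c in (1, 2)}
        for k in range(10):
            te = folds == k
            tpl_rows = []
            for c in (1, 2):
                held = pool_p[te & (pool_y == c)]
                n_in = int(np.sum(~te & (pool_y == c)))
                tpl_rows.append((class_sum[c] - held.sum(axis=0)) / n_in)
            t_norm = _center_normalize(np.stack(tpl_rows))
            rho = np.clip(np.einsum("ijt,njt->ijn", k_norm, t_norm), -1, 1)
            sign = np.where(pool_y[te] == 1, 1.0, -1.0)
            for j in range(n_freq):
                model = train_fda(rho[~te][:, j, :], pool_y[~te])
                pred, scores = fda_predict(model, rho[te][:, j, :])
                accs[k, j] = float(np.mean(pred == pool_y[te]))
                norm = np.linalg.norm(model.weights)
                if norm > 0:
                    marg[k, j] = float(np.mean(sign * scores) / norm)
        q = accs.mean(axis=0)
        margins = marg.mean(axis=0)
    else:
        raise ValueError(f"unknown calibration strategy {strategy!r}")

    q_max = q.max()
    se = np.sqrt(max(q_max * (1 - q_max), 0.0) / n_eval)
    tied = np.flatnonzero(q >= q_max - se)
    # tie-break: largest held-out margin; residual ties go to the
    # lowest frequency (np.argmax returns the first maximum)
    idx = int(tied[np.argmax(margins[tied])])
    selector = np.zeros(n_freq)
    selector[idx] = 1.0
    return CalibrationResult(
        q=q, selector=selector, f_a_index=idx,
        f_a_freq=float(grid.freqs[idx]), q_at_f_a=float(q[idx]),
        margin=margins,
    )


def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> np.ndarray:
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        fold[members] = np.arange(len(members)) % n_folds
    return fold


def tcsp_features(profile: np.ndarray, f_a_index: int) -> np.ndarray:
    """Extract y_t = rho[F_a]: the 2-entry correlation pair at the chosen point."""
    profile = np.asarray(profile)
    n_freq = profile.shape[-2]
    if not (0 <= f_a_index < n_freq):
        raise IndexError(f"F_a index {f_a_index} outside the {n_freq}-point grid")
    return profile[..., f_a_index, :]


def select_one_hot(profile: np.ndarray, selector: np.ndarray) -> np.ndarray:
    """Feature selection as the sparse-selector product (equivalent to indexing)."""
    profile = np.asarray(profile)
    selector = np.asarray(selector, dtype=float)
    if int(round(selector.sum())) != 1 or np.any((selector != 0) & (selector != 1)):
        raise ValueError("selector must be one-hot")
    return np.einsum("...jn,j->...n", profile, selector)


def fuse(y_t: np.ndarray, y_c: np.ndarray) -> np.ndarray:
    """Fusion feature vector Y = [y_t, y_c], tCSP correlations first."""
    y_t = np.atleast_1d(np.asarray(y_t, dtype=float))
    y_c = np.atleast_1d(np.asarray(y_c, dtype=float)) if np.size(y_c) else \
        np.empty(0)
    return np.concatenate([y_t, y_c])


def save_calibration(path, result: CalibrationResult) -> None:
    container.save_container(path, {
        "q": result.q, "selector": result.selector,
        "f_a_index": int(result.f_a_index), "f_a_freq": float(result.f_a_freq),
        "q_at_f_a": float(result.q_at_f_a),
    }, kind="calibration")


def load_calibration(path) -> CalibrationResult:
    p = container.load_container(path, expect_kind="calibration")
    return CalibrationResult(p["q"], p["selector"], int(p["f_a_index"]),
                             float(p["f_a_freq"]), float(p["q_at_f_a"]))
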