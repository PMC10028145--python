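"""Common spatial pattern (CSP) fitting, filtering and log-variance features.

CSP finds spatial filters that maximize the variance of one class while
minimizing it for the other. The implementation follows the classical
whitening route: trace-normalized per-trial covariances are averaged per
class, the composite covariance is whitened, and the whitened class
covariance is jointly diagonalized; the filter matrix is ``W = B' P`` with
spatial filters as rows. Because the two whitened class covariances sum to
the identity, their eigenvalues are complementary: ``Λ1 + Λ2 = I``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from tcsp.io import EpochSet
from tcsp import container

logger = logging.getLogger(__name__)

__all__ = ["CSPModel", "fit_csp", "apply_csp", "csp_features",
           "save_csp_model", "load_csp_model"]

#: eigenvalues of the composite covariance below RANK_TOL * max are floored
RANK_TOL = 1e-10


@dataclass
class CSPModel:
    """Fitted CSP filter bank and the intermediate decomposition products."""

    class_cov: tuple[np.ndarray, np.ndarray]   # C̄_1, C̄_2 (N x N)
    composite: np.ndarray                      # C_c = C̄_1 + C̄_2
    whitener: np.ndarray                       # P = D_c^{-1/2} V_c'
    eigvecs: np.ndarray                        # B (columns)
    eigvals: tuple[np.ndarray, np.ndarray]     # Λ_1, Λ_2 diagonals
    filters: np.ndarray                        # W = B' P, rows are filters
    n_keep: int                                # M components kept per end
    channel_labels: list[str] | None = field(default=None)

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    @property
    def selected_filters(self) -> np.ndarray:
        """The first M and last M rows of W, in that order (2M x N)."""
        m = self.n_keep
        return np.vstack([self.filters[:m], self.filters[-m:]])

    @property
    def patterns(self) -> np.ndarray:
        """Forward patterns: columns of W^{-1} (scalp topographies)."""
        return np.linalg.pinv(self.filters)


def _class_covariance(trials: np.ndarray) -> np.ndarray:
    """Average of trace-normalized per-trial spatial covariances.

    Trials are mean-centered across the class (the over-trials average
    matrix is subtracted) before each trial covariance is formed.
    """
    centered = trials - trials.mean(axis=0, keepdims=True)
    covs = np.einsum("int,imt->inm", centered, centered)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("a trial has zero power; cannot normalize covariance")
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(train: EpochSet, n_keep: int = 4,
            regularization: str = "floor", ridge: float = 1e-8) -> CSPModel:
    """Fit the CSP filter matrix from two-class training epochs.

    Parameters
    ----------
    train : EpochSet
        Training trials; both classes must be present.
    n_keep : int
        M, the number of components retained from each end of the
        eigenvalue spectrum (2M features per trial downstream).
    regularization : {"floor", "ridge"}
        How to handle a rank-deficient composite covariance (CAR removes
        one rank): "floor" clips small eigenvalues of C_c at
        ``RANK_TOL * max`` before the inverse square root; "ridge" adds
        ``ridge * trace/N`` to the diagonal of both class covariances.
    """
    classes = np.unique(train.labels)
    if set(classes) != {1, 2}:
        raise ValueError(f"training data must contain both classes, got {classes}")
    n_ch = train.n_channels
    if 2 * n_keep > n_ch:
        raise ValueError(f"2M={2 * n_keep} exceeds the channel count {n_ch}")
    if train.n_samples <= n_ch:
        logger.warning("T=%d <= N=%d: trial covariances are rank deficient",
                       train.n_samples, n_ch)

    c1 = _class_covariance(train.data[train.labels == 1])
    c2 = _class_covariance(train.data[train.labels == 2])
    if regularization == "ridge":
        lam = ridge * np.trace(c1 + c2) / (2 * n_ch)
        c1 = c1 + lam * np.eye(n_ch)
        c2 = c2 + lam * np.eye(n_ch)
    cc = c1 + c2

    # whitening: C_c = V_c D_c V_c', P = D_c^{-1/2} V_c'
    dvals, vecs = linalg.eigh(cc)
    order = np.argsort(dvals)[::-1]
    dvals, vecs = dvals[order], vecs[:, order]
    floor = RANK_TOL * dvals.max()
    if regularization == "floor" and np.any(dvals < floor):
        logger.warning("composite covariance is rank deficient; "
                       "flooring %d eigenvalue(s)", int(np.sum(dvals < floor)))
        dvals = np.maximum(dvals, floor)
    whitener = (vecs / np.sqrt(dvals)).T  # D^{-1/2} V'

    s1 = whitener @ c1 @ whitener.T
    lam1, b = linalg.eigh((s1 + s1.T) / 2)
    s2 = whitener @ c2 @ whitener.T
    lam2 = np.einsum("ij,jk,ki->i", b.T, (s2 + s2.T) / 2, b)

    # Components are ordered by the class-1 variance fraction
    # lam1/(lam1+lam2), descending. Within the retained rank the whitened
    # class covariances sum to the identity, so this equals lam1 itself;
    # directions lost to CAR (lam1+lam2 ~ 0) are pinned to the
    # uninformative midpoint 0.5 so they are never selected from either end.
    total = lam1 + lam2
    informative = total > 0.5
    key = np.where(informative, lam1 / np.where(informative, total, 1.0), 0.5)
    order = np.argsort(-key, kind="stable")
    lam1, lam2, b = lam1[order], lam2[order], b[:, order]

    filters = b.T @ whitener
    # eigenvectors are sign-indeterminate: make the largest coefficient positive
    signs = np.sign(filters[np.arange(n_ch), np.argmax(np.abs(filters), axis=1)])
    signs[signs == 0] = 1.0
    filters = filters * signs[:, None]

    return CSPModel(
        class_cov=(c1, c2), composite=cc, whitener=whitener,
        eigvecs=b, eigvals=(lam1, lam2), filters=filters, n_keep=n_keep,
    )


def apply_csp(model: CSPModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Project trials onto the retained spatial filters.

    Returns the uncorrelated component array Z of shape
    (n_trials, 2M, T); rows 0..M-1 are the class-1-variance-maximizing
    components and rows M..2M-1 the class-2 ones.
    """
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    single = data.ndim == 2
    if single:
        data = data[None]
    if data.shape[1] != model.n_channels:
        raise ValueError(
            f"epochs have {data.shape[1]} channels, model expects {model.n_channels}"
        )
    z = np.einsum("cn,int->ict", model.selected_filters, data)
    return z[0] if single else z


def csp_features(z: np.ndarray) -> np.ndarray:
    """Log band-power proportion features from one trial's components.

    ``sigma_p = log(var(z_p) / sum_q var(z_q))`` with the unbiased sample
    variance over time; the exponentials of the feature vector sum to 1.
    """
    z = np.asarray(z)
    if z.ndim != 2:
        raise ValueError("expected a 2M x T component matrix")
    variances = z.var(axis=1, ddof=1)
    zero = np.flatnonzero(variances <= 0)
    if zero.size:
        raise ValueError(f"component row(s) {zero.tolist()} have zero variance")
    return np.log(variances / variances.sum())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _model_payload(model: CSPModel) -> dict:
    payload = {
        "class_cov_1": model.class_cov[0], "class_cov_2": model.class_cov[1],
        "composite": model.composite, "whitener": model.whitener,
        "eigvecs": model.eigvecs,
        "eigvals_1": model.eigvals[0], "eigvals_2": model.eigvals[1],
        "filters": model.filters, "n_keep": int(model.n_keep),
    }
    if model.channel_labels is not None:
        payload["channel_labels"] = list(model.channel_labels)
    return payload


def save_csp_model(path, model: CSPModel) -> None:
    container.save_container(path, _model_payload(model), kind="csp_model")


def load_csp_model(path) -> CSPModel:
    p = container.load_container(path, expect_kind="csp_model")
    return CSPModel(
        class_cov=(p["class_cov_1"], p["class_cov_2"]),
        composite=p["composite"], whitener=p["whitener"], eigvecs=p["eigvecs"],
        eigvals=(p["eigvals_1"], p["eigvals_2"]), filters=p["filters"],
        n_keep=int(p["n_keep"]),
        channel_labels=p.get("channel_labels"),
    )
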