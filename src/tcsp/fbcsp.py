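"""Filter-bank CSP comparator.

CSP is fit independently in contiguous sub-bands (default 8-32 Hz in six
4 Hz bands), log-variance features are pooled across bands, and the most
label-informative features are kept by a quantile-binned mutual-information
ranking estimated on the training data. This is one concrete, documented
variant of the filter-bank family; comparisons against it are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from tcsp.io import EpochSet
from tcsp.csp import fit_csp, apply_csp, csp_features

__all__ = ["FilterBank", "fbcsp_features", "mutual_information_binned"]


def _default_bands():
    return [(8.0 + 4 * k, 12.0 + 4 * k) for k in range(6)]


@dataclass
class FilterBank:
    """Ordered, non-degenerate sub-bands in Hz."""

    bands: list[tuple[float, float]] = field(default_factory=_default_bands)

    def __post_init__(self):
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"degenerate band ({lo}, {hi})")
        lows = [b[0] for b in self.bands]
        if lows != sorted(lows):
            raise ValueError("bands must be ordered by lower edge")

    def __len__(self):
        return len(self.bands)


def _bandpass_epochs(epochs: EpochSet, band, order: int = 4) -> EpochSet:
    lo, hi = band
    if hi >= epochs.rate / 2:
        raise ValueError(f"band {band} reaches Nyquist {epochs.rate / 2}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=epochs.rate,
                     output="sos")
    data = sps.sosfiltfilt(sos, epochs.data, axis=2)
    return EpochSet(data, epochs.labels, epochs.rate, epochs.window_start)


def mutual_information_binned(feature: np.ndarray, labels: np.ndarray,
                              n_bins: int = 4) -> float:
    """Mutual information (nats) between a quantile-binned feature and the label."""
    edges = np.quantile(feature, np.linspace(0, 1, n_bins + 1)[1:-1])
    binned = np.searchsorted(edges, feature)
    mi = 0.0
    n = len(labels)
    for b in np.unique(binned):
        for c in np.unique(labels):
            pxy = np.mean((binned == b) & (labels == c))
            if pxy == 0:
                continue
            px = np.mean(binned == b)
            py = np.mean(labels == c)
            mi += pxy * np.log(pxy / (px * py))
    return float(mi)


def fbcsp_features(train: EpochSet, evaluation: EpochSet,
                   bank: FilterBank | None = None, n_keep: int = 4,
                   k_select: int | None = 8, n_bins: int = 4,
                   assume_filtered: tuple[float, float] | None = None):
    """Per-band CSP features with mutual-information selection.

    Fits one CSP per sub-band on the training epochs, pools the 2M
    log-variance features of every band, ranks them by mutual information
    with the training labels (quantile-binned), and keeps the top
    ``k_select`` (all features when ``k_select`` is None). The selection
    learned on the training data is applied unchanged to ``evaluation``.

    ``assume_filtered`` names a band already applied upstream; a sub-band
    equal to it is used without re-filtering.

    Returns ``(train_features, eval_features, info)`` where ``info`` holds
    the per-feature band index, mutual-information scores, and the kept
    column indices.
    """
    bank = bank or FilterBank()
    feats_train, feats_eval, band_of = [], [], []
    for b_idx, band in enumerate(bank.bands):
        if assume_filtered is not None and tuple(band) == tuple(assume_filtered):
            tr_band, ev_band = train, evaluation
        else:
            tr_band = _bandpass_epochs(train, band)
            ev_band = _bandpass_epochs(evaluation, band)
        model = fit_csp(tr_band, n_keep=n_keep)
        z_tr = apply_csp(model, tr_band)
        z_ev = apply_csp(model, ev_band)
        feats_train.append(np.stack([csp_features(z) for z in z_tr]))
        feats_eval.append(np.stack([csp_features(z) for z in z_ev]))
        band_of.extend([b_idx] * (2 * n_keep))
    x_tr = np.hstack(feats_train)
    x_ev = np.hstack(feats_eval)

    scores = np.array([
        mutual_information_binned(x_tr[:, k], train.labels, n_bins=n_bins)
        for k in range(x_tr.shape[1])
    ])
    if k_select is None or k_select >= x_tr.shape[1]:
        kept = np.arange(x_tr.shape[1])
    else:
        kept = np.sort(np.argsort(scores)[::-1][:k_select])
    info = {"band_of_feature": np.asarray(band_of), "mi_scores": scores,
            "kept": kept}
    return x_tr[:, kept], x_ev[:, kept], info
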