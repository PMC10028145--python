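"""End-to-end experiment orchestration and accuracy aggregation.

For every nested train/calibration/test split the pipeline fits CSP on
the training partition, transforms and concatenates the components,
builds class templates from training trials only, calibrates the optimal
frequency point on the calibration partition, trains one FDA per method
variant on the training features, and scores the held-out test trials.
The test partition's labels are used exclusively for scoring — nothing
fitted depends on them, which the leakage guard asserts bit-wise on the
serialized models.

Method names: ``csp``, ``fbcsp``, ``tcsp``, and the fusions ``tcsp+csp``,
``tcsp+fbcsp``, ``csp+fbcsp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from tcsp.io import EpochSet, RawRecording, preprocess, extract_epochs, make_splits
from tcsp.csp import fit_csp, apply_csp, csp_features, _model_payload
from tcsp.timefreq import make_grid, morlet_tfr, concatenate_tfr
from tcsp.features import (
    compute_templates, correlation_profiles, calibrate_frequency,
    tcsp_features, fuse,
)
from tcsp.fda import train_fda, fda_predict
from tcsp.fbcsp import FilterBank, fbcsp_features

__all__ = ["ExperimentConfig", "run_subject", "aggregate", "KNOWN_METHODS"]

KNOWN_METHODS = ("csp", "fbcsp", "tcsp", "csp+fbcsp", "tcsp+fbcsp", "tcsp+csp")


@dataclass
class ExperimentConfig:
    """Resolved parameters of one experiment run.

    Defaults follow the broadband motor-imagery setting: 8-32 Hz band,
    100 samples/s, a 0.5-3.0 s post-cue window, 10-fold nested splits
    with an 8/1/1 train/calibration/test ratio, M = 4 CSP components per
    end, and a 32-point frequency grid over the analysis band.
    """

    band: tuple[float, float] = (8.0, 32.0)
    target_rate: float = 100.0
    window: tuple[float, float] = (0.5, 3.0)
    n_folds: int = 10
    ratio: tuple[int, int, int] = (8, 1, 1)
    methods: tuple[str, ...] = ("csp", "tcsp", "tcsp+csp")
    m_csp: int = 4
    grid_band: tuple[float, float] | None = None
    n_freqs: int = 32
    n_cycles: float = 7.0
    calib_strategy: str = "pooled_cv"
    n_boot: int = 10
    fbcsp_bands: list[tuple[float, float]] | None = None
    fbcsp_k_select: int = 8
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one method required")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {KNOWN_METHODS}")
        if self.grid_band is None:
            self.grid_band = tuple(self.band)

    def as_dict(self) -> dict:
        return asdict(self)


def _trial_features(z_batch: np.ndarray) -> np.ndarray:
    return np.stack([csp_features(z) for z in z_batch])


def _concat_power(model, epochs, config, grid):
    z = apply_csp(model, epochs)                       # (I, 2M, T)
    g = morlet_tfr(z, epochs.rate, grid, n_cycles=config.n_cycles)
    # float32 halves the footprint of the (I, J, 2M*T) blocks; the
    # correlation features are O(1) quantities and do not need float64
    return concatenate_tfr(g, grid).power.astype(np.float32)  # (I, J, 2M*T)


def run_fold(epochs: EpochSet, scheme, config: ExperimentConfig):
    """Fit every requested method on one split; return accuracies + models.

    Returns ``(accuracies, detail)``: a dict method -> test accuracy and a
    detail dict holding the chosen frequency point, the calibration Q
    vector, and a serializable payload of every fitted quantity.
    """
    train = epochs.subset(scheme.train_idx)
    calib = epochs.subset(scheme.calib_idx)
    test = epochs.subset(scheme.test_idx)
    grid = make_grid(config.grid_band, config.n_freqs)
    needs_tcsp = any("tcsp" in m for m in config.methods)
    needs_csp = needs_tcsp or any(m in ("csp", "csp+fbcsp") for m in config.methods)
    needs_fb = any("fbcsp" in m for m in config.methods)

    models_payload: dict = {}
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    if needs_csp:
        csp_model = fit_csp(train, n_keep=config.m_csp)
        models_payload["csp"] = _model_payload(csp_model)
        yc_train = _trial_features(apply_csp(csp_model, train))
        yc_test = _trial_features(apply_csp(csp_model, test))
        feats["csp"] = (yc_train, yc_test)

    detail = {"fold": scheme.fold_id}
    if needs_tcsp:
        h_train = _concat_power(csp_model, train, config, grid)
        h_calib = _concat_power(csp_model, calib, config, grid)
        h_test = _concat_power(csp_model, test, config, grid)
        templates = compute_templates(h_train, train.labels)
        calres = calibrate_frequency(
            h_train, train.labels, h_calib, calib.labels, grid,
            n_boot=config.n_boot, seed=config.seed + scheme.fold_id,
            strategy=config.calib_strategy,
        )
        rho_train = correlation_profiles(h_train, templates)
        rho_test = correlation_profiles(h_test, templates)
        yt_train = tcsp_features(rho_train, calres.f_a_index)
        yt_test = tcsp_features(rho_test, calres.f_a_index)
        feats["tcsp"] = (yt_train, yt_test)
        models_payload["templates"] = {
            "template_1": templates.template_1, "template_2": templates.template_2,
        }
        models_payload["calibration"] = {
            "q": calres.q, "selector": calres.selector,
            "f_a_index": int(calres.f_a_index), "f_a_freq": float(calres.f_a_freq),
        }
        detail["f_a_freq"] = calres.f_a_freq
        detail["f_a_index"] = calres.f_a_index
        detail["q"] = calres.q

    if needs_fb:
        bank = FilterBank(config.fbcsp_bands) if config.fbcsp_bands else FilterBank()
        fb_train, fb_test, fb_info = fbcsp_features(
            train, test, bank, n_keep=config.m_csp,
            k_select=config.fbcsp_k_select, assume_filtered=config.band,
        )
        feats["fbcsp"] = (fb_train, fb_test)
        models_payload["fbcsp_selection"] = {
            "kept": fb_info["kept"], "mi_scores": fb_info["mi_scores"],
        }

    accuracies = {}
    for method in config.methods:
        parts = method.split("+")
        x_train = np.hstack([feats[p][0] for p in parts])
        x_test = np.hstack([feats[p][1] for p in parts])
        fda = train_fda(x_train, train.labels)
        models_payload[f"fda_{method}"] = {
            "weights": fda.weights, "threshold": float(fda.threshold),
        }
        pred, _ = fda_predict(fda, x_test)
        accuracies[method] = float(np.mean(pred == test.labels))
    detail["models"] = models_payload
    return accuracies, detail


def run_subject(data, config: ExperimentConfig, subject: str = "S1",
                already_preprocessed: bool = False):
    """Run the nested cross-validated comparison for one subject.

    ``data`` may be a RawRecording (preprocessed and epoched per the
    config unless ``already_preprocessed``) or an EpochSet. Returns
    ``(table, details)``: a tidy DataFrame with one row per
    subject/method/fold and a list of per-fold detail dicts (chosen F_a,
    Q vector, serializable fitted models).
    """
    if isinstance(data, RawRecording):
        raw = data if already_preprocessed else preprocess(
            data, band=config.band, target_rate=config.target_rate)
        epochs = extract_epochs(raw, window=config.window)
    elif isinstance(data, EpochSet):
        epochs = data
    else:
        raise TypeError("data must be a RawRecording or an EpochSet")

    schemes = make_splits(epochs, n_folds=config.n_folds, ratio=config.ratio,
                          seed=config.seed)
    rows, details = [], []
    for scheme in schemes:
        accs, detail = run_fold(epochs, scheme, config)
        detail["subject"] = subject
        details.append(detail)
        for method, acc in accs.items():
            rows.append({"subject": subject, "method": method,
                         "fold": scheme.fold_id, "accuracy": acc})
    return pd.DataFrame(rows), details


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Subject x method accuracy table with Av. / Std. summary rows.

    Fold accuracies are first averaged within subject; the summary rows
    are the across-subject mean and population standard deviation. The
    per-fold standard deviation is available from the tidy table itself.
    """
    if table.empty:
        raise ValueError("no results to aggregate")
    per_subject = (table.groupby(["subject", "method"])["accuracy"]
                   .mean().unstack("method"))
    summary = pd.DataFrame({
        m: {"Av.": per_subject[m].mean(), "Std.": per_subject[m].std(ddof=0)}
        for m in per_subject.columns
    })
    out = pd.concat([per_subject, summary])
    out.attrs["best_method_per_subject"] = per_subject.idxmax(axis=1).to_dict()
    return out
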