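"""The transformed-CSP chain: templates, calibration, and features.

After CSP, each trial's components are Morlet-transformed (32 frequency
points, 8-32 Hz) and concatenated along time into one J x T_w matrix.
Class templates are the training means; a trial's feature at frequency j
is its pair of Pearson correlations with the two templates. Calibration
scores every frequency point and picks the subject-specific optimum F_a
— which should land on the simulated rhythm frequency.
"""

import numpy as np

from tcsp import (
    SimulationSpec, simulate_recording, preprocess, extract_epochs,
    make_splits, fit_csp, apply_csp, make_grid, morlet_tfr, concatenate_tfr,
    compute_templates, correlate_with_templates, calibrate_frequency,
    tcsp_features, fuse, csp_features,
)

grid = make_grid((8, 32), 32)
f0 = float(grid.freqs[grid.nearest(11.0)])   # place the rhythm on-grid
spec = SimulationSpec(n_trials=60, erd_depth=0.5, snr=1.0, f0=f0, seed=2)
rec, _ = simulate_recording(spec)
epochs = extract_epochs(preprocess(rec, (8, 32), 100), (0.5, 3.0))
scheme = make_splits(epochs, n_folds=10, ratio=(8, 1, 1), seed=2)[0]
train = epochs.subset(scheme.train_idx)
calib = epochs.subset(scheme.calib_idx)

model = fit_csp(train, n_keep=4)


def concat(ep):
    g = morlet_tfr(apply_csp(model, ep), ep.rate, grid)
    return concatenate_tfr(g, grid).power


h_train, h_calib = concat(train), concat(calib)
print(f"concatenated representation: {h_train.shape[1]} frequencies x "
      f"{h_train.shape[2]} samples ({h_train.shape[2] / 100:.0f} s)")

result = calibrate_frequency(h_train, train.labels, h_calib, calib.labels,
                             grid, seed=2)
print(f"optimal frequency point F_a = {result.f_a_freq:.2f} Hz "
      f"(true rhythm at {f0:.2f} Hz), calibration accuracy "
      f"{result.q_at_f_a:.2f}")

templates = compute_templates(h_train, train.labels)
rho = correlate_with_templates(h_train[0], templates)
y_t = tcsp_features(rho, result.f_a_index)
y_c = csp_features(apply_csp(model, train.data[0]))
y = fuse(y_t, y_c)
print(f"trial 0 (class {train.labels[0]}): y_t = {np.round(y_t, 3)}, "
      f"fused feature length = {len(y)}")
print("y_t correlates the trial with the class-1 and class-2 templates; "
      "the entry matching the trial's own class should be the larger one.")
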