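"""Cross-validated comparison of CSP, tCSP, and their fusion.

Runs the full nested train/calibration/test pipeline on one simulated
subject and prints the per-method accuracy table. Under a narrowband
ERD decoded through a broad 8-32 Hz band-pass, the correlation-template
features (tcsp) typically match or beat broadband log-variance features
(csp), and the fusion is at least as good as either alone.
"""

from tcsp import SimulationSpec, simulate_recording
from tcsp.pipeline import ExperimentConfig, run_subject, aggregate

spec = SimulationSpec(n_trials=40, erd_depth=0.5, snr=0.5, seed=5)
rec, _ = simulate_recording(spec)

config = ExperimentConfig(methods=("csp", "fbcsp", "tcsp", "tcsp+csp"),
                          seed=5)
table, details = run_subject(rec, config, subject="sim05")

print(aggregate(table).to_string(float_format=lambda v: f"{v:.3f}"))
freqs = sorted(d["f_a_freq"] for d in details)
print(f"\nF_a chosen per fold (Hz): {[round(f, 1) for f in freqs]}")
print("Rows are per-subject mean accuracies over the 10 folds; 'Av.'/'Std.'"
      " summarize across subjects (one here). The chosen F_a values cluster"
      f" near the simulated rhythm ({spec.f0} Hz).")
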