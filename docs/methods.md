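# Methods

## The decoding problem

Two-class motor-imagery (MI) brain–computer interfaces decode which hand a
subject imagines moving from multichannel EEG. The physiological signature
is event-related desynchronization (ERD): a task-locked drop of sensorimotor
rhythm power (mu, ~8–14 Hz; beta, ~14–30 Hz), strongest over the hemisphere
contralateral to the imagined hand (electrodes C3/C4). Common spatial
pattern (CSP) filtering extracts this contrast spatially, but its
log-variance features integrate power over the whole analysis band, so a
narrowband, subject-specific effect is diluted by broadband background
activity. The transformed-CSP (tCSP) chain implemented here moves the
frequency optimization *after* the spatial filtering: CSP components are
taken to the time-frequency domain, concatenated, compared against class
templates by Pearson correlation, and a held-out calibration partition
selects the single most discriminative frequency point per subject.

## Pipeline

1. **Preprocessing** (`tcsp.io`). Zero-phase FIR band-pass (Hamming
   windowed-sinc, tap count from the 3.3/Δf rule with a 2 Hz transition,
   applied forward–backward), integer decimation to 100 samples/s (the
   band-pass doubles as the anti-aliasing filter since the default 8–32 Hz
   band lies below the post-decimation Nyquist), then common average
   reference (CAR). Epochs are cut half-open `[start, end)` relative to
   each cue; defaults 0.5–3.0 s (T = 250 samples). Nested
   train/calibration/test splits are class-stratified from a seeded
   shuffle; the default 10-fold 8/1/1 ratio gives 64/8/8 trials at 40
   trials per class.
2. **CSP** (`tcsp.csp`). Per class: trials are centered by the
   over-trials mean matrix, each trial covariance is trace-normalized,
   then averaged. The composite covariance is eigendecomposed and
   whitened (`P = D^{-1/2} V'`); the whitened class-1 covariance is
   diagonalized by `B`, and the filter matrix is `W = B'P` with filters
   as rows. Eigenvalue complementarity `Λ1 + Λ2 = I` holds on the
   retained rank and is checked in the tests. The first and last
   M = 4 rows are kept (2M = 8 components); log-variance features are
   `log(var_p / Σ var_q)`.
3. **Time-frequency transform** (`tcsp.timefreq`). Each component is
   convolved with 7-cycle complex Morlet wavelets (L2-normalized,
   truncated at ±5 σ_t, reflection padding, same-length output) on a
   linear grid of 32 points over 8–32 Hz (step ≈ 0.77 Hz). Power
   (squared magnitude) is kept and the 2M per-component maps are
   concatenated along time into one J × T_w matrix, T_w = 2M·T (20 s at
   the defaults).
4. **Templates and correlation features** (`tcsp.features`). Class
   templates are element-wise means of the training trials'
   concatenated power. A trial's feature at frequency j is the pair of
   Pearson correlations of its row j with the two templates. Pearson
   centering/normalization makes the feature invariant to per-trial
   power scaling — the property that protects it from global rhythm
   amplitude fluctuations.
5. **Frequency calibration.** At every grid point an FDA classifier on
   the 2-entry correlation features is scored against held-out data,
   giving the subject's row of the accuracy matrix Q. The default
   scoring pools training and calibration trials into a 10-fold
   cross-validation with templates refit per fold; a
   strictly-training-only bootstrap alternative
   (`strategy="bootstrap"`) rescoring the calibration partition is
   selectable. The optimal point F_a maximizes Q; because neighbouring
   points are correlated through the Morlet bandwidth and accuracy is
   quantized, all points within one binomial standard error of the
   maximum are treated as tied and the tie is broken by the
   scale-normalized FDA decision margin on the held-out trials, falling
   back to the lowest frequency. Selection is expressible as a one-hot
   selector product, and both paths are tested for equivalence.
6. **Classification and fusion** (`tcsp.fda`, `tcsp.features.fuse`).
   FDA: `U ∝ S_w^{-1}(m1 − m2)` with a ridge of `1e-6·trace(S_w)/d` on
   the pooled within-class scatter, threshold midway between projected
   means, `f(y) = 0` assigned to class 2. Fusion concatenates
   `Y = [y_t, y_c]` with the correlation pair first; any of
   csp / fbcsp / tcsp and their pairwise fusions can be run side by
   side on identical splits (`tcsp.pipeline`).
7. **Filter-bank comparator** (`tcsp.fbcsp`). Six contiguous 4 Hz
   sub-bands over 8–32 Hz (4th-order Butterworth, zero-phase), CSP with
   M = 4 per band, features pooled and ranked by quantile-binned (4
   bins) mutual information with the training labels, top 8 kept. With
   a single band equal to the global band-pass and no selection it
   reduces exactly to plain CSP. All of these settings are one concrete
   variant of the filter-bank family; comparisons against it are
   qualitative.

## Synthetic data generator

`tcsp.simulate` emulates the phenomenology the pipeline targets, not a
biophysical head model. Two sinusoidal sources at f0 (default 11 Hz, random
phase per trial) with smooth unimodal topographies peaking over C3 and C4
(unit-norm mixing columns) ride on independent per-channel pink noise
(PSD ∝ 1/f, FFT-shaped) plus white sensor noise. From cue onset to cue+4 s
the source contralateral to the imagined hand is attenuated in amplitude by
`erd_depth` (multiplicative, matching the ratio definition of ERSP
baselining) and the ipsilateral source by a third of that, reproducing the
bilateral-but-contralateral-dominant ERD pattern. `snr` is the
channel-averaged rhythm-to-background power ratio at nominal amplitude.

Trial-to-trial rhythm power in real EEG fluctuates strongly and mostly
bilaterally (vigilance); the generator therefore draws a per-trial log-gain
shared by both sources (sd 0.5) plus a smaller independent per-source
log-gain (sd 0.15). This within-class variability is what keeps
single-trial decoding away from the ceiling and is exactly the nuisance
against which scale-invariant correlation features are robust while
log-variance features are not. With both terms at 0 the generator is
deterministic in amplitude, which the closed-form ERSP checks use
(attenuation `1−d` appears as `20·log10(1−d)` dB, −6.02 dB at d = 0.5).

What the generator does **not** emulate: realistic volume conduction
(leadfield mixing), EOG/EMG artifacts, beta-band rebound (ERS), 50 Hz line
noise, non-stationary background, or inter-subject variability of rhythm
frequency. Passing tests therefore demonstrate correctness of the chain
and its behaviour under the modeled ERD physiology, not performance on
real recordings.

## Numerical choices and degenerate inputs

- **Rank deficiency after CAR.** CAR removes one spatial rank, so the
  composite covariance has a near-null direction. Its eigenvalues are
  floored at `1e-10 × max` before the inverse square root (a Tikhonov
  ridge on the class covariances is selectable). Components are ordered
  by the class-1 variance *fraction* `λ1/(λ1+λ2)` rather than raw `λ1`;
  within the retained rank the two coincide exactly, and directions lost
  to CAR (where `λ1+λ2 ≈ 0`) are pinned to the uninformative midpoint
  0.5 so they are never preferred from either end of the spectrum.
- **Sign conventions.** Filter rows are normalized so the
  largest-magnitude coefficient is positive (power features are
  sign-invariant; stored models become reproducible).
- **Zero-variance rows** in templates or trials yield correlation 0 with
  a logged warning rather than NaN; zero-variance CSP components raise,
  naming the row.
- **Coincident class means** in FDA produce a zero-margin model that
  predicts class 2 everywhere (with a warning) so permutation tests run
  to completion.
- **Test trials are never centered** by training class means: centering
  enters covariance estimation only, and the filter application uses
  the raw trial.
- **Calibration data never enter the final model**: final templates,
  the FDA, and the CSP filters come from the training partition alone;
  calibration only chooses F_a. The pipeline's leakage guard asserts
  bit-identical serialized models when test labels are replaced by
  dummies (HDF5 written with `track_times=False` to make serialization
  deterministic).

## Problem sizes used in the shipped checks

The simulation studies in the test-suite and the acceptance script use 40
trials/class for the method comparison (ERD depth 0.5, snr 0.5, 20 seeds),
60 trials/class for frequency recovery (20 seeds), and 100 trials/class for
the null calibration (200 test trials); the CSP oracle runs 100 random
problems at N ≤ 8. These sizes give stable Monte-Carlo estimates at
interactive runtimes.

## Known limitations

- Exactly one frequency point is selected per subject; no multi-point or
  band selection.
- Binary classification only; no one-vs-rest extension.
- The filter-bank comparator fixes one variant of a family with many
  published configurations; its numbers are context, not a reference
  implementation.
- With 8 simulated channels and M = 4, all 2M = 8 retained components
  include the CAR-null direction; its log-variance feature is nearly
  constant and carries no discriminative weight, but appears in feature
  vectors (visible as a large negative entry).
- EDF export quantizes to 16 bits per channel with per-channel symmetric
  scaling.
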