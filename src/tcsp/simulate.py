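"""Synthetic two-class motor-imagery EEG with controllable lateralized ERD.

The generator emulates the phenomenology that drives sensorimotor-rhythm
decoding: two narrowband oscillatory sources (one per hemisphere, peaking
over the motor channels) ride on 1/f pink background noise plus white
sensor noise. From cue onset the source contralateral to the imagined
hand is attenuated in amplitude by ``erd_depth`` (the ipsilateral source
by a configurable fraction of that), producing the classic
contralateral-dominant event-related desynchronization. Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tcsp.io import RawRecording, save_recording, write_edf

__all__ = ["SimulationSpec", "GroundTruth", "simulate_recording", "write_fixture"]

_DEFAULT_LABELS = ["F7", "C5", "C3", "C1", "C2", "C4", "C6", "F8"]


@dataclass
class SimulationSpec:
    """Parameters of the simulated recording.

    ``n_trials`` is per class; ``window`` is the trial span in seconds
    with the cue at 0 (the pre-cue second provides the ERSP baseline);
    ``snr`` is the channel-averaged rhythm-to-background power ratio
    before cue onset (at the nominal amplitude); ``erd_depth`` is the
    fractional amplitude attenuation of the contralateral source during
    the 4 s task period.

    Sensorimotor rhythm power fluctuates strongly from trial to trial in
    real recordings, and this within-class variability is what keeps
    single-trial decoding away from the ceiling. The fluctuation is
    mostly bilateral (vigilance-driven), with a smaller independent
    hemispheric part: ``amp_variability`` is the standard deviation of a
    per-trial log-gain shared by both sources, ``amp_asymmetry`` that of
    an additional per-source log-gain. Set both to 0 for a
    deterministic-amplitude model (used by closed-form power checks).
    """

    n_channels: int = 8
    rate: float = 100.0
    n_trials: int = 40
    window: tuple[float, float] = (-1.0, 5.0)
    f0: float = 11.0
    erd_depth: float = 0.5
    snr: float = 1.0
    ipsi_fraction: float = 1 / 3
    amp_variability: float = 0.5
    amp_asymmetry: float = 0.15
    erd_duration: float = 4.0
    gap: float = 1.0
    pink_fraction: float = 0.8
    mixing: np.ndarray | None = None
    channel_labels: list[str] = field(default_factory=lambda: list(_DEFAULT_LABELS))
    left_motor: str = "C3"
    right_motor: str = "C4"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        if not 0 < self.f0 < self.rate / 2:
            raise ValueError("f0 must lie below the Nyquist frequency")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.amp_variability < 0 or self.amp_asymmetry < 0:
            raise ValueError("amplitude variability terms must be non-negative")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")
        if self.n_trials < 1:
            raise ValueError("need at least one trial per class")
        if len(self.channel_labels) != self.n_channels:
            if self.n_channels <= len(_DEFAULT_LABELS):
                self.channel_labels = _DEFAULT_LABELS[: self.n_channels]
            else:
                self.channel_labels = [f"CH{k}" for k in range(self.n_channels)]
        if self.mixing is None:
            self.mixing = _default_mixing(self.n_channels, self.channel_labels,
                                          self.left_motor, self.right_motor)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.n_channels, 2):
            raise ValueError("mixing must be n_channels x 2 (left, right source)")
        norms = np.linalg.norm(self.mixing, axis=0)
        if np.any(norms == 0):
            raise ValueError("mixing columns must be nonzero")
        self.mixing = self.mixing / norms


@dataclass
class GroundTruth:
    """What the simulator actually put into the recording."""

    f0: float
    erd_depth: float
    mixing: np.ndarray
    labels: np.ndarray         # per-trial class, in event order
    cue_samples: np.ndarray


def _default_mixing(n_channels, labels, left_motor, right_motor) -> np.ndarray:
    """Smooth unimodal topographies peaking over the two motor channels."""
    x = np.linspace(-1.0, 1.0, n_channels)
    li = labels.index(left_motor) if left_motor in labels else n_channels // 4
    ri = labels.index(right_motor) if right_motor in labels else 3 * n_channels // 4
    width = 0.35
    left = np.exp(-((x - x[li]) ** 2) / (2 * width ** 2))
    right = np.exp(-((x - x[ri]) ** 2) / (2 * width ** 2))
    return np.column_stack([left, right])


def _pink_noise(rng, n_channels, n_samples) -> np.ndarray:
    """Unit-variance pink noise (PSD ~ 1/f) via FFT spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= shape
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def simulate_recording(spec: SimulationSpec) -> tuple[RawRecording, GroundTruth]:
    """Generate the continuous recording and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    trial_len = int(round((spec.window[1] - spec.window[0]) * rate))
    cue_offset = int(round(-spec.window[0] * rate))
    gap_len = int(round(spec.gap * rate))
    n_total = 2 * spec.n_trials
    block = trial_len + gap_len
    n_samples = n_total * block

    labels = rng.permutation(np.repeat([1, 2], spec.n_trials))

    # background: pink + white sensor noise, unit total variance per channel
    signal = np.sqrt(spec.pink_fraction) * _pink_noise(rng, spec.n_channels, n_samples)
    signal += np.sqrt(1 - spec.pink_fraction) * rng.standard_normal(
        (spec.n_channels, n_samples))

    # rhythm amplitude from the channel-averaged SNR (mixing columns unit-norm,
    # so the mean mixed rhythm power over channels is a^2 / n_channels)
    amp = float(np.sqrt(spec.snr * spec.n_channels))

    t = np.arange(trial_len) / rate
    erd_start = cue_offset
    erd_stop = min(trial_len, cue_offset + int(round(spec.erd_duration * rate)))
    cue_samples = np.empty(n_total, dtype=int)
    for i, label in enumerate(labels):
        start = i * block
        cue_samples[i] = start + cue_offset
        phases = rng.uniform(0, 2 * np.pi, size=2)
        shared = spec.amp_variability * rng.standard_normal()
        gains = np.exp(shared + spec.amp_asymmetry * rng.standard_normal(2))
        sources = (amp * gains[:, None]
                   * np.sin(2 * np.pi * spec.f0 * t[None, :] + phases[:, None]))
        envelope = np.ones((2, trial_len))
        # class 1 = left hand: contralateral (right hemisphere) source suppressed
        contra = 1 if label == 1 else 0
        ipsi = 1 - contra
        envelope[contra, erd_start:erd_stop] = 1 - spec.erd_depth
        envelope[ipsi, erd_start:erd_stop] = 1 - spec.erd_depth * spec.ipsi_fraction
        signal[:, start:start + trial_len] += spec.mixing @ (sources * envelope)

    events = [(int(s), int(c)) for s, c in zip(cue_samples, labels)]
    rec = RawRecording(signal, rate, list(spec.channel_labels), events)
    truth = GroundTruth(f0=spec.f0, erd_depth=spec.erd_depth,
                        mixing=spec.mixing.copy(), labels=labels,
                        cue_samples=cue_samples)
    return rec, truth


def write_fixture(recording: RawRecording, truth: GroundTruth, path) -> dict:
    """Write the recording + ground-truth sidecar; also export EDF.

    Returns the paths written: the numeric_container at ``path`` and an
    EDF twin next to it (for reader round-trip tests).
    """
    path = Path(path)
    sidecar = {
        "f0": float(truth.f0),
        "erd_depth": float(truth.erd_depth),
        "mixing": truth.mixing,
        "labels": truth.labels.astype(np.int64),
        "cue_samples": truth.cue_samples.astype(np.int64),
    }
    save_recording(path, recording, ground_truth=sidecar)
    edf_path = path.with_suffix(".edf")
    write_edf(edf_path, recording)
    return {"container": path, "edf": edf_path}
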