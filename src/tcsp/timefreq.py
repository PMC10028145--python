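"""Morlet time-frequency transformation, segment concatenation, and ERSP maps.

After CSP filtering each trial is a 2M x T component matrix. Every
component is convolved with a bank of complex Morlet wavelets on a linear
frequency grid (default 8-32 Hz in 32 points, a step of about 0.8 Hz) and
the squared magnitude is kept, giving a 2M x J x T power tensor. The 2M
per-component maps are then concatenated along time into a single
J x T_w matrix with T_w = 2M * T — at the default M=4 and a 2.5 s window
this is the 20 s concatenated representation the correlation templates
operate on.

ERSP (event-related spectral perturbation) maps are the diagnostic view:
power relative to a pre-cue baseline in dB, negative = ERD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from tcsp.io import EpochSet

__all__ = ["TFRGrid", "ConcatenatedTFR", "make_grid", "morlet_kernel",
           "morlet_tfr", "concatenate_tfr", "ersp"]

#: default wavelet width (cycles); sigma_t = n_cycles / (2 pi f)
DEFAULT_N_CYCLES = 7.0


@dataclass(frozen=True)
class TFRGrid:
    """Linearly spaced analysis frequencies over a band."""

    freqs: np.ndarray
    band: tuple[float, float]

    @property
    def n_points(self) -> int:
        return len(self.freqs)

    @property
    def step(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def nearest(self, freq: float) -> int:
        """Index of the grid point closest to ``freq``."""
        return int(np.argmin(np.abs(self.freqs - freq)))


@dataclass
class ConcatenatedTFR:
    """Per-trial concatenated time-frequency power matrix H (J x T_w)."""

    power: np.ndarray          # (J, 2M*T) or (I, J, 2M*T) for a batch
    grid: TFRGrid
    segment_len: int           # T
    n_segments: int            # 2M

    @property
    def t_w(self) -> int:
        return self.segment_len * self.n_segments

    def segments(self) -> np.ndarray:
        """Undo the concatenation: power reshaped back to (..., 2M, J, T)."""
        p = self.power
        j = p.shape[-2]
        parts = p.reshape(*p.shape[:-1], self.n_segments, self.segment_len)
        return np.moveaxis(parts, -2, -3).reshape(
            *p.shape[:-2], self.n_segments, j, self.segment_len
        )


def make_grid(band=(8.0, 32.0), n_points: int = 32) -> TFRGrid:
    """Linear frequency grid, endpoints inclusive.

    The defaults span 8-32 Hz in 32 points (step 24/31 ≈ 0.774 Hz).
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"band {band} must satisfy 0 < low < high")
    if n_points < 2:
        raise ValueError("a grid needs at least 2 points")
    return TFRGrid(freqs=np.linspace(low, high, n_points), band=(low, high))


def morlet_kernel(freq: float, rate: float,
                  n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at ±5 sigma_t."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return kernel / np.linalg.norm(kernel)


def morlet_tfr(z: np.ndarray, rate: float, grid: TFRGrid,
               n_cycles: float = DEFAULT_N_CYCLES,
               output: str = "power") -> np.ndarray:
    """Morlet transform of component time courses.

    Parameters
    ----------
    z : ndarray (..., T)
        Component matrix; any leading shape (components, or trials x
        components) is preserved.
    output : {"power", "amplitude"}
        Squared magnitude (default; ERD is a power phenomenon) or
        magnitude of the complex coefficients.

    Returns the (..., J, T) tensor. Edges are handled by reflection
    padding so the output has the same length as the input.
    """
    z = np.asarray(z, dtype=float)
    if np.any(grid.freqs >= rate / 2):
        raise ValueError(f"grid reaches {grid.freqs.max()} Hz >= Nyquist {rate / 2}")
    if output not in ("power", "amplitude"):
        raise ValueError(f"unknown output {output!r}")
    lead = z.shape[:-1]
    t_len = z.shape[-1]
    flat = z.reshape(-1, t_len)

    out = np.empty((flat.shape[0], grid.n_points, t_len))
    for j, f in enumerate(grid.freqs):
        kernel = morlet_kernel(f, rate, n_cycles)
        pad = len(kernel) // 2
        padded = np.pad(flat, [(0, 0), (pad, pad)], mode="reflect")
        conv = fftconvolve(padded, kernel[None, :], mode="same", axes=1)
        mag2 = conv.real ** 2 + conv.imag ** 2
        out[:, j, :] = mag2[:, pad:pad + t_len]
    if output == "amplitude":
        out = np.sqrt(out)
    return out.reshape(*lead, grid.n_points, t_len)


def concatenate_tfr(g: np.ndarray, grid: TFRGrid) -> ConcatenatedTFR:
    """Concatenate per-component maps along time: H[j, (m-1)T + t] = G[m, j, t].

    Accepts a single trial (2M, J, T) or a batch (I, 2M, J, T); segment
    order follows the component row order (first M, then last M CSP
    components).
    """
    g = np.asarray(g)
    if g.ndim not in (3, 4):
        raise ValueError("expected (2M, J, T) or (I, 2M, J, T)")
    n_seg, j, t = g.shape[-3], g.shape[-2], g.shape[-1]
    h = np.moveaxis(g, -3, -2).reshape(*g.shape[:-3], j, n_seg * t)
    return ConcatenatedTFR(power=h, grid=grid, segment_len=t, n_segments=n_seg)


def ersp(epochs: EpochSet, channel, grid: TFRGrid, baseline: tuple[float, float],
         channel_labels: list[str] | None = None,
         n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Trial-averaged ERSP map (J x T) for one channel, in dB.

    Per trial and frequency, power is divided by its mean over the
    baseline window (seconds relative to cue) and converted to
    10*log10; maps are then averaged across trials. Negative values are
    ERD, positive ERS.
    """
    if isinstance(channel, str):
        if channel_labels is None:
            raise ValueError("channel_labels required to resolve a channel name")
        channel = channel_labels.index(channel)
    b0 = int(round((baseline[0] - epochs.window_start) * epochs.rate))
    b1 = int(round((baseline[1] - epochs.window_start) * epochs.rate))
    if not (0 <= b0 < b1 <= epochs.n_samples):
        raise ValueError(f"baseline {baseline} outside the epoch window")

    power = morlet_tfr(epochs.data[:, channel, :], epochs.rate, grid,
                       n_cycles=n_cycles)              # (I, J, T)
    base = power[:, :, b0:b1].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power is zero for some trial/frequency")
    return (10 * np.log10(power / base)).mean(axis=0)
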