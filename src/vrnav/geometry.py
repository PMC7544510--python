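"""Circular track geometry and circular-smoothing primitives.

The virtual environment is a closed loop built from two identical 200-cm
semicircular corridors.  Most analyses pool the two corridors and work on
the 200-cm "main track" coordinate, so positions, profile offsets and
decoding errors all live on a circle and every distance is a circular
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d


@dataclass(frozen=True)
class TrackGeometry:
    """Geometry of one semicircular corridor (the analysis coordinate)."""

    corridor_length: float = 200.0
    landmarks: tuple[float, ...] = (0.0, 83.0, 117.0)
    reward_center: float = 0.0
    reward_halfwidth: float = 12.0

    def __post_init__(self) -> None:
        if self.corridor_length <= 0:
            raise ValueError("corridor_length must be positive")
        for lm in self.landmarks:
            if not (0 <= lm < self.corridor_length):
                raise ValueError("landmarks must lie in [0, corridor_length)")


def circular_distance(a, b, length: float):
    """Signed circular displacement from ``b`` to ``a`` in ``(-L/2, L/2]``.

    Positive values mean ``a`` is ahead of ``b`` in the running direction.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % length
    d = np.where(d > length / 2, d - length, d)
    # map the boundary -L/2 onto +L/2 so the interval is half-open
    d = np.where(d == -length / 2, length / 2, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def physical_lap_distance(corridor_length: float, gain: float) -> float:
    """Wheel distance the animal must run to cover one 200-cm lap.

    The gain couples wheel displacement to virtual displacement
    (dx_virtual = gain * dx_wheel), so a full lap costs L / gain of
    physical running: 250 cm at gain 0.8, 166.7 cm at gain 1.2.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    return corridor_length / gain


def smooth_circular(values: np.ndarray, sd_bins: float, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing with wrap-around (circular) boundary.

    Sum-preserving, so smoothed spike-count maps keep the total count.
    ``sd_bins <= 0`` returns the input unchanged.
    """
    values = np.asarray(values, dtype=float)
    if sd_bins <= 0:
        return values.copy()
    return gaussian_filter1d(values, sd_bins, axis=axis, mode="wrap")


def smooth_circular_2d(values: np.ndarray, sd_bins: tuple[float, float]) -> np.ndarray:
    """2-D circular Gaussian smoothing (both axes wrap)."""
    values = np.asarray(values, dtype=float)
    if sd_bins[0] <= 0 and sd_bins[1] <= 0:
        return values.copy()
    return gaussian_filter(values, sigma=sd_bins, mode="wrap")


def bin_edges(length: float, bin_width: float) -> np.ndarray:
    n = int(round(length / bin_width))
    if abs(n * bin_width - length) > 1e-9:
        raise ValueError("bin width must tile the track length exactly")
    return np.linspace(0.0, length, n + 1)


def bin_centers(length: float, bin_width: float) -> np.ndarray:
    edges = bin_edges(length, bin_width)
    return 0.5 * (edges[:-1] + edges[1:])


def position_to_bin(position: np.ndarray, length: float, bin_width: float) -> np.ndarray:
    """Integer bin index of each position on the circular track."""
    n = int(round(length / bin_width))
    idx = np.floor((np.asarray(position, dtype=float) % length) / bin_width).astype(int)
    return np.clip(idx, 0, n - 1)


def offsets_cm(n_bins: int, bin_width: float) -> np.ndarray:
    """Signed circular offsets (cm) corresponding to bin shifts 0..n-1.

    Offset k > n/2 is reported as k - n bins, giving values in (-L/2, L/2].
    """
    k = np.arange(n_bins)
    k = np.where(k > n_bins / 2, k - n_bins, k)
    return k * bin_width


def circular_xcorr(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Circular cross-correlation c[k] = sum_i a[i] * b[i-k] via FFT.

    c[k] is large when shifting ``b`` forward by ``k`` bins aligns it with
    ``a``.  Inputs are used as given (z-score beforehand to get Pearson
    correlations).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[axis]
    fa = np.fft.rfft(a, axis=axis)
    fb = np.fft.rfft(b, axis=axis)
    return np.fft.irfft(fa * np.conj(fb), n=n, axis=axis)


def refine_circular_peak(corr: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Sub-bin offset of a correlation peak by parabolic interpolation.

    ``corr`` is (..., n) over circular lags and ``best`` the integer
    argmax per row; returns a fractional correction in (-0.5, 0.5).  A
    continuous peak estimate avoids the heavy ties a bin-quantized
    argmax produces (which would make permutation tests on the shift
    statistic conservative) and sharpens shift recovery below the bin
    width.
    """
    corr = np.atleast_2d(corr)
    best = np.atleast_1d(best)
    n = corr.shape[-1]
    rows = np.arange(len(best))
    c0 = corr[rows, best]
    cm = corr[rows, (best - 1) % n]
    cp = corr[rows, (best + 1) % n]
    denom = cm - 2 * c0 + cp
    delta = np.where(np.abs(denom) > 1e-15, 0.5 * (cm - cp) / denom, 0.0)
    return np.clip(delta, -0.5, 0.5)


def zscore_profile(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score along ``axis``; constant rows come back as all zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out
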