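"""Theta-phase extraction and phase-resolved firing statistics.

Phase is defined by the peaks of the 6-9 Hz band-passed LFP: each
retained peak marks 0/360 degrees and phase advances linearly between
consecutive peaks (peaks following the previous one by less than 60 ms
are discarded).  A single per-session offset re-centers phase so that the
pooled firing rate of CA1 pyramidal neurons peaks at 180 degrees.

Phase-resolved statistics follow the same count/occupancy logic as the
spatial profiles: 20-degree bins, 40-degree s.d. circular smoothing, and
the theta modulation index (F_max - F_min) / F_mean.  Phase precession is
quantified from the phase x position profile: the spatial
cross-correlogram of each phase row against the phase-averaged profile
yields a drift curve (cm of forward shift per phase bin) which is fitted
with a sinusoid; drift > 0 means the field sits ahead of its average
position, and the reported phase offset is the behind-to-ahead zero
crossing of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .geometry import (
    circular_xcorr,
    offsets_cm,
    position_to_bin,
    smooth_circular,
    smooth_circular_2d,
    zscore_profile,
)
from .session import SessionTimeline
from .profiles import spikes_per_sample, _random_shifts

PHASE_BIN_DEG = 20.0
PHASE_SMOOTH_SD_DEG = 40.0
MIN_CYCLE_S = 0.06


@dataclass
class ThetaPhaseSeries:
    """Instantaneous theta phase per timeline sample."""

    phase: np.ndarray  # deg in [0, 360); meaningful only where valid
    cycle_id: np.ndarray  # integer cycle index, -1 outside valid range
    valid: np.ndarray  # False before the first / after the last peak
    offset_deg: float = 0.0  # centering rotation already applied

    def with_offset(self, offset_deg: float) -> "ThetaPhaseSeries":
        return ThetaPhaseSeries(
            phase=(self.phase + offset_deg) % 360.0,
            cycle_id=self.cycle_id,
            valid=self.valid,
            offset_deg=self.offset_deg + offset_deg,
        )

    @property
    def unwrapped(self) -> np.ndarray:
        """Monotone phase (deg), unwrapped across the 360 boundary."""
        return np.unwrap(self.phase, period=360.0)

    def phase_at(self, sample_coord: np.ndarray) -> np.ndarray:
        """Phase (deg) at fractional sample coordinates.

        Theta advances 40-60 degrees per 60-Hz sample, so binning events
        by the phase of their containing sample is both biased (half a
        sample, about 24 degrees) and aliased (cycles span only 6-9
        samples).  Linear interpolation of the unwrapped phase at the
        exact event time avoids both.
        """
        n = len(self.phase)
        return np.interp(sample_coord, np.arange(n), self.unwrapped) % 360.0

    @property
    def phase_mid(self) -> np.ndarray:
        """Phase at sample centers (continuous events within a sample)."""
        d = np.diff(self.phase) % 360.0
        d = np.append(d, d[-1] if len(d) else 0.0)
        return (self.phase + 0.5 * d) % 360.0


@dataclass
class ThetaProfile:
    """Firing rate over theta-phase bins plus the modulation index."""

    bin_centers_deg: np.ndarray
    rate: np.ndarray
    f_max: float
    f_min: float
    f_mean: float
    index: float
    preferred_phase_deg: float


@dataclass
class PhasePositionProfile:
    """2-D firing rate over (theta phase x position) and its drift curve."""

    phase_centers_deg: np.ndarray
    position_centers_cm: np.ndarray
    rate: np.ndarray  # (n_phase, n_pos)
    drift_cm: np.ndarray  # per phase bin, in (-L/2, L/2]
    amplitude_cm: float
    offset_deg: float


# ---------------------------------------------------------------------------
# phase extraction


def extract_theta_phase(
    lfp: np.ndarray,
    fs: float,
    band: tuple[float, float] = (6.0, 9.0),
    min_cycle_s: float = MIN_CYCLE_S,
    peak_prominence_sd: float = 0.5,
    population_spike_times: list[np.ndarray] | None = None,
    timeline: SessionTimeline | None = None,
) -> ThetaPhaseSeries:
    """Theta phase from LFP peaks, linearly interpolated between peaks.

    If ``population_spike_times`` (the CA1 pyramidal units) and the
    timeline are given, the phase is re-centered so the pooled population
    rate peaks at 180 degrees.
    """
    lfp = np.asarray(lfp, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate must exceed twice the band top")
    if len(lfp) < 10 * fs / band[0]:
        raise ValueError("LFP shorter than ten theta cycles")
    sos = butter(3, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, lfp)
    peaks, _ = find_peaks(filtered, prominence=peak_prominence_sd * filtered.std())
    if len(peaks) < 2:
        raise ValueError("no theta peaks detected")
    # discard peaks arriving sooner than the refractory interval
    retained = [peaks[0]]
    min_gap = min_cycle_s * fs
    for p in peaks[1:]:
        if p - retained[-1] >= min_gap:
            retained.append(p)
    retained = np.asarray(retained)

    n = len(lfp)
    samples = np.arange(n)
    unwrapped = np.interp(samples, retained, np.arange(len(retained)) * 360.0)
    phase = unwrapped % 360.0
    valid = (samples >= retained[0]) & (samples < retained[-1])
    cycle_id = np.searchsorted(retained, samples, side="right") - 1
    cycle_id[~valid] = -1
    series = ThetaPhaseSeries(phase=phase, cycle_id=cycle_id, valid=valid)
    if population_spike_times is not None and timeline is not None:
        series = center_theta_phase(series, population_spike_times, timeline)
    return series


def center_theta_phase(
    theta: ThetaPhaseSeries,
    population_spike_times: list[np.ndarray],
    timeline: SessionTimeline,
    target_deg: float = 180.0,
) -> ThetaPhaseSeries:
    """Rotate phase so the pooled population rate peaks at ``target_deg``."""
    pooled = np.concatenate([np.asarray(t, dtype=float) for t in population_spike_times])
    profile = theta_rate_profile(pooled, timeline, theta)
    return theta.with_offset(target_deg - profile.preferred_phase_deg)


def _spike_sample_coords(spike_times: np.ndarray, timeline: SessionTimeline) -> np.ndarray:
    u = (np.asarray(spike_times, dtype=float) - timeline.time[0]) * timeline.sample_rate
    return np.clip(u, 0.0, timeline.n_samples - 1 - 1e-9)


def spike_phases(
    spike_times: np.ndarray, timeline: SessionTimeline, theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Theta phase (deg) of each spike falling in valid (and masked) samples.

    Phases are interpolated at the exact spike times.
    """
    u = _spike_sample_coords(spike_times, timeline)
    idx = np.floor(u).astype(int)
    keep = theta.valid[idx]
    if mask is not None:
        keep &= mask[idx]
    return theta.phase_at(u[keep])


# ---------------------------------------------------------------------------
# phase-resolved rate and modulation index


def phase_occupancy(
    theta: ThetaPhaseSeries,
    ok: np.ndarray,
    dt: float,
    n_bins: int,
    upsample: int = 8,
) -> np.ndarray:
    """Seconds spent per phase bin, integrated within samples.

    Each selected sample is split into ``upsample`` sub-intervals with
    linearly interpolated phase; this matters because theta sweeps 40-60
    degrees per 60-Hz sample, so whole-sample binning aliases badly
    against 20-degree bins.
    """
    unw = theta.unwrapped
    step = np.diff(unw)
    step = np.append(step, step[-1] if len(step) else 0.0)
    sel = np.flatnonzero(ok)
    frac = (np.arange(upsample) + 0.5) / upsample
    sub = (unw[sel, None] + step[sel, None] * frac[None, :]) % 360.0
    pb = np.clip((sub / (360.0 / n_bins)).astype(int), 0, n_bins - 1)
    return np.bincount(pb.ravel(), minlength=n_bins) * (dt / upsample)


def theta_rate_profile(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
    bin_deg: float = PHASE_BIN_DEG,
    smooth_sd_deg: float = PHASE_SMOOTH_SD_DEG,
) -> ThetaProfile:
    """Firing rate across theta phases and the modulation index.

    The displayed rate curve (and the preferred phase) use the smoothed
    maps.  The modulation index (F_max - F_min) / F_mean is computed
    from the unsmoothed binned rates, because circular smoothing
    attenuates the first harmonic by a known factor (about 0.78 at
    40 deg s.d.) and would bias the index away from its analytic value
    2m for a sinusoidally modulated rate — breaking its companion
    relation PPC ~ (index / 4)^2.  The extreme bins are picked by
    split-half cross-validation (argmax/argmin on the interleaved half
    of the spikes, rate read from the other half, symmetrized), which
    removes the upward selection bias a noisy max-minus-min carries.
    """
    n_bins = int(round(360.0 / bin_deg))
    ok = theta.valid if mask is None else (theta.valid & mask)
    phases = spike_phases(spike_times, timeline, theta, mask)
    pb = np.clip((phases / bin_deg).astype(int), 0, n_bins - 1)
    counts = np.bincount(pb, minlength=n_bins).astype(float)
    occ = phase_occupancy(theta, ok, timeline.dt, n_bins)
    if not occ.any():
        raise ValueError("no occupancy in any phase bin")
    sd_bins = smooth_sd_deg / bin_deg
    sc = smooth_circular(counts, sd_bins)
    so = smooth_circular(occ, sd_bins)
    rate = np.zeros_like(sc)
    np.divide(sc, so, out=rate, where=so > 0)
    raw = np.zeros_like(counts)
    np.divide(counts, occ, out=raw, where=occ > 0)
    f_max, f_min, f_mean = float(raw.max()), float(raw.min()), float(raw.mean())
    counts_even = np.bincount(pb[::2], minlength=n_bins).astype(float)
    amp = _cv_peak_trough_amplitude(
        counts_even[None, :], (counts - counts_even)[None, :], occ
    )[0]
    centers = (np.arange(n_bins) + 0.5) * bin_deg
    return ThetaProfile(
        bin_centers_deg=centers,
        rate=rate,
        f_max=float(f_max),
        f_min=float(f_min),
        f_mean=float(f_mean),
        index=float(amp / f_mean) if f_mean > 0 else 0.0,
        preferred_phase_deg=float(centers[np.argmax(rate)]),
    )


def _cv_peak_trough_amplitude(
    counts_a: np.ndarray, counts_b: np.ndarray, occ: np.ndarray
) -> np.ndarray:
    """Cross-validated F_max - F_min per row of stacked count maps.

    The extreme bins are located on one half of the spikes and the rate
    difference is read from the other half (then symmetrized), so the
    noise that picks the extremes never contributes to the value —
    removing the upward bias of a plain max-minus-min on noisy bins.
    Each half is rescaled by its own spike count to estimate the full
    rate.
    """
    ok = occ > 0
    rows = np.arange(len(counts_a))

    def half_rate(c):
        n = c.sum(axis=1, keepdims=True)
        total = (counts_a + counts_b).sum(axis=1, keepdims=True)
        scale = np.where(n > 0, total / np.maximum(n, 1), 0.0)
        r = np.zeros_like(c)
        np.divide(c * scale, occ[None, :], out=r, where=np.broadcast_to(ok, c.shape))
        return r

    ra, rb = half_rate(counts_a), half_rate(counts_b)
    masked_a = np.where(ok[None, :], ra, np.nan)
    masked_b = np.where(ok[None, :], rb, np.nan)
    amp_ab = (
        ra[rows, np.nanargmax(masked_b, axis=1)]
        - ra[rows, np.nanargmin(masked_b, axis=1)]
    )
    amp_ba = (
        rb[rows, np.nanargmax(masked_a, axis=1)]
        - rb[rows, np.nanargmin(masked_a, axis=1)]
    )
    return 0.5 * (amp_ab + amp_ba)


def theta_significance(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
    n_shuffles: int = 500,
    min_shift_s: float = 5.0,
    alpha: float = 0.05,
    bin_deg: float = PHASE_BIN_DEG,
    smooth_sd_deg: float = PHASE_SMOOTH_SD_DEG,
    seed: int | None = None,
):
    """Circular time-shift permutation test of the theta modulation index.

    Returns (p_value, significant, observed index, null indices).
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(round(360.0 / bin_deg))
    st = np.asarray(spike_times, dtype=float)
    if len(st) == 0:
        return 1.0, False, 0.0, np.zeros(n_shuffles)
    ok = theta.valid if mask is None else (theta.valid & mask)
    occ = phase_occupancy(theta, ok, timeline.dt, n_bins)

    def index_of(counts_even: np.ndarray, counts_odd: np.ndarray) -> np.ndarray:
        # cross-validated index, matching theta_rate_profile's definition
        amp = _cv_peak_trough_amplitude(counts_even, counts_odd, occ)
        full = counts_even + counts_odd
        rate = np.zeros_like(full)
        np.divide(full, occ, out=rate, where=np.broadcast_to(occ > 0, full.shape))
        mean = rate.mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = amp / mean
        return np.where(mean > 0, idx, 0.0)

    u = _spike_sample_coords(st, timeline)
    n = timeline.n_samples

    def count_maps(u_spikes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.floor(u_spikes).astype(int)
        keep = ok[idx]
        pb = np.clip((theta.phase_at(u_spikes[keep]) / bin_deg).astype(int), 0, n_bins - 1)
        even = np.bincount(pb[::2], minlength=n_bins).astype(float)
        odd = np.bincount(pb[1::2], minlength=n_bins).astype(float)
        return even, odd

    ce, co = count_maps(u)
    observed = float(index_of(ce[None, :], co[None, :])[0])
    shifts = _random_shifts(n_shuffles, n, timeline.sample_rate, min_shift_s, rng)
    null_even = np.empty((n_shuffles, n_bins))
    null_odd = np.empty((n_shuffles, n_bins))
    for k, s in enumerate(shifts):
        null_even[k], null_odd[k] = count_maps((u + s) % n)
    null = index_of(null_even, null_odd)
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(p), bool(significant), observed, null


def ppc(phases_deg: np.ndarray) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise phase gaps.

    Computed in O(N) through the resultant-length identity
    (|sum exp(i theta)|^2 - N) / (N (N - 1)), which equals the average of
    cos(theta_i - theta_j) over all ordered pairs i < j.
    """
    phases = np.deg2rad(np.asarray(phases_deg, dtype=float))
    n = len(phases)
    if n < 2:
        raise ValueError("PPC requires at least two spikes")
    c, s = np.cos(phases).sum(), np.sin(phases).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


# ---------------------------------------------------------------------------
# phase x position profiles and precession


def _sinusoid_design(phase_centers_deg: np.ndarray) -> np.ndarray:
    th = np.deg2rad(phase_centers_deg)
    return np.column_stack([np.sin(th), np.cos(th), np.ones_like(th)])


def fit_drift_sinusoid(
    drift_cm: np.ndarray, phase_centers_deg: np.ndarray | None = None
) -> tuple[float, float]:
    """Least-squares fit of a * sin(theta - phi) + c to a drift curve.

    Returns (amplitude, offset_deg).  The offset is the zero crossing
    where the fitted drift goes from negative (field behind) to positive
    (field ahead); for an injected drift A*sin(theta - theta0) it equals
    theta0.  A constant curve returns amplitude 0 and offset nan.
    """
    drift = np.asarray(drift_cm, dtype=float)
    if phase_centers_deg is None:
        phase_centers_deg = (np.arange(len(drift)) + 0.5) * 360.0 / len(drift)
    if len(drift) < 4:
        raise ValueError("need at least four phase bins")
    if np.ptp(drift) == 0:
        return 0.0, float("nan")
    X = _sinusoid_design(phase_centers_deg)
    beta, *_ = np.linalg.lstsq(X, drift, rcond=None)
    p, q, _ = beta
    amplitude = float(np.hypot(p, q))
    offset = float(np.rad2deg(np.arctan2(-q, p)) % 360.0)
    return amplitude, offset


def phase_position_profile(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
    bin_deg: float = PHASE_BIN_DEG,
    bin_cm: float = 2.0,
    smooth_sd_deg: float = PHASE_SMOOTH_SD_DEG,
    smooth_sd_cm: float = 8.0,
) -> PhasePositionProfile:
    """2-D (phase x position) rate map with its spatial drift curve."""
    L = timeline.geometry.corridor_length
    n_phase = int(round(360.0 / bin_deg))
    n_pos = int(round(L / bin_cm))
    ok = theta.valid if mask is None else (theta.valid & mask)
    posbin = position_to_bin(timeline.position, L, bin_cm)
    u = _spike_sample_coords(spike_times, timeline)
    idx = np.floor(u).astype(int)
    keep = ok[idx]
    spk_phase = np.clip(
        (theta.phase_at(u[keep]) / bin_deg).astype(int), 0, n_phase - 1
    )
    spk_pos = posbin[idx[keep]]
    counts = np.bincount(
        spk_phase * n_pos + spk_pos, minlength=n_phase * n_pos
    ).astype(float).reshape(n_phase, n_pos)
    occ = _phase_position_occupancy(theta, ok, posbin, timeline.dt, n_phase, n_pos)
    sd = (smooth_sd_deg / bin_deg, smooth_sd_cm / bin_cm)
    sc = smooth_circular_2d(counts, sd)
    so = smooth_circular_2d(occ, sd)
    rate = np.zeros_like(sc)
    np.divide(sc, so, out=rate, where=so > 0)

    # the drift curve comes from maps smoothed only along position:
    # smoothing across phase would shrink the measured drift amplitude by
    # a known harmonic factor and bias the recovered precession
    sc_u = smooth_circular_2d(counts, (0.0, sd[1]))
    so_u = smooth_circular_2d(occ, (0.0, sd[1]))
    rate_u = np.zeros_like(sc_u)
    np.divide(sc_u, so_u, out=rate_u, where=so_u > 0)
    drift = _drift_curve(rate_u, bin_cm)
    amplitude, offset = fit_drift_sinusoid(drift, (np.arange(n_phase) + 0.5) * bin_deg)
    return PhasePositionProfile(
        phase_centers_deg=(np.arange(n_phase) + 0.5) * bin_deg,
        position_centers_cm=(np.arange(n_pos) + 0.5) * bin_cm,
        rate=rate,
        drift_cm=drift,
        amplitude_cm=amplitude,
        offset_deg=offset,
    )


def _phase_position_occupancy(
    theta: ThetaPhaseSeries,
    ok: np.ndarray,
    posbin: np.ndarray,
    dt: float,
    n_phase: int,
    n_pos: int,
    upsample: int = 8,
) -> np.ndarray:
    """(phase x position) occupancy in seconds, phase integrated within
    samples as in :func:`phase_occupancy` (position is constant within a
    sample at these speeds)."""
    unw = theta.unwrapped
    step = np.diff(unw)
    step = np.append(step, step[-1] if len(step) else 0.0)
    sel = np.flatnonzero(ok)
    frac = (np.arange(upsample) + 0.5) / upsample
    sub = (unw[sel, None] + step[sel, None] * frac[None, :]) % 360.0
    pb = np.clip((sub / (360.0 / n_phase)).astype(int), 0, n_phase - 1)
    flat = pb * n_pos + posbin[sel][:, None]
    occ = np.bincount(flat.ravel(), minlength=n_phase * n_pos) * (dt / upsample)
    return occ.reshape(n_phase, n_pos)


def _drift_curve(rate2d: np.ndarray, bin_cm: float) -> np.ndarray:
    """Argmax of the spatial cross-correlogram of each phase row against
    the phase-averaged profile, as signed circular displacement in cm."""
    mean_profile = rate2d.mean(axis=0)
    a = zscore_profile(rate2d, axis=-1)
    b = zscore_profile(mean_profile)
    n = rate2d.shape[-1]
    corr = circular_xcorr(a, b[None, :]) / n
    cm = offsets_cm(n, bin_cm)
    order = np.lexsort((cm, np.abs(cm)))
    best = order[np.argmax(corr[:, order], axis=-1)]
    from .geometry import circular_distance, refine_circular_peak

    delta = refine_circular_peak(corr, best)
    return circular_distance(cm[best] + delta * bin_cm, 0.0, n * bin_cm)


def precession_significance(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    bin_deg: float = PHASE_BIN_DEG,
    bin_cm: float = 2.0,
    smooth_sd_cm: float = 8.0,
    seed: int | None = None,
):
    """Spike-phase permutation test of the drift amplitude.

    The statistic is the sinusoid amplitude of the drift curve computed
    from maps smoothed only along the spatial dimension (no phase
    smoothing), so drift cannot be an artifact of phase smoothing.  The
    null permutes the theta phases of the spikes.

    Returns (p_value, significant, observed amplitude, null amplitudes).
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    L = timeline.geometry.corridor_length
    n_phase = int(round(360.0 / bin_deg))
    n_pos = int(round(L / bin_cm))
    ok = theta.valid if mask is None else (theta.valid & mask)
    posbin = position_to_bin(timeline.position, L, bin_cm)

    u = _spike_sample_coords(np.asarray(spike_times, dtype=float), timeline)
    idx = np.floor(u).astype(int)
    keep = ok[idx]
    n_spk = int(keep.sum())
    if n_spk < 2:
        return 1.0, False, 0.0, np.zeros(n_shuffles)
    spk_phase = np.clip(
        (theta.phase_at(u[keep]) / bin_deg).astype(int), 0, n_phase - 1
    )
    spk_pos = posbin[idx[keep]]
    if len(np.unique(spk_phase)) < 2:
        return 1.0, False, 0.0, np.zeros(n_shuffles)

    occ = _phase_position_occupancy(theta, ok, posbin, timeline.dt, n_phase, n_pos)
    sd = (0.0, smooth_sd_cm / bin_cm)
    so = smooth_circular_2d(occ, sd)
    phase_centers = (np.arange(n_phase) + 0.5) * bin_deg
    X = _sinusoid_design(phase_centers)
    pinv = np.linalg.pinv(X)

    def amplitudes(phase_of_spikes: np.ndarray) -> np.ndarray:
        """phase_of_spikes: (n_reps, n_spk) -> drift amplitude per rep."""
        n_reps = phase_of_spikes.shape[0]
        flat = (
            np.arange(n_reps)[:, None] * (n_phase * n_pos)
            + phase_of_spikes * n_pos
            + spk_pos[None, :]
        )
        counts = np.bincount(flat.ravel(), minlength=n_reps * n_phase * n_pos)
        counts = counts.reshape(n_reps, n_phase, n_pos).astype(float)
        sc = smooth_circular(counts, sd[1], axis=-1)
        rate = np.zeros_like(sc)
        np.divide(sc, so[None, :, :], out=rate, where=np.broadcast_to(so > 0, sc.shape))
        amps = np.empty(n_reps)
        for r in range(n_reps):
            drift = _drift_curve(rate[r], bin_cm)
            p, q, _ = pinv @ drift
            amps[r] = np.hypot(p, q)
        return amps

    observed = float(amplitudes(spk_phase[None, :])[0])
    perm = np.stack([rng.permutation(spk_phase) for _ in range(n_shuffles)])
    null = amplitudes(perm)
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(p), bool(significant), observed, null


# ---------------------------------------------------------------------------
# population-level tests


def layer_fraction_test(
    flags: np.ndarray,
    depths_um: np.ndarray,
    animal_ids: np.ndarray,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise test of significant-neuron fractions across cortical layers.

    The null permutes recording depths within each animal, guarding
    against between-animal sampling biases.
    """
    from .session import assign_layer

    flags = np.asarray(flags, dtype=bool)
    depths = np.asarray(depths_um, dtype=float)
    animals = np.asarray(animal_ids)
    rng = np.random.default_rng(seed)

    def layer_fractions(d: np.ndarray) -> dict[str, float]:
        layers = np.array([assign_layer(x) for x in d])
        return {
            lay: flags[layers == lay].mean()
            for lay in ("L2-4", "L5", "L6")
            if np.any(layers == lay)
        }

    obs = layer_fractions(depths)
    if len(obs) < 2:
        raise ValueError("need neurons in at least two layers")
    pairs = [(a, b) for i, a in enumerate(obs) for b in list(obs)[i + 1 :]]
    null = {pair: np.empty(n_shuffles) for pair in pairs}
    for k in range(n_shuffles):
        d = depths.copy()
        for an in np.unique(animals):
            sel = animals == an
            d[sel] = rng.permutation(d[sel])
        fr = layer_fractions(d)
        for a, b in pairs:
            null[(a, b)][k] = abs(fr.get(a, np.nan) - fr.get(b, np.nan))
    rows = []
    for a, b in pairs:
        observed = abs(obs[a] - obs[b])
        nl = null[(a, b)][~np.isnan(null[(a, b)])]
        p = (1 + np.sum(nl >= observed)) / (len(nl) + 1)
        rows.append((a, b, obs[a], obs[b], observed, float(p), bool(p <= alpha)))
    return pd.DataFrame(
        rows, columns=["layer_a", "layer_b", "frac_a", "frac_b", "diff", "p", "significant"]
    )


def circular_median(phases_deg: np.ndarray) -> float:
    """Circular median: the sample angle minimizing mean circular deviation."""
    th = np.deg2rad(np.asarray(phases_deg, dtype=float) % 360.0)
    dev = np.pi - np.abs(np.pi - np.abs(th[:, None] - th[None, :]))
    return float(np.rad2deg(th[np.argmin(dev.mean(axis=1))]))


def _median_test_statistic(groups: list[np.ndarray]) -> float:
    """Count-based multi-sample equal-circular-medians statistic.

    Counts, per group, how many observations fall in the half circle
    starting at the pooled circular median; large imbalance across groups
    yields a large statistic (chi-square-like form).
    """
    pooled = np.concatenate(groups)
    med = circular_median(pooled)
    N = len(pooled)
    m = np.array([np.sum(((g - med) % 360.0) < 180.0) for g in groups], dtype=float)
    n = np.array([len(g) for g in groups], dtype=float)
    M = m.sum()
    if M == 0 or M == N:
        return 0.0
    return float(N**2 / (M * (N - M)) * np.sum(m**2 / n) - N * M / (N - M))


def circular_median_test(
    groups: list[np.ndarray],
    n_shuffles: int = 500,
    seed: int | None = None,
) -> tuple[float, float]:
    """Multi-sample test for equal circular medians (permutation p-value).

    The statistic follows the count-based construction; the p-value comes
    from shuffling group labels, so its asymptotic normalization is not
    relied upon.  Returns (statistic, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 5 for g in groups):
        raise ValueError("need >= 2 groups with >= 5 observations each")
    rng = np.random.default_rng(seed)
    observed = _median_test_statistic(groups)
    pooled = np.concatenate(groups)
    sizes = np.cumsum([len(g) for g in groups])[:-1]
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = _median_test_statistic(np.split(rng.permutation(pooled), sizes))
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    return float(observed), float(p)


def linear_circular_correlation(
    phases_deg: np.ndarray,
    positions_cm: np.ndarray,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
):
    """Circular-linear correlation between spike phase and in-field position.

    Coefficient from the standard circular-linear formula; significance
    from a spike-phase permutation null (same null as the drift test).
    Returns (r, p, significant).
    """
    import pingouin as pg

    phases = np.asarray(phases_deg, dtype=float)
    x = np.asarray(positions_cm, dtype=float)
    if len(phases) < 10:
        raise ValueError("need at least 10 spikes in the field")
    if np.ptp(x) == 0 or np.ptp(phases) == 0:
        raise ValueError("degenerate spread in positions or phases")
    rng = np.random.default_rng(seed)
    r, _ = pg.circ_corrcl(np.deg2rad(phases), x)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        rn, _ = pg.circ_corrcl(np.deg2rad(rng.permutation(phases)), x)
        null[k] = abs(rn)
    p = (1 + np.sum(null >= abs(r))) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(r), float(p), bool(significant)


def rayleigh_test(phases_deg: np.ndarray) -> float:
    """Rayleigh test of circular uniformity; p = 1 for a single phase."""
    import pingouin as pg

    phases = np.asarray(phases_deg, dtype=float)
    if len(phases) < 1:
        raise ValueError("need at least one phase")
    if len(phases) == 1:
        return 1.0
    _, p = pg.circ_rayleigh(np.deg2rad(phases))
    return float(p)


def field_extent_mask(profile_rate: np.ndarray, threshold_frac: float = 0.5) -> np.ndarray:
    """Contiguous circular region around the peak above a rate threshold.

    Used to select in-field spikes for the linear-circular comparison;
    the field is the run of bins >= threshold_frac * peak containing the
    peak (wrapping around the track edge).
    """
    rate = np.asarray(profile_rate, dtype=float)
    n = len(rate)
    peak = int(np.argmax(rate))
    thr = threshold_frac * rate[peak]
    mask = np.zeros(n, dtype=bool)
    mask[peak] = True
    i = peak
    while rate[(i - 1) % n] >= thr and not mask[(i - 1) % n]:
        i -= 1
        mask[i % n] = True
    j = peak
    while rate[(j + 1) % n] >= thr and not mask[(j + 1) % n]:
        j += 1
        mask[j % n] = True
    return mask
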