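"""Spatial response profiles, permutation tests, and gain-shift estimation.

The spatial response profile of a neuron is the ratio of its circularly
smoothed spike-count map over the circularly smoothed occupancy map
(2-cm bins, 8-cm s.d. Gaussian, both maps smoothed before division).
Significance of spatial tuning uses a circular time-shift null (the spike
train is rotated in time by a random period > 5 s), which preserves the
spike train's autostructure while destroying its relation to position.

The gain shift of a neuron is the circular offset by which its medium-gain
profile must be shifted to best correlate with its low- or high-gain
profile; its null is built by permuting trial gain labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    bin_centers,
    circular_distance,
    circular_xcorr,
    offsets_cm,
    position_to_bin,
    refine_circular_peak,
    smooth_circular,
    zscore_profile,
)
from .session import SessionTimeline

DEFAULT_BIN_CM = 2.0
DEFAULT_SMOOTH_SD_CM = 8.0


@dataclass
class ResponseProfile:
    """Firing rate over circular position bins."""

    bin_centers: np.ndarray  # cm
    rate: np.ndarray  # Hz
    counts: np.ndarray  # smoothed spike counts per bin
    occupancy: np.ndarray  # smoothed seconds per bin
    valid: np.ndarray  # False where smoothed occupancy was zero
    bin_cm: float
    smooth_sd_cm: float
    condition: str | None = None

    @property
    def preferred_position(self) -> float:
        """Position of maximal firing rate (cm)."""
        return float(self.bin_centers[np.argmax(np.where(self.valid, self.rate, -np.inf))])

    @property
    def length(self) -> float:
        return float(self.bin_cm * len(self.bin_centers))


@dataclass
class GainShiftResult:
    """Best circular offset of the medium-gain profile onto a gain profile."""

    shift_cm: float
    correlation: float
    valid: bool
    significant: bool | None = None
    null_95: float | None = None
    p_value: float | None = None
    alpha_scale: float | None = None
    var_explained_static: float | None = None
    var_explained_with_shift: float | None = None


def spikes_per_sample(spike_times: np.ndarray, timeline: SessionTimeline) -> np.ndarray:
    """Spike counts per timeline sample (spikes resampled at 60 Hz)."""
    idx = timeline.sample_of_time(spike_times)
    return np.bincount(idx, minlength=timeline.n_samples)


def _maps(
    posbin: np.ndarray,
    sample_counts: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    dt: float,
):
    """Raw (unsmoothed) spike-count and occupancy maps over masked samples."""
    pb = posbin[mask]
    counts = np.bincount(pb, weights=sample_counts[mask], minlength=n_bins)
    occ = np.bincount(pb, minlength=n_bins) * dt
    return counts, occ


def profile_from_maps(
    counts: np.ndarray,
    occupancy: np.ndarray,
    length: float,
    bin_cm: float,
    smooth_sd_cm: float,
    condition: str | None = None,
) -> ResponseProfile:
    """Smooth count and occupancy maps separately, then divide."""
    sd_bins = smooth_sd_cm / bin_cm
    sc = smooth_circular(counts, sd_bins)
    so = smooth_circular(occupancy, sd_bins)
    valid = so > 0
    rate = np.zeros_like(sc)
    np.divide(sc, so, out=rate, where=valid)
    return ResponseProfile(
        bin_centers=bin_centers(length, bin_cm),
        rate=rate,
        counts=sc,
        occupancy=so,
        valid=valid,
        bin_cm=bin_cm,
        smooth_sd_cm=smooth_sd_cm,
        condition=condition,
    )


def spatial_profile(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    mask: np.ndarray | None = None,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    use_loop: bool = False,
    condition: str | None = None,
) -> ResponseProfile:
    """Occupancy-normalized firing-rate profile on the circular track.

    ``use_loop=True`` computes the profile on the 400-cm two-corridor loop
    instead of the pooled 200-cm main track.
    """
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    if not np.any(mask):
        raise ValueError("mask selects no samples")
    L = timeline.geometry.corridor_length * (2 if use_loop else 1)
    pos = timeline.loop_position if use_loop else timeline.position
    n_bins = int(round(L / bin_cm))
    posbin = position_to_bin(pos, L, bin_cm)
    sample_counts = spikes_per_sample(np.asarray(spike_times, dtype=float), timeline)
    counts, occ = _maps(posbin, sample_counts, mask, n_bins, timeline.dt)
    return profile_from_maps(counts, occ, L, bin_cm, smooth_sd_cm, condition)


# ---------------------------------------------------------------------------
# circular time-shift null


def _random_shifts(
    n_shuffles: int, n_samples: int, sample_rate: float, min_shift_s: float, rng
) -> np.ndarray:
    """Random circular time shifts (in samples), each > min_shift_s from 0."""
    lo = int(np.ceil(min_shift_s * sample_rate))
    hi = n_samples - lo
    if hi <= lo:
        raise ValueError("session too short for the requested minimum time shift")
    return rng.integers(lo, hi, size=n_shuffles)


def _shifted_count_maps(
    posbin: np.ndarray,
    sample_counts: np.ndarray,
    mask: np.ndarray,
    shifts: np.ndarray,
    n_bins: int,
) -> np.ndarray:
    """Spike-count maps after circular time shifts of the spike train.

    Shifting the spike train forward by ``s`` samples means the spikes of
    sample ``i`` land on sample ``i + s`` (mod n); occupancy is unchanged.
    Returns an (n_shuffles, n_bins) array of unsmoothed count maps.
    """
    n = len(posbin)
    spike_samples = np.flatnonzero(sample_counts)
    weights = sample_counts[spike_samples].astype(float)
    maps = np.empty((len(shifts), n_bins))
    for k, s in enumerate(shifts):
        idx = (spike_samples + s) % n
        keep = mask[idx]
        maps[k] = np.bincount(posbin[idx[keep]], weights=weights[keep], minlength=n_bins)
    return maps


def profile_significance(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    mask: np.ndarray | None = None,
    n_shuffles: int = 500,
    min_shift_s: float = 5.0,
    alpha: float = 0.01,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    seed: int | None = None,
):
    """Permutation test of spatial tuning.

    Statistic: maximal amplitude of the profile, max(rate) - mean(rate).
    Significant iff the exact permutation p-value (1 + #{null >= obs}) /
    (n + 1) is at most alpha, which keeps the nominal level at any
    shuffle count.

    Returns (p_value, significant, observed, null) — null is the array of
    shuffled statistics.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    if timeline.duration <= 2 * min_shift_s:
        raise ValueError("session too short for the requested minimum time shift")
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    rng = np.random.default_rng(seed)
    L = timeline.geometry.corridor_length
    n_bins = int(round(L / bin_cm))
    sd_bins = smooth_sd_cm / bin_cm
    posbin = position_to_bin(timeline.position, L, bin_cm)
    sample_counts = spikes_per_sample(np.asarray(spike_times, dtype=float), timeline)
    counts, occ = _maps(posbin, sample_counts, mask, n_bins, timeline.dt)
    so = smooth_circular(occ, sd_bins)
    valid = so > 0

    def stat(count_maps: np.ndarray) -> np.ndarray:
        sc = smooth_circular(count_maps, sd_bins, axis=-1)
        rate = np.zeros_like(sc)
        np.divide(sc, so, out=rate, where=np.broadcast_to(valid, sc.shape))
        r = np.where(valid, rate, np.nan)
        return np.nanmax(r, axis=-1) - np.nanmean(r, axis=-1)

    observed = float(stat(counts[None, :])[0])
    shifts = _random_shifts(n_shuffles, timeline.n_samples, timeline.sample_rate, min_shift_s, rng)
    null = stat(_shifted_count_maps(posbin, sample_counts, mask, shifts, n_bins))
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(p), bool(significant), observed, null


# ---------------------------------------------------------------------------
# gain shift


def estimate_gain_shift(
    profile_gain: ResponseProfile, profile_medium: ResponseProfile
) -> GainShiftResult:
    """Circular offset of the medium profile that best matches the gain one.

    All integer bin offsets are scanned and the correlation between the
    z-scored profiles is maximized; the peak is then refined below the
    bin width by parabolic interpolation.  Exact ties break toward the
    smaller absolute shift, then toward the negative one.  Positive
    shifts mean the gain profile sits ahead of the medium profile.
    """
    if len(profile_gain.rate) != len(profile_medium.rate):
        raise ValueError("profiles must share the same binning")
    a = zscore_profile(profile_gain.rate)
    b = zscore_profile(profile_medium.rate)
    if not a.any() or not b.any():
        return GainShiftResult(shift_cm=0.0, correlation=np.nan, valid=False)
    n = len(a)
    bin_cm = profile_gain.bin_cm
    corr = circular_xcorr(a, b) / n
    cm = offsets_cm(n, bin_cm)
    order = np.lexsort((cm, np.abs(cm)))  # preference: small |shift|, negative first
    best = order[np.argmax(corr[order])]
    delta = refine_circular_peak(corr, np.array([best]))[0]
    shift = circular_distance(cm[best] + delta * bin_cm, 0.0, n * bin_cm)
    return GainShiftResult(shift_cm=float(shift), correlation=float(corr[best]), valid=True)


def per_trial_maps(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    trials: pd.DataFrame,
    mask: np.ndarray | None = None,
    bin_cm: float = DEFAULT_BIN_CM,
):
    """Unsmoothed per-trial spike-count and occupancy maps (trials x bins)."""
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    L = timeline.geometry.corridor_length
    n_bins = int(round(L / bin_cm))
    posbin = position_to_bin(timeline.position, L, bin_cm)
    sample_counts = spikes_per_sample(np.asarray(spike_times, dtype=float), timeline)
    counts = np.zeros((len(trials), n_bins))
    occ = np.zeros((len(trials), n_bins))
    for k, (i0, i1) in enumerate(zip(trials["i_start"], trials["i_end"])):
        m = mask[i0:i1]
        pb = posbin[i0:i1][m]
        counts[k] = np.bincount(pb, weights=sample_counts[i0:i1][m], minlength=n_bins)
        occ[k] = np.bincount(pb, minlength=n_bins) * timeline.dt
    return counts, occ


def _shift_from_maps(
    counts_g, occ_g, counts_m, occ_m, bin_cm, sd_bins
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gain-shift estimate from stacked condition maps.

    Inputs are (n_reps, n_bins); returns (shift_cm, correlation) arrays.
    """
    rate_g = np.zeros_like(counts_g)
    rate_m = np.zeros_like(counts_m)
    sg, og = smooth_circular(counts_g, sd_bins), smooth_circular(occ_g, sd_bins)
    sm, om = smooth_circular(counts_m, sd_bins), smooth_circular(occ_m, sd_bins)
    np.divide(sg, og, out=rate_g, where=og > 0)
    np.divide(sm, om, out=rate_m, where=om > 0)
    a = zscore_profile(rate_g)
    b = zscore_profile(rate_m)
    n = a.shape[-1]
    corr = circular_xcorr(a, b) / n
    cm = offsets_cm(n, bin_cm)
    order = np.lexsort((cm, np.abs(cm)))
    best = order[np.argmax(corr[:, order], axis=-1)]
    delta = refine_circular_peak(corr, best)
    shift = circular_distance(cm[best] + delta * bin_cm, 0.0, n * bin_cm)
    return shift, corr[np.arange(len(corr)), best]


def gain_shift_significance(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    trials: pd.DataFrame,
    gain: float,
    gain_medium: float = 1.0,
    mask: np.ndarray | None = None,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    seed: int | None = None,
) -> GainShiftResult:
    """Gain shift with a trial-label permutation null.

    The gain labels of whole trials are permuted between the two
    conditions; the shift is significant iff its absolute value exceeds
    the (1 - alpha) percentile of the null absolute shifts.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    sel = trials["gain"].isin([gain, gain_medium])
    sub = trials[sel].reset_index(drop=True)
    labels = (sub["gain"] == gain).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("both gain conditions must be present")
    rng = np.random.default_rng(seed)
    counts, occ = per_trial_maps(spike_times, timeline, sub, mask, bin_cm)
    sd_bins = smooth_sd_cm / bin_cm

    def condition_maps(lab_matrix):
        cg = lab_matrix.astype(float) @ counts
        og = lab_matrix.astype(float) @ occ
        cm_ = (~lab_matrix).astype(float) @ counts
        om = (~lab_matrix).astype(float) @ occ
        return cg, og, cm_, om

    obs_shift, obs_corr = _shift_from_maps(
        *condition_maps(labels[None, :]), bin_cm, sd_bins
    )
    perm = np.stack([rng.permutation(labels) for _ in range(n_shuffles)])
    null_shift, _ = _shift_from_maps(*condition_maps(perm), bin_cm, sd_bins)
    null_abs = np.abs(null_shift)
    crit = np.percentile(null_abs, 100 * (1 - alpha))
    p = (1 + np.sum(null_abs >= abs(obs_shift[0]))) / (n_shuffles + 1)
    return GainShiftResult(
        shift_cm=float(obs_shift[0]),
        correlation=float(obs_corr[0]),
        valid=True,
        significant=bool(p <= alpha),  # exact permutation criterion
        null_95=float(crit),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# variance explained (amplitude-scaled residual ratio)


def variance_explained(
    rate_gain: np.ndarray,
    rate_medium: np.ndarray,
    shift_cm: float,
    bin_cm: float = DEFAULT_BIN_CM,
) -> tuple[float, float]:
    """Fraction of profile variance explained by the medium-gain profile.

    The gain profile Rg is fitted as alpha * Rm (alpha by least squares);
    the printed ratio sum((Rg - alpha Rm)^2) / sum((Rg - <Rg>)^2) is a
    residual fraction, so the explained fraction reported here is one
    minus that ratio.  The second value repeats the fit with Rm circularly
    shifted by ``shift_cm``.
    """
    rg = np.asarray(rate_gain, dtype=float)
    rm = np.asarray(rate_medium, dtype=float)
    denom = np.sum((rg - rg.mean()) ** 2)
    if denom == 0:
        raise ValueError("gain profile has zero variance")

    def explained(rm_used: np.ndarray) -> float:
        mm = np.sum(rm_used**2)
        alpha = np.sum(rg * rm_used) / mm if mm > 0 else 0.0
        return 1.0 - np.sum((rg - alpha * rm_used) ** 2) / denom

    static = explained(rm)
    k = int(round(shift_cm / bin_cm))
    with_shift = explained(np.roll(rm, k))
    return float(static), float(with_shift)


# ---------------------------------------------------------------------------
# rate-change and corridor tests


def rate_change_test(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_shuffles: int = 500,
    min_shift_s: float = 5.0,
    alpha: float = 0.01,
    seed: int | None = None,
):
    """Mean-rate difference between two conditions vs a time-shift null.

    Returns (p_value, significant, observed |rate difference| in Hz).
    """
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both conditions must contain samples")
    rng = np.random.default_rng(seed)
    n = timeline.n_samples
    sample_counts = spikes_per_sample(np.asarray(spike_times, dtype=float), timeline)
    t_a, t_b = mask_a.sum() * timeline.dt, mask_b.sum() * timeline.dt

    def stat(counts: np.ndarray) -> float:
        return abs(counts[mask_a].sum() / t_a - counts[mask_b].sum() / t_b)

    observed = stat(sample_counts)
    shifts = _random_shifts(n_shuffles, n, timeline.sample_rate, min_shift_s, rng)
    spike_samples = np.flatnonzero(sample_counts)
    weights = sample_counts[spike_samples].astype(float)
    null = np.empty(n_shuffles)
    for k, s in enumerate(shifts):
        idx = (spike_samples + s) % n
        null[k] = abs(
            weights[mask_a[idx]].sum() / t_a - weights[mask_b[idx]].sum() / t_b
        )
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(p), bool(significant), float(observed)


def corridor_difference_test(
    spike_times: np.ndarray,
    timeline: SessionTimeline,
    trials: pd.DataFrame,
    mask: np.ndarray | None = None,
    n_shuffles: int = 500,
    alpha: float = 0.01,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    seed: int | None = None,
):
    """Do the two semicircular corridors evoke different peak rates?

    Statistic: |rate difference between corridors at the pooled-profile
    peak position| (matching positions 200 cm apart on the loop).  Null:
    per-trial corridor identities shuffled.

    Returns (p_value, significant, observed difference in Hz).
    """
    if trials["corridor_id"].nunique() < 2:
        raise ValueError("both corridor identities must be traversed")
    rng = np.random.default_rng(seed)
    counts, occ = per_trial_maps(spike_times, timeline, trials, mask, bin_cm)
    sd_bins = smooth_sd_cm / bin_cm
    labels = trials["corridor_id"].to_numpy() == 1

    pooled_counts = smooth_circular(counts.sum(0), sd_bins)
    pooled_occ = smooth_circular(occ.sum(0), sd_bins)
    pooled = np.zeros_like(pooled_counts)
    np.divide(pooled_counts, pooled_occ, out=pooled, where=pooled_occ > 0)
    peak = int(np.argmax(pooled))

    def stat(lab_matrix: np.ndarray) -> np.ndarray:
        c1 = smooth_circular(lab_matrix.astype(float) @ counts, sd_bins, axis=-1)
        o1 = smooth_circular(lab_matrix.astype(float) @ occ, sd_bins, axis=-1)
        c0 = smooth_circular((~lab_matrix).astype(float) @ counts, sd_bins, axis=-1)
        o0 = smooth_circular((~lab_matrix).astype(float) @ occ, sd_bins, axis=-1)
        r1 = np.where(o1[:, peak] > 0, c1[:, peak] / np.where(o1[:, peak] > 0, o1[:, peak], 1), 0.0)
        r0 = np.where(o0[:, peak] > 0, c0[:, peak] / np.where(o0[:, peak] > 0, o0[:, peak], 1), 0.0)
        return np.abs(r1 - r0)

    observed = float(stat(labels[None, :])[0])
    perm = np.stack([rng.permutation(labels) for _ in range(n_shuffles)])
    null = stat(perm)
    p = (1 + np.sum(null >= observed)) / (n_shuffles + 1)
    significant = p <= alpha  # exact permutation criterion
    return float(p), bool(significant), observed


def shift_vs_position_summary(
    shifts: np.ndarray,
    preferred_positions: np.ndarray,
    length: float = 200.0,
    bin_cm: float = 20.0,
) -> pd.DataFrame:
    """Median shift across neurons grouped by preferred-position bin.

    Exposes the contrast between neurons firing at landmarks (small
    shifts) and between landmarks (larger shifts).
    """
    shifts = np.asarray(shifts, dtype=float)
    pos = np.asarray(preferred_positions, dtype=float)
    if len(shifts) == 0:
        raise ValueError("no neurons provided")
    n_bins = int(round(length / bin_cm))
    idx = position_to_bin(pos, length, bin_cm)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append(((b + 0.5) * bin_cm, float(np.median(shifts[sel])), int(sel.sum())))
    return pd.DataFrame(rows, columns=["position_cm", "median_shift_cm", "n_neurons"])
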