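"""Independent-Poisson Bayesian decoding of position from population spikes.

For a spike-count vector R = (r_1..r_M) counted in a window of t seconds,
the posterior over track position x is

    P(x | R) = (1/Z) P(x) (prod_i f_i(x)^r_i) exp(-t sum_i f_i(x))

with f_i(x) the spatial response profile of neuron i estimated from
medium-gain correct trials.  Medium-gain windows are decoded with 20-fold
cross-validated encoding models (contiguous trial blocks); low/high-gain
windows are decoded with the full medium-gain model.  The decoded
position is the posterior argmax and the decoding error is the signed
circular distance decoded - actual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geometry import circular_distance, smooth_circular, smooth_circular_2d
from .profiles import (
    DEFAULT_BIN_CM,
    DEFAULT_SMOOTH_SD_CM,
    _maps,
    profile_from_maps,
    spikes_per_sample,
)
from .geometry import position_to_bin
from .session import SessionTimeline
from .theta import ThetaPhaseSeries

RATE_FLOOR_HZ = 0.01
MIN_NEURONS = 10


@dataclass
class EncodingModel:
    """Per-neuron rate maps f_i(x) plus the positional prior."""

    rates: np.ndarray  # (M, n_bins) Hz, floored at rate_floor
    prior: np.ndarray  # (n_bins,), sums to 1
    bin_centers: np.ndarray  # cm
    bin_cm: float
    rate_floor: float = RATE_FLOOR_HZ

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    @property
    def log_rates(self) -> np.ndarray:
        return np.log(np.maximum(self.rates, self.rate_floor))

    @property
    def sum_rates(self) -> np.ndarray:
        return np.maximum(self.rates, self.rate_floor).sum(axis=0)


@dataclass
class DecodingResult:
    """Per-window decoding outputs."""

    windows: pd.DataFrame  # time, actual, decoded, error, gain, trial_id, speed, phase
    bin_centers: np.ndarray
    window_s: float
    length: float
    posterior: np.ndarray | None = None  # (n_windows, n_bins) if kept


def fit_encoding_model(
    spike_trains: list[np.ndarray],
    timeline: SessionTimeline,
    sample_mask: np.ndarray,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    prior: str = "occupancy",
    rate_floor: float = RATE_FLOOR_HZ,
) -> EncodingModel:
    """Spatial response profiles of all neurons from the selected samples.

    ``prior`` is either the occupancy of the training samples or
    "uniform".
    """
    L = timeline.geometry.corridor_length
    n_bins = int(round(L / bin_cm))
    posbin = position_to_bin(timeline.position, L, bin_cm)
    rates = np.empty((len(spike_trains), n_bins))
    occ_raw = None
    for i, st in enumerate(spike_trains):
        counts = spikes_per_sample(np.asarray(st, dtype=float), timeline)
        c, o = _maps(posbin, counts, sample_mask, n_bins, timeline.dt)
        prof = profile_from_maps(c, o, L, bin_cm, smooth_sd_cm)
        rates[i] = prof.rate
        occ_raw = o
    if prior == "occupancy":
        pr = occ_raw / occ_raw.sum()
        pr = np.maximum(pr, 1e-12)
        pr = pr / pr.sum()
    elif prior == "uniform":
        pr = np.full(n_bins, 1.0 / n_bins)
    else:
        raise ValueError(f"unknown prior {prior!r}")
    centers = (np.arange(n_bins) + 0.5) * bin_cm
    return EncodingModel(rates=rates, prior=pr, bin_centers=centers, bin_cm=bin_cm,
                         rate_floor=rate_floor)


def posterior(counts: np.ndarray, model: EncodingModel, t: float) -> np.ndarray:
    """Posterior over position for one or many count vectors.

    ``counts`` is (M,) or (n_windows, M); computed in the log domain and
    normalized so each posterior sums to 1.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    if t <= 0:
        raise ValueError("window length must be positive")
    logpost = (
        np.log(model.prior)[None, :]
        + counts @ model.log_rates
        - t * model.sum_rates[None, :]
    )
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    if np.any(~np.isfinite(post)):
        raise ValueError("posterior mass vanished")
    return post[0] if post.shape[0] == 1 and np.ndim(counts) == 1 else post


# ---------------------------------------------------------------------------
# windows


def make_windows(
    timeline: SessionTimeline,
    window_s: float,
    mask: np.ndarray | None = None,
    theta: ThetaPhaseSeries | None = None,
    min_masked_frac: float = 0.5,
) -> pd.DataFrame:
    """Non-overlapping spike-count windows tiling the session.

    Each window carries the behavioral state of its center sample; only
    windows with at least ``min_masked_frac`` of masked samples are kept.
    """
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    w = int(round(window_s * timeline.sample_rate))
    n_win = timeline.n_samples // w
    idx = np.arange(n_win)
    i0 = idx * w
    centers = i0 + w // 2
    frac = np.add.reduceat(mask.astype(float), i0)[:n_win] / w
    keep = frac >= min_masked_frac
    if theta is not None:
        keep &= theta.valid[centers]
    df = pd.DataFrame(
        {
            "window_id": idx[keep],
            "t_start": timeline.time[0] + i0[keep] * timeline.dt,
            "time": timeline.time[centers[keep]],
            "actual": timeline.position[centers[keep]],
            "gain": timeline.gain[centers[keep]],
            "trial_id": timeline.trial_id[centers[keep]],
            "speed": timeline.speed[centers[keep]],
        }
    )
    if theta is not None:
        # interpolated at the exact window center: theta sweeps ~50 degrees
        # per sample, so sample-start phases alias against 20-degree bins
        df["phase"] = theta.phase_at(i0[keep] + w / 2.0)
        df["cycle_id"] = theta.cycle_id[centers[keep]]
    return df


def window_counts(
    spike_trains: list[np.ndarray], windows: pd.DataFrame, window_s: float
) -> np.ndarray:
    """Spike counts per (window, neuron)."""
    t0 = windows["t_start"].to_numpy()
    counts = np.empty((len(windows), len(spike_trains)))
    for j, st in enumerate(spike_trains):
        st = np.asarray(st, dtype=float)
        counts[:, j] = np.searchsorted(st, t0 + window_s) - np.searchsorted(st, t0)
    return counts


# ---------------------------------------------------------------------------
# session decoding


def decode_session(
    spike_trains: list[np.ndarray],
    timeline: SessionTimeline,
    trials: pd.DataFrame,
    train_trial_ids: np.ndarray,
    mask: np.ndarray | None = None,
    theta: ThetaPhaseSeries | None = None,
    window_s: float = 0.25,
    folds: int = 20,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
    prior: str = "occupancy",
    min_neurons: int = MIN_NEURONS,
    keep_posterior: bool = False,
) -> DecodingResult:
    """Decode a whole session with cross-validated medium-gain models.

    ``train_trial_ids`` are the trials used to build encoding models
    (medium-gain correct trials).  They are split into ``folds``
    contiguous blocks; windows in a block are decoded with the model
    trained on the remaining blocks, windows outside the training trials
    with the full model.
    """
    if len(spike_trains) < min_neurons:
        raise ValueError(
            f"need more than {min_neurons} spatially tuned neurons to decode, "
            f"got {len(spike_trains)}"
        )
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    train_trial_ids = np.asarray(train_trial_ids)
    windows = make_windows(timeline, window_s, mask, theta)
    counts = window_counts(spike_trains, windows, window_s)
    L = timeline.geometry.corridor_length
    n_bins = int(round(L / bin_cm))
    post = np.empty((len(windows), n_bins))

    trial_of_window = windows["trial_id"].to_numpy()
    in_train = np.isin(trial_of_window, train_trial_ids)
    trial_samples = np.isin(timeline.trial_id, train_trial_ids)

    folds = min(folds, len(train_trial_ids))
    blocks = np.array_split(train_trial_ids, folds)
    full_mask = mask & trial_samples
    full_model = fit_encoding_model(
        spike_trains, timeline, full_mask, bin_cm, smooth_sd_cm, prior
    )
    if np.any(~in_train):
        post[~in_train] = posterior(counts[~in_train], full_model, window_s)
    if folds <= 1:  # no held-out models: decode everything with the full model
        if np.any(in_train):
            post[in_train] = posterior(counts[in_train], full_model, window_s)
        blocks = []
    for block in blocks:
        sel = np.isin(trial_of_window, block)
        if not np.any(sel):
            continue
        train_mask = mask & trial_samples & ~np.isin(timeline.trial_id, block)
        model = fit_encoding_model(
            spike_trains, timeline, train_mask, bin_cm, smooth_sd_cm, prior
        )
        post[sel] = posterior(counts[sel], model, window_s)

    decoded = full_model.bin_centers[np.argmax(post, axis=1)]
    out = windows.copy()
    out["decoded"] = decoded
    out["error"] = circular_distance(decoded, out["actual"].to_numpy(), L)
    out["cv_heldout"] = in_train
    return DecodingResult(
        windows=out,
        bin_centers=full_model.bin_centers,
        window_s=window_s,
        length=L,
        posterior=post if keep_posterior else None,
    )


# ---------------------------------------------------------------------------
# summaries


def decoded_distribution(
    result: DecodingResult, smooth_sd_cm: float = 2.0, gain: float | None = None
) -> np.ndarray:
    """Column-normalized density of decoded vs actual position.

    Rows: decoded position bins; columns: actual position bins.  The
    joint histogram is smoothed with a circular 2-D Gaussian, then each
    actual-position column is normalized to sum to 1 (unvisited columns
    stay zero).
    """
    w = result.windows
    if gain is not None:
        w = w[w["gain"] == gain]
    if len(w) == 0:
        raise ValueError("no decoded windows")
    nb = len(result.bin_centers)
    bc = result.bin_centers[0] * 2  # = bin width
    dec = position_to_bin(w["decoded"].to_numpy(), result.length, bc)
    act = position_to_bin(w["actual"].to_numpy(), result.length, bc)
    joint = np.zeros((nb, nb))
    np.add.at(joint, (dec, act), 1.0)
    joint = smooth_circular_2d(joint, (smooth_sd_cm / bc, smooth_sd_cm / bc))
    sums = joint.sum(axis=0, keepdims=True)
    return np.divide(joint, sums, out=np.zeros_like(joint), where=sums > 0)


def _circular_mean_error(errors: np.ndarray, length: float, weights=None) -> float:
    """Weighted circular average of signed errors on a circle of size L."""
    ang = errors * 2 * np.pi / length
    w = np.ones_like(ang) if weights is None else weights
    z = np.sum(w * np.exp(1j * ang))
    return float(np.angle(z) * length / (2 * np.pi))


@dataclass
class ErrorSummary:
    """Per-position decoding error statistics for one gain condition."""

    position_centers: np.ndarray
    mean_error: np.ndarray  # weighted circular average per position (cm)
    bias: np.ndarray  # most-likely error per position (cm)
    mean_error_se: np.ndarray
    bias_se: np.ndarray
    gain: float
    corrected: bool = False


def error_summaries(
    result: DecodingResult,
    gain: float,
    reference: "ErrorSummary | None" = None,
    pos_bin_cm: float = 8.0,
    err_bin_cm: float = 2.0,
    smooth_sd_cm: float = 2.0,
    jackknife_folds: int = 20,
) -> ErrorSummary:
    """Mean decoding error and decoding bias as a function of position.

    The error distribution per position bin is smoothed and normalized;
    the mean error is its weighted circular average and the bias its
    argmax.  When ``reference`` (the medium-gain summary) is given, both
    curves are reported after subtracting the reference values.  Standard
    errors come from a jackknife over contiguous window folds.
    """
    w = result.windows[result.windows["gain"] == gain]
    if len(w) == 0:
        raise ValueError(f"no windows at gain {gain}")
    L = result.length
    n_pos = int(round(L / pos_bin_cm))
    n_err = int(round(L / err_bin_cm))
    posb = position_to_bin(w["actual"].to_numpy(), L, pos_bin_cm)
    err = w["error"].to_numpy()
    errb = np.clip(((err + L / 2) / err_bin_cm).astype(int) % n_err, 0, n_err - 1)
    err_centers = (np.arange(n_err) + 0.5) * err_bin_cm - L / 2

    def curves(sel: np.ndarray):
        joint = np.zeros((n_err, n_pos))
        np.add.at(joint, (errb[sel], posb[sel]), 1.0)
        joint = smooth_circular_2d(joint, (smooth_sd_cm / err_bin_cm, 0.0))
        sums = joint.sum(axis=0)
        mean = np.full(n_pos, np.nan)
        bias = np.full(n_pos, np.nan)
        for pcol in range(n_pos):
            if sums[pcol] > 0:
                dist = joint[:, pcol] / sums[pcol]
                mean[pcol] = _circular_mean_error(err_centers, L, weights=dist)
                bias[pcol] = err_centers[np.argmax(dist)]
        return mean, bias

    all_sel = np.ones(len(w), dtype=bool)
    mean, bias = curves(all_sel)

    folds = min(jackknife_folds, max(2, len(w) // 10))
    fold_of = np.minimum(np.arange(len(w)) * folds // len(w), folds - 1)
    jk_mean = np.empty((folds, n_pos))
    jk_bias = np.empty((folds, n_pos))
    for f in range(folds):
        m, b = curves(fold_of != f)
        jk_mean[f], jk_bias[f] = m, b
    fac = (folds - 1) / folds
    mean_se = np.sqrt(fac * np.nansum((jk_mean - np.nanmean(jk_mean, 0)) ** 2, 0))
    bias_se = np.sqrt(fac * np.nansum((jk_bias - np.nanmean(jk_bias, 0)) ** 2, 0))

    corrected = False
    if reference is not None:
        mean = circular_distance(mean, reference.mean_error, L)
        bias = circular_distance(bias, reference.bias, L)
        corrected = True
    return ErrorSummary(
        position_centers=(np.arange(n_pos) + 0.5) * pos_bin_cm,
        mean_error=mean,
        bias=bias,
        mean_error_se=mean_se,
        bias_se=bias_se,
        gain=gain,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# theta-phase-resolved decoding


@dataclass
class PhaseDecodingResult:
    phase_centers_deg: np.ndarray
    mean_error: np.ndarray  # cm per phase bin, smoothed
    amplitude_cm: float
    offset_deg: float
    p_value: float
    significant: bool


def decode_by_theta_phase(
    spike_trains: list[np.ndarray],
    timeline: SessionTimeline,
    model: EncodingModel,
    theta: ThetaPhaseSeries,
    mask: np.ndarray | None = None,
    window_s: float = 0.05,
    bin_deg: float = 20.0,
    smooth_sd_deg: float = 40.0,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    min_per_bin: int = 5,
    seed: int | None = None,
) -> PhaseDecodingResult:
    """Mean decoding error across theta phases (50-ms windows).

    The per-phase-bin circular-mean error is smoothed across phase and
    fitted with a sinusoid; significance compares the fitted amplitude to
    a null where window phases are randomized.
    """
    from .theta import fit_drift_sinusoid

    windows = make_windows(timeline, window_s, mask, theta)
    if len(windows) == 0:
        raise ValueError("no usable decoding windows")
    counts = window_counts(spike_trains, windows, window_s)
    post = posterior(counts, model, window_s)
    decoded = model.bin_centers[np.argmax(post, axis=1)]
    L = timeline.geometry.corridor_length
    err = circular_distance(decoded, windows["actual"].to_numpy(), L)
    # remove the position-dependent component of the error first: theta
    # phase and position are locked on a ~3-cm wavelength at running
    # speed, so per-position decoding bias would otherwise masquerade as
    # phase modulation
    posb = position_to_bin(windows["actual"].to_numpy(), L, 8.0)
    for b in np.unique(posb):
        sel = posb == b
        err[sel] = circular_distance(
            err[sel], _circular_mean_error(err[sel], L), L
        )
    phase = windows["phase"].to_numpy()
    n_bins = int(round(360.0 / bin_deg))
    rng = np.random.default_rng(seed)
    sd_bins = smooth_sd_deg / bin_deg
    centers = (np.arange(n_bins) + 0.5) * bin_deg

    def amplitude_of(ph: np.ndarray):
        pb = np.clip((ph / bin_deg).astype(int), 0, n_bins - 1)
        curve = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = pb == b
            if sel.sum() >= min_per_bin:
                curve[b] = _circular_mean_error(err[sel], L)
        good = ~np.isnan(curve)
        # the 50-ms window grid can alias against theta and leave bins
        # structurally unpopulated; the sinusoid is then fitted on the
        # populated bins directly (smoothing needs the full circle)
        if good.sum() < 8:
            raise ValueError("insufficient windows in too many phase bins")
        if good.all():
            sm = smooth_circular(curve, sd_bins)
            amp, off = fit_drift_sinusoid(sm, centers)
            return sm, amp, off
        amp, off = fit_drift_sinusoid(curve[good], centers[good])
        return curve, amp, off

    smoothed, amplitude, offset = amplitude_of(phase)
    # randomized phases: circular shift of the window-phase sequence, so
    # the null keeps the autocorrelation of both errors and phase (a
    # plain per-window permutation is anti-conservative here because
    # consecutive 50-ms windows are strongly dependent)
    null = np.empty(n_shuffles)
    lo = max(1, int(5.0 / window_s))
    shifts = rng.integers(lo, max(lo + 1, len(phase) - lo), size=n_shuffles)
    for k in range(n_shuffles):
        _, null[k], _ = amplitude_of(np.roll(phase, shifts[k]))
    p = (1 + np.sum(null >= amplitude)) / (n_shuffles + 1)
    return PhaseDecodingResult(
        phase_centers_deg=centers,
        mean_error=smoothed,
        amplitude_cm=float(amplitude),
        offset_deg=float(offset),
        p_value=float(p),
        significant=bool(p <= alpha),  # exact permutation criterion
    )


# ---------------------------------------------------------------------------
# licks in decoded coordinates


def licks_in_decoded_coordinates(
    timeline: SessionTimeline,
    result: DecodingResult,
    bin_cm: float = 2.0,
    smooth_sd_cm: float = 8.0,
) -> pd.DataFrame:
    """Lick-position densities using decoded instead of actual positions.

    Each lick takes the decoded position of its containing window; licks
    outside decoded windows are dropped (count reported).  Returns one
    row per gain with the circular-mean decoded lick position, the shift
    relative to medium gain, and the number of licks used/dropped.
    """
    L = result.length
    lick_idx = np.flatnonzero(timeline.lick > 0)
    lick_t = timeline.time[lick_idx]
    w = result.windows
    win_id_of_lick = ((lick_t - timeline.time[0]) / result.window_s).astype(int)
    win_lookup = pd.Series(np.arange(len(w)), index=w["window_id"].to_numpy())
    rows = []
    matched = win_lookup.reindex(win_id_of_lick)
    dropped = int(matched.isna().sum())
    good = ~matched.isna().to_numpy()
    widx = matched[good].to_numpy().astype(int)
    decoded = w["decoded"].to_numpy()[widx]
    gains = w["gain"].to_numpy()[widx]
    medium_mean = None
    for g in sorted(np.unique(w["gain"])):
        sel = gains == g
        if not np.any(sel):
            continue
        mean_pos = _circular_mean_error(
            circular_distance(decoded[sel], 0.0, L), L
        )
        rows.append({"gain": g, "mean_decoded_lick_cm": mean_pos % L, "n_licks": int(sel.sum())})
        if g == 1.0:
            medium_mean = mean_pos
    df = pd.DataFrame(rows)
    if medium_mean is not None:
        df["shift_vs_medium_cm"] = [
            circular_distance(m, medium_mean, L) for m in df["mean_decoded_lick_cm"]
        ]
    df.attrs["dropped_licks"] = dropped
    return df
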