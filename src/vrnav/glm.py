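"""Two-step orthogonalized ridge regression of spike counts.

Spike counts in 250-ms windows are first regressed on position (100
indicator columns of 2-cm bins, medium-gain trials), then the residual is
regressed on behavioral state: run speed, acceleration, pupil size, pupil
azimuth, pupil elevation and lick count, each binned in 10 quantiles, and
a scalar reward indicator, all replicated at 9 lags from -1 s to +1 s in
0.25-s steps (6 x 10 x 9 + 9 = 549 columns).  Fitting position first and
the behavioral variables on the residual keeps the two components
orthogonal even though behavior and position are strongly correlated on
the track.

The delay-model scan refits step 1 with the position indicators shifted
in time (0 to 1000 ms in 100-ms steps); the optimal response latency is
the delay whose predicted low/high-gain profiles best correlate with the
predicted medium-gain profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .geometry import position_to_bin
from .profiles import DEFAULT_BIN_CM, DEFAULT_SMOOTH_SD_CM, profile_from_maps
from .profiles import estimate_gain_shift
from .session import SessionTimeline

LAGS_S = tuple(np.arange(-1.0, 1.01, 0.25))  # 9 lags
BEHAVIORAL_VARS = ("speed", "accel", "pupil_size", "pupil_az", "pupil_el", "lick")


@dataclass
class GlmDesign:
    """Aligned 250-ms windows with positional and behavioral designs."""

    windows: pd.DataFrame  # window_id, time, posbin, gain, trial_id, masked
    X_pos: np.ndarray  # (W, n_pos_bins) one-hot
    X_beh: np.ndarray  # (W, 549)
    window_s: float
    pos_bin_cm: float
    lags_s: tuple[float, ...]
    quantile_edges: dict[str, np.ndarray]
    length: float


@dataclass
class GlmFit:
    """Two-step fit: positional and behavioral coefficients + predictions."""

    beta_pos: np.ndarray
    beta_beh: np.ndarray
    y_mean: float
    yhat_pos: np.ndarray  # centered prediction, all windows
    yhat_beh: np.ndarray
    lam: float

    @property
    def yhat(self) -> np.ndarray:
        return self.yhat_pos + self.yhat_beh


def _window_average(series: np.ndarray, n_win: int, w: int) -> np.ndarray:
    return np.add.reduceat(series[: n_win * w], np.arange(n_win) * w) / w


def build_designs(
    timeline: SessionTimeline,
    window_s: float = 0.25,
    pos_bin_cm: float = DEFAULT_BIN_CM,
    n_quantiles: int = 10,
    lags_s: tuple[float, ...] = LAGS_S,
    mask: np.ndarray | None = None,
    quantile_gain: float = 1.0,
    delay_s: float = 0.0,
) -> GlmDesign:
    """Build the positional and behavioral design matrices.

    Behavioral variables are averaged within each 250-ms window (their
    smoothing window) and binned in quantiles whose edges come from the
    medium-gain windows.  ``delay_s`` shifts the position indicators in
    time for the latency scan (position taken ``delay_s`` earlier).
    Constant covariates collapse to fewer bins with a warning-free merge.
    """
    import warnings

    L = timeline.geometry.corridor_length
    w = int(round(window_s * timeline.sample_rate))
    n_win = timeline.n_samples // w
    centers = np.arange(n_win) * w + w // 2
    center_t = timeline.time[centers]
    if mask is None:
        mask = np.ones(timeline.n_samples, dtype=bool)
    masked = _window_average(mask.astype(float), n_win, w) >= 0.5

    delayed = timeline.sample_of_time(center_t - delay_s)
    posbin = position_to_bin(timeline.position[delayed], L, pos_bin_cm)
    n_pos = int(round(L / pos_bin_cm))
    X_pos = np.zeros((n_win, n_pos))
    X_pos[np.arange(n_win), posbin] = 1.0

    speed_w = _window_average(timeline.speed, n_win, w)
    variables = {
        "speed": speed_w,
        "accel": np.diff(speed_w, prepend=speed_w[0]) / window_s,
        "pupil_size": _window_average(timeline.covariates.get("pupil_size", np.zeros(timeline.n_samples)), n_win, w),
        "pupil_az": _window_average(timeline.covariates.get("pupil_az", np.zeros(timeline.n_samples)), n_win, w),
        "pupil_el": _window_average(timeline.covariates.get("pupil_el", np.zeros(timeline.n_samples)), n_win, w),
        "lick": np.add.reduceat(timeline.lick[: n_win * w].astype(float), np.arange(n_win) * w),
        "reward": np.add.reduceat(timeline.reward[: n_win * w].astype(float), np.arange(n_win) * w) > 0,
    }
    gain_w = timeline.gain[centers]
    ref = gain_w == quantile_gain
    if not ref.any():
        ref = np.ones(n_win, dtype=bool)

    edges = {}
    binned = {}
    for name in BEHAVIORAL_VARS:
        v = variables[name]
        qs = np.quantile(v[ref], np.linspace(0, 1, n_quantiles + 1)[1:-1])
        qs = np.unique(qs)  # degenerate (constant) covariates merge bins
        edges[name] = qs
        binned[name] = np.searchsorted(qs, v)

    lag_steps = [int(round(tau / window_s)) for tau in lags_s]
    cols = []
    for name in BEHAVIORAL_VARS:
        onehot = np.zeros((n_win, n_quantiles))
        onehot[np.arange(n_win), binned[name]] = 1.0
        for step in lag_steps:
            cols.append(_shift_rows(onehot, step))
    reward_vec = variables["reward"].astype(float)[:, None]
    for step in lag_steps:
        cols.append(_shift_rows(reward_vec, step))
    X_beh = np.concatenate(cols, axis=1)

    windows = pd.DataFrame(
        {
            "window_id": np.arange(n_win),
            "time": center_t,
            "posbin": position_to_bin(timeline.position[centers], L, pos_bin_cm),
            "gain": gain_w,
            "trial_id": timeline.trial_id[centers],
            "masked": masked,
        }
    )
    return GlmDesign(
        windows=windows,
        X_pos=X_pos,
        X_beh=X_beh,
        window_s=window_s,
        pos_bin_cm=pos_bin_cm,
        lags_s=tuple(lags_s),
        quantile_edges=edges,
        length=L,
    )


def _shift_rows(X: np.ndarray, step: int) -> np.ndarray:
    """Row-shifted copy: out[t] = X[t - step]; out-of-range rows are zero."""
    out = np.zeros_like(X)
    if step == 0:
        return X.copy()
    if step > 0:
        out[step:] = X[:-step]
    else:
        out[:step] = X[-step:]
    return out


def window_spike_counts(
    spike_times: np.ndarray, timeline: SessionTimeline, window_s: float = 0.25
) -> np.ndarray:
    """Spike counts in the same windows as :func:`build_designs`."""
    w = int(round(window_s * timeline.sample_rate))
    n_win = timeline.n_samples // w
    t0 = timeline.time[0] + np.arange(n_win) * window_s
    st = np.sort(np.asarray(spike_times, dtype=float))
    return (np.searchsorted(st, t0 + window_s) - np.searchsorted(st, t0)).astype(float)


def _ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """(X'X + lam I)^-1 X'y via scikit-learn's closed-form solver."""
    model = Ridge(alpha=lam, fit_intercept=False, solver="cholesky")
    model.fit(X, y)
    return model.coef_


def _cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    train_sel: np.ndarray,
    trial_ids: np.ndarray,
    lam: float,
    folds: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-model coefficients + predictions with CV on training windows.

    Training windows get predictions from the model fitted on the other
    contiguous trial folds; all other windows from the full model.
    """
    beta_full = _ridge(X[train_sel], y[train_sel], lam)
    yhat = X @ beta_full
    train_trials = np.unique(trial_ids[train_sel])
    n_folds = min(folds, len(train_trials))
    for block in np.array_split(train_trials, n_folds):
        sel = train_sel & np.isin(trial_ids, block)
        if not sel.any():
            continue
        fit_sel = train_sel & ~np.isin(trial_ids, block)
        if not fit_sel.any():
            continue
        beta = _ridge(X[fit_sel], y[fit_sel], lam)
        yhat[sel] = X[sel] @ beta
    return beta_full, yhat


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    train_sel: np.ndarray,
    trial_ids: np.ndarray,
    grid=(0.1, 1.0, 10.0, 100.0, 1000.0),
    folds: int = 5,
) -> float:
    """Ridge penalty by nested CV (contiguous trial folds) on the
    training windows; smallest-MSE lambda, ties toward stronger penalty."""
    train_trials = np.unique(trial_ids[train_sel])
    n_folds = min(folds, len(train_trials))
    best_lam, best_mse = grid[0], np.inf
    for lam in grid:
        sse, n = 0.0, 0
        for block in np.array_split(train_trials, n_folds):
            val = train_sel & np.isin(trial_ids, block)
            fit = train_sel & ~np.isin(trial_ids, block)
            if not val.any() or not fit.any():
                continue
            beta = _ridge(X[fit], y[fit], lam)
            sse += np.sum((y[val] - X[val] @ beta) ** 2)
            n += val.sum()
        mse = sse / max(n, 1)
        if mse <= best_mse:
            best_mse, best_lam = mse, lam
    return float(best_lam)


def fit_two_step(
    y_counts: np.ndarray,
    design: GlmDesign,
    lam: float | str = 1.0,
    folds: int = 20,
    train_gain: float = 1.0,
) -> GlmFit:
    """Position-then-behavior ridge fit with cross-validated predictions.

    ``y_counts`` are raw spike counts per window; they are mean-centered
    with the mean of the training (medium-gain) windows.  ``lam="auto"``
    selects the penalty by nested cross-validation.
    """
    w = design.windows
    train_sel = (w["gain"].to_numpy() == train_gain) & w["masked"].to_numpy()
    if not train_sel.any():
        raise ValueError("no training windows at the requested gain")
    trial_ids = w["trial_id"].to_numpy()
    y_mean = float(np.mean(y_counts[train_sel]))
    y = np.asarray(y_counts, dtype=float) - y_mean
    if lam == "auto":
        lam = select_lambda(design.X_pos, y, train_sel, trial_ids)
    beta_pos, yhat_pos = _cv_predict(
        design.X_pos, y, train_sel, trial_ids, float(lam), folds
    )
    resid = y - yhat_pos
    beta_beh, yhat_beh = _cv_predict(
        design.X_beh, resid, train_sel, trial_ids, float(lam), folds
    )
    return GlmFit(
        beta_pos=beta_pos,
        beta_beh=beta_beh,
        y_mean=y_mean,
        yhat_pos=yhat_pos,
        yhat_beh=yhat_beh,
        lam=float(lam),
    )


def predicted_profiles(
    prediction_centered: np.ndarray,
    fit_mean: float,
    design: GlmDesign,
    smooth_sd_cm: float = DEFAULT_SMOOTH_SD_CM,
):
    """Per-gain response profiles computed from a model prediction.

    The predicted counts (prediction + training mean, floored at 0) are
    accumulated over actual-position bins exactly as spike counts are,
    and divided by the windows' occupancy, with the same circular
    smoothing as spike-derived profiles.
    """
    w = design.windows
    n_pos = design.X_pos.shape[1]
    pred_counts = np.maximum(prediction_centered + fit_mean, 0.0)
    profiles = {}
    for g in sorted(w["gain"].unique()):
        sel = (w["gain"] == g).to_numpy() & w["masked"].to_numpy()
        pb = w["posbin"].to_numpy()[sel]
        counts = np.bincount(pb, weights=pred_counts[sel], minlength=n_pos)
        occ = np.bincount(pb, minlength=n_pos) * design.window_s
        profiles[float(g)] = profile_from_maps(
            counts, occ, design.length, design.pos_bin_cm, smooth_sd_cm,
            condition=f"gain={g}",
        )
    return profiles


def predicted_gain_shifts(
    fit: GlmFit,
    design: GlmDesign,
    component: str = "full",
) -> pd.DataFrame:
    """Gain shifts measured on profiles predicted by the fitted model.

    ``component`` selects which prediction builds the profiles: "full"
    (position + behavior), "pos", or "beh".
    """
    pred = {"full": fit.yhat, "pos": fit.yhat_pos, "beh": fit.yhat_beh}[component]
    profiles = predicted_profiles(pred, fit.y_mean, design)
    medium = profiles.get(1.0)
    if medium is None:
        raise ValueError("no medium-gain windows to anchor the shift")
    rows = []
    for g, prof in profiles.items():
        if g == 1.0:
            continue
        res = estimate_gain_shift(prof, medium)
        rows.append({"gain": g, "shift_cm": res.shift_cm, "correlation": res.correlation})
    return pd.DataFrame(rows)


def fit_delay_models(
    y_counts: np.ndarray,
    timeline: SessionTimeline,
    delays_s=tuple(np.arange(0.0, 1.001, 0.1)),
    lam: float | str = 1.0,
    folds: int = 20,
    mask: np.ndarray | None = None,
    window_s: float = 0.25,
) -> pd.DataFrame:
    """Latency scan: refit step 1 with time-shifted position indicators.

    For each delay the two-step model (trained on medium gain) is
    refitted and its predicted profiles at low and high gain are
    correlated with the measured (spike-derived) profiles of those gain
    conditions; only at the true response latency does the
    medium-trained model transfer to the manipulated gains, because the
    apparent field shift a latency produces scales with the visual speed
    and hence with the gain.  The table is sorted by delay; the row with
    ``optimal == True`` marks the argmax (ties toward the smaller delay).
    """
    rows = []
    measured = None
    for delay in delays_s:
        design = build_designs(timeline, window_s=window_s, mask=mask, delay_s=delay)
        if measured is None:
            # spike-derived per-gain profiles (delay-independent reference)
            measured = predicted_profiles(
                np.asarray(y_counts, dtype=float), 0.0, design
            )
        fit = fit_two_step(y_counts, design, lam=lam, folds=folds)
        profiles = predicted_profiles(fit.yhat, fit.y_mean, design)
        corrs = []
        for g, prof in profiles.items():
            if g == 1.0 or g not in measured:
                continue
            a, b = prof.rate, measured[g].rate
            if a.std() > 0 and b.std() > 0:
                corrs.append(np.corrcoef(a, b)[0, 1])
        rows.append({"delay_s": float(delay), "score": float(np.mean(corrs)) if corrs else np.nan})
    df = pd.DataFrame(rows).sort_values("delay_s", ignore_index=True)
    best = int(np.argmax(df["score"].to_numpy()))  # first occurrence: smaller delay
    df["optimal"] = False
    df.loc[best, "optimal"] = True
    return df
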