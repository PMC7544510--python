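"""Co-fluctuation of V1 and CA1 decoding errors beyond position and speed.

The raw correlation between the two regions' decoding errors partly
reflects shared tuning to position and running speed.  The analysis here
compares the measured joint error distribution with one where the pairing
of simultaneous windows is shuffled only among windows taken at the same
position (within 2 cm) and the same speed quintile.  The difference map
isolates covariance that position and speed cannot explain; shared
spatial noise shows up as excess mass along the identity diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import circular_distance, smooth_circular, smooth_circular_2d
from .decoding import DecodingResult, decode_session


@dataclass
class JointErrorMap:
    """Joint density of (V1 error, CA1 error), measured vs shuffled."""

    error_centers: np.ndarray  # cm
    measured: np.ndarray  # (n_err, n_err), sums to 1
    shuffled: np.ndarray  # average over shuffle repetitions, sums to 1
    difference: np.ndarray  # measured - shuffled, sums to ~0
    n_singleton_cells: int

    def diagonal_excess(self, band_cm: float = 10.0) -> float:
        """Integrated difference mass within |errV1 - errCA1| <= band."""
        L = self.error_centers[-1] - self.error_centers[0] + (
            self.error_centers[1] - self.error_centers[0]
        )
        d = circular_distance(
            self.error_centers[:, None], self.error_centers[None, :], L
        )
        return float(self.difference[np.abs(d) <= band_cm].sum())


def _condition_cells(position, speed, length, pos_bin_cm=2.0, n_speed_bins=5):
    """(position bin, speed quintile) cell index per window."""
    from .geometry import position_to_bin

    posb = position_to_bin(position, length, pos_bin_cm)
    edges = np.quantile(speed, np.linspace(0, 1, n_speed_bins + 1)[1:-1])
    speedb = np.searchsorted(edges, speed)
    return posb * n_speed_bins + speedb


def shuffle_within_bins(
    err_a: np.ndarray,
    cells: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Permute one region's errors within identical conditioning cells.

    Singleton cells cannot be permuted and are left fixed; their count is
    returned alongside the shuffled errors.
    """
    out = err_a.copy()
    singles = 0
    for c in np.unique(cells):
        idx = np.flatnonzero(cells == c)
        if len(idx) < 2:
            singles += 1
            continue
        out[idx] = err_a[idx[rng.permutation(len(idx))]]
    return out, singles


def joint_error_map(
    err_v1: np.ndarray,
    err_ca1: np.ndarray,
    position: np.ndarray,
    speed: np.ndarray,
    length: float = 200.0,
    err_bin_cm: float = 2.0,
    smooth_sd_cm: float = 4.0,
    pos_bin_cm: float = 2.0,
    n_speed_bins: int = 5,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> JointErrorMap:
    """Measured vs position/speed-conditioned-shuffle joint error map."""
    err_v1 = np.asarray(err_v1, dtype=float)
    err_ca1 = np.asarray(err_ca1, dtype=float)
    if len(err_v1) != len(err_ca1) or len(err_v1) < 2:
        raise ValueError("need >= 2 simultaneous windows from both regions")
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    n_err = int(round(length / err_bin_cm))
    centers = (np.arange(n_err) + 0.5) * err_bin_cm - length / 2

    def density(ev, ec):
        bi = np.clip(((ev + length / 2) / err_bin_cm).astype(int) % n_err, 0, n_err - 1)
        bj = np.clip(((ec + length / 2) / err_bin_cm).astype(int) % n_err, 0, n_err - 1)
        h = np.zeros((n_err, n_err))
        np.add.at(h, (bi, bj), 1.0)
        h = smooth_circular_2d(h, (smooth_sd_cm / err_bin_cm, smooth_sd_cm / err_bin_cm))
        return h / h.sum()

    measured = density(err_v1, err_ca1)
    cells = _condition_cells(position, speed, length, pos_bin_cm, n_speed_bins)
    shuffled = np.zeros_like(measured)
    singles = 0
    for _ in range(n_shuffles):
        ev, singles = shuffle_within_bins(err_v1, cells, rng)
        shuffled += density(ev, err_ca1)
    shuffled /= n_shuffles
    return JointErrorMap(
        error_centers=centers,
        measured=measured,
        shuffled=shuffled,
        difference=measured - shuffled,
        n_singleton_cells=singles,
    )


def mismatch_distribution(
    dec_v1: np.ndarray,
    dec_ca1: np.ndarray,
    position: np.ndarray,
    speed: np.ndarray,
    length: float = 200.0,
    bin_cm: float = 2.0,
    smooth_sd_cm: float = 4.0,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Density of the circular distance between the two decoded positions.

    Returns a table (mismatch_cm, measured, shuffled, difference); the
    shuffle permutes V1 decoded positions within (position, speed) cells.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(length / bin_cm))
    centers = (np.arange(n_bins) + 0.5) * bin_cm - length / 2

    def density(dv):
        mm = circular_distance(dv, dec_ca1, length)
        b = np.clip(((mm + length / 2) / bin_cm).astype(int) % n_bins, 0, n_bins - 1)
        h = np.bincount(b, minlength=n_bins).astype(float)
        h = smooth_circular(h, smooth_sd_cm / bin_cm)
        return h / h.sum()

    measured = density(np.asarray(dec_v1, dtype=float))
    cells = _condition_cells(position, speed, length)
    shuffled = np.zeros(n_bins)
    for _ in range(n_shuffles):
        dv, _ = shuffle_within_bins(np.asarray(dec_v1, dtype=float), cells, rng)
        shuffled += density(dv)
    shuffled /= n_shuffles
    return pd.DataFrame(
        {
            "mismatch_cm": centers,
            "measured": measured,
            "shuffled": shuffled,
            "difference": measured - shuffled,
        }
    )


def simultaneous_errors(
    res_v1: DecodingResult, res_ca1: DecodingResult, correct_trial_ids=None
) -> pd.DataFrame:
    """Align two regions' decoding results on shared windows.

    Returns a table with err_v1, err_ca1, dec_v1, dec_ca1, actual, speed,
    gain, phase/cycle when available; restricted to ``correct_trial_ids``
    when given.
    """
    cols = ["window_id", "decoded", "error"]
    a = res_v1.windows.set_index("window_id")
    b = res_ca1.windows.set_index("window_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    out = pd.DataFrame(
        {
            "err_v1": a["error"].to_numpy(),
            "err_ca1": b["error"].to_numpy(),
            "dec_v1": a["decoded"].to_numpy(),
            "dec_ca1": b["decoded"].to_numpy(),
            "actual": a["actual"].to_numpy(),
            "speed": a["speed"].to_numpy(),
            "gain": a["gain"].to_numpy(),
            "trial_id": a["trial_id"].to_numpy(),
        }
    )
    for extra in ("phase", "cycle_id"):
        if extra in a.columns:
            out[extra] = a[extra].to_numpy()
    if correct_trial_ids is not None:
        out = out[out["trial_id"].isin(correct_trial_ids)].reset_index(drop=True)
    return out


def split_thirds_control(
    spikes_v1: list[np.ndarray],
    spikes_ca1: list[np.ndarray],
    timeline,
    trials: pd.DataFrame,
    usable_trial_ids: np.ndarray,
    mask: np.ndarray | None = None,
    window_s: float = 0.25,
    n_shuffles: int = 100,
    min_neurons: int = 10,
    seed: int | None = None,
) -> JointErrorMap:
    """Error coupling with independently trained decoders.

    The usable trials are split into three equal contiguous parts: the V1
    decoder trains on part 1, the CA1 decoder on part 2, and the joint
    error map is evaluated on part 3 only — a common overfit of training
    noise can then no longer produce coupling.
    """
    usable = np.asarray(usable_trial_ids)
    if len(usable) < 3:
        raise ValueError("need at least three usable trials to split")
    part1, part2, part3 = np.array_split(usable, 3)
    res_v1 = decode_session(
        spikes_v1, timeline, trials, part1, mask=mask, window_s=window_s,
        folds=1, min_neurons=min_neurons,
    )
    res_ca1 = decode_session(
        spikes_ca1, timeline, trials, part2, mask=mask, window_s=window_s,
        folds=1, min_neurons=min_neurons,
    )
    sim = simultaneous_errors(res_v1, res_ca1, correct_trial_ids=part3)
    if len(sim) < 2:
        raise ValueError("too few evaluation windows in the held-out third")
    return joint_error_map(
        sim["err_v1"].to_numpy(),
        sim["err_ca1"].to_numpy(),
        sim["actual"].to_numpy(),
        sim["speed"].to_numpy(),
        length=timeline.geometry.corridor_length,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def cycle_modulation_correlation(
    sim: pd.DataFrame,
    length: float = 200.0,
    min_windows: int = 3,
    min_cycles: int = 30,
    n_shuffles: int = 100,
    seed: int | None = None,
):
    """Correlation of per-theta-cycle error-modulation amplitudes.

    For each complete theta cycle with at least ``min_windows`` decoded
    windows, the decoding errors of each region are fitted with a
    sinusoid of phase; the absolute fitted amplitudes are correlated
    across cycles between regions.  The null shuffles one region's
    errors within (position, speed) cells before the per-cycle fits.

    Returns (r, p, n_cycles, null_r array).
    """
    from .theta import _sinusoid_design

    if "cycle_id" not in sim.columns:
        raise ValueError("simultaneous windows must carry theta cycle ids")
    rng = np.random.default_rng(seed)

    def cycle_amplitudes(err_a, err_b):
        amps_a, amps_b = [], []
        for _, grp in sim.assign(_ea=err_a, _eb=err_b).groupby("cycle_id"):
            if len(grp) < min_windows or grp["cycle_id"].iloc[0] < 0:
                continue
            X = _sinusoid_design(grp["phase"].to_numpy())
            for err, acc in ((grp["_ea"], amps_a), (grp["_eb"], amps_b)):
                beta, *_ = np.linalg.lstsq(X, err.to_numpy(), rcond=None)
                acc.append(np.hypot(beta[0], beta[1]))
        return np.asarray(amps_a), np.asarray(amps_b)

    a, b = cycle_amplitudes(sim["err_v1"].to_numpy(), sim["err_ca1"].to_numpy())
    if len(a) < min_cycles:
        raise ValueError(f"need >= {min_cycles} complete cycles, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) cycle amplitudes")
    r = float(np.corrcoef(a, b)[0, 1])
    cells = _condition_cells(
        sim["actual"].to_numpy(), sim["speed"].to_numpy(), length
    )
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        ev, _ = shuffle_within_bins(sim["err_v1"].to_numpy(), cells, rng)
        na, nb = cycle_amplitudes(ev, sim["err_ca1"].to_numpy())
        null[k] = np.corrcoef(na, nb)[0, 1]
    p = (1 + np.sum(null >= r)) / (n_shuffles + 1)
    return r, float(p), len(a), null
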