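"""Session data model and behavioral preprocessing.

Holds the uniformly sampled behavioral state of one recording session and
the spike trains of the recorded units, and implements the behavioral
rules: trial segmentation on the circular track, lick-bout detection,
trial-outcome classification, run-speed gating, and the waveform / depth
rules that assign cell types and cortical layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TrackGeometry, circular_distance

#: waveform trough-to-peak width below which a unit is a putative interneuron
INTERNEURON_WIDTH_US = 600.0

#: cortical depth ranges (um, half-open) for putative V1 layers
LAYER_BOUNDS = {"L2-4": (250.0, 500.0), "L5": (500.0, 700.0), "L6": (700.0, 950.0)}

#: run-speed threshold (cm/s); analyses use only samples faster than this
SPEED_THRESHOLD_CM_S = 5.0


@dataclass
class SessionTimeline:
    """Uniformly sampled behavioral state (60 Hz by default).

    ``position`` is the 200-cm main-track coordinate; ``corridor_id``
    tells which of the two identical semicircular corridors the animal is
    in, so ``position + 200 * corridor_id`` is the 400-cm loop coordinate.
    """

    time: np.ndarray
    position: np.ndarray
    corridor_id: np.ndarray
    wheel: np.ndarray
    speed: np.ndarray
    gain: np.ndarray
    trial_id: np.ndarray
    lick: np.ndarray
    reward: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    sample_rate: float = 60.0
    geometry: TrackGeometry = field(default_factory=TrackGeometry)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("position", "corridor_id", "wheel", "speed", "gain",
                     "trial_id", "lick", "reward"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"timeline field {name!r} has wrong length")
        if n > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-6:
                raise ValueError("time must be strictly increasing with constant step")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def loop_position(self) -> np.ndarray:
        """Position on the full 400-cm loop (two corridors unrolled)."""
        return self.position + self.geometry.corridor_length * self.corridor_id

    def sample_of_time(self, t) -> np.ndarray:
        """Index of the sample containing time ``t`` (clipped to range)."""
        idx = np.floor((np.asarray(t, dtype=float) - self.time[0]) * self.sample_rate)
        return np.clip(idx.astype(int), 0, self.n_samples - 1)


@dataclass
class SpikeTrainSet:
    """Spike times per neuron plus unit metadata.

    ``meta`` has one row per neuron: neuron_id, region (CA1/V1), depth_um,
    waveform_us, and the derived cell_type and layer columns.
    """

    spike_times: list[np.ndarray]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.spike_times) != len(self.meta):
            raise ValueError("spike_times and meta length mismatch")
        if "cell_type" not in self.meta.columns:
            self.meta = self.meta.copy()
            self.meta["cell_type"] = [
                classify_cell_type(w) for w in self.meta["waveform_us"]
            ]
            self.meta["layer"] = [assign_layer(d) for d in self.meta["depth_um"]]

    def __len__(self) -> int:
        return len(self.spike_times)

    def region_index(self, region: str) -> np.ndarray:
        return np.flatnonzero((self.meta["region"] == region).to_numpy())

    def subset(self, indices) -> "SpikeTrainSet":
        indices = np.asarray(indices, dtype=int)
        return SpikeTrainSet(
            [self.spike_times[i] for i in indices],
            self.meta.iloc[indices].reset_index(drop=True),
        )


def classify_cell_type(width_us: float) -> str:
    """Putative interneuron iff trough-to-peak width < 600 us (strict)."""
    if width_us <= 0:
        raise ValueError("waveform width must be positive")
    return "interneuron" if width_us < INTERNEURON_WIDTH_US else "pyramidal"


def assign_layer(depth_um: float) -> str:
    """Putative V1 layer from recording depth; outside all bins -> 'none'."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    for layer, (lo, hi) in LAYER_BOUNDS.items():
        if lo <= depth_um < hi:
            return layer
    return "none"


def speed_mask(speed: np.ndarray, threshold: float = SPEED_THRESHOLD_CM_S) -> np.ndarray:
    """True where run speed strictly exceeds the gating threshold."""
    return np.asarray(speed, dtype=float) > threshold


def compute_speed(wheel: np.ndarray, sample_rate: float, boxcar_s: float = 0.25) -> np.ndarray:
    """Run speed (cm/s) from cumulative wheel distance.

    Wheel displacement per sample is smoothed with a boxcar window before
    differentiation-by-sample-rate, suppressing encoder quantization.
    """
    wheel = np.asarray(wheel, dtype=float)
    disp = np.diff(wheel, prepend=wheel[0])
    width = max(1, int(round(boxcar_s * sample_rate)))
    kernel = np.ones(width) / width
    # reflected edges: same length output, no phase shift for odd widths
    padded = np.pad(disp, (width // 2, width - 1 - width // 2), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return smoothed * sample_rate


def segment_trials(timeline: SessionTimeline, min_progress_cm: float = 50.0) -> pd.DataFrame:
    """One trial per 200-cm traversal, boundaries at crossings of position 0.

    A crossing only opens a new trial after at least ``min_progress_cm`` of
    forward progress since the previous boundary, so brief backward jitter
    across the 0-line is not double counted.

    Returns a table (trial_id, gain, t_start, t_end, i_start, i_end,
    corridor_id) with half-open sample ranges [i_start, i_end).
    Raises if gain is not constant within a candidate trial.
    """
    n = timeline.n_samples
    cols = ["trial_id", "gain", "t_start", "t_end", "i_start", "i_end", "corridor_id"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    L = timeline.geometry.corridor_length
    pos = timeline.position
    # unwrapped absolute position; a trial boundary is a forward crossing
    # of position 0, i.e. an increment of the integer lap index
    dpos = circular_distance(pos[1:], pos[:-1], L)
    travel = pos[0] + np.concatenate([[0.0], np.cumsum(dpos)])
    lap = np.floor(travel / L + 1e-9).astype(int)

    boundaries = [0]
    last_lap = lap[0]
    for i in range(1, n):
        if lap[i] > last_lap and travel[i] - travel[boundaries[-1]] >= min_progress_cm:
            boundaries.append(i)
            last_lap = lap[i]
    boundaries.append(n)

    rows = []
    for k in range(len(boundaries) - 1):
        i0, i1 = boundaries[k], boundaries[k + 1]
        g = timeline.gain[i0:i1]
        if np.ptp(g) > 1e-9:
            raise ValueError(f"gain not constant within trial {k}")
        rows.append(
            (k, float(g[0]), float(timeline.time[i0]),
             float(timeline.time[i1 - 1] + timeline.dt), i0, i1,
             int(timeline.corridor_id[i0]))
        )
    return pd.DataFrame(rows, columns=cols)


def detect_lick_bouts(
    lick_positions: np.ndarray,
    lick_trials: np.ndarray,
    lick_rewarded: np.ndarray,
    geometry: TrackGeometry,
    max_gap_cm: float = 20.0,
) -> pd.DataFrame:
    """Group licks into bouts: consecutive licks < 20 cm apart share a bout.

    Gaps are circular distances on the main track; bouts never span trials.
    A bout is "correct" iff it overlaps the reward zone and contained a
    lick that triggered reward delivery.

    Returns a table (bout_id, trial_id, position, n_licks, correct) where
    ``position`` is the first lick of the bout.
    """
    lick_positions = np.asarray(lick_positions, dtype=float)
    lick_trials = np.asarray(lick_trials, dtype=int)
    lick_rewarded = np.asarray(lick_rewarded, dtype=bool)
    L = geometry.corridor_length
    rows = []
    bout_id = -1
    prev_pos = prev_trial = None
    for pos, trial, rew in zip(lick_positions, lick_trials, lick_rewarded):
        gap = (
            np.inf
            if prev_pos is None or trial != prev_trial
            else abs(circular_distance(pos, prev_pos, L))
        )
        if gap >= max_gap_cm:
            bout_id += 1
            rows.append([bout_id, trial, pos, 0, False, False])
        rows[-1][3] += 1
        in_zone = abs(circular_distance(pos, geometry.reward_center, L)) <= geometry.reward_halfwidth
        rows[-1][4] = rows[-1][4] or in_zone
        rows[-1][5] = rows[-1][5] or bool(rew)
        prev_pos, prev_trial = pos, trial
    df = pd.DataFrame(rows, columns=["bout_id", "trial_id", "position", "n_licks",
                                     "overlaps_zone", "rewarded"])
    df["correct"] = df["overlaps_zone"] & df["rewarded"]
    return df.drop(columns=["overlaps_zone", "rewarded"])


def licks_from_timeline(timeline: SessionTimeline) -> pd.DataFrame:
    """Flatten per-sample lick counts to one row per lick with position.

    A lick is marked rewarded if reward was delivered in its sample.
    """
    idx = np.flatnonzero(timeline.lick > 0)
    counts = timeline.lick[idx].astype(int)
    rows = np.repeat(idx, counts)
    return pd.DataFrame(
        {
            "time": timeline.time[rows],
            "position": timeline.position[rows],
            "trial_id": timeline.trial_id[rows],
            "rewarded": timeline.reward[rows].astype(bool),
        }
    )


def classify_trials(bouts: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Label each trial correct / early / late.

    Rewarded trials with < 5 incorrect licks are correct (exactly 5 is
    still correct when rewarded — the stated rules leave 5 open).  Trials
    with > 5 incorrect licks are "early" if the previous trial was
    correct, otherwise "late".  Remaining unrewarded trials are "late".
    """
    out = []
    prev_correct = True
    for trial_id in trials["trial_id"]:
        tb = bouts[bouts["trial_id"] == trial_id]
        rewarded = bool(tb["correct"].any())
        n_incorrect = int(tb.loc[~tb["correct"], "n_licks"].sum())
        if rewarded and n_incorrect <= 5:
            outcome = "correct"
        elif n_incorrect > 5:
            outcome = "early" if prev_correct else "late"
        else:
            outcome = "late"
        out.append(outcome)
        prev_correct = outcome == "correct"
    result = trials.copy()
    result["outcome"] = out
    return result
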