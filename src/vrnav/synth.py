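"""Synthetic virtual-navigation sessions with known ground truth.

Emulates the study conditions this package analyzes: a mouse running on a
wheel through a circular 200-cm corridor (two identical semicircular
corridors forming a 400-cm loop), gain manipulations applied in blocks of
5-10 trials at gains {0.8, 1.0, 1.2}, licking for reward around landmark
L1, 6-9 Hz theta, and place cells in CA1 and V1 whose firing position
interpolates between visual anchoring and wheel-distance anchoring.

Every neuron is generated from an explicit :class:`NeuronGroundTruth`, so
downstream estimators (gain shift, theta modulation index, precession
drift, decoder bias, GLM latency) can be checked against the parameters
that produced the spikes.

Generative model per neuron
---------------------------
On a gain-g trial the place field is a circular Gaussian bump centered at

    c_g = anchor + D * (w * g + (1 - w))

so the visual-coordinate field shift relative to medium gain is
``w * (g - 1) * D``: a purely visual cell (w = 0) never moves, a purely
distance-anchored cell (w = 1) moves with the physical distance run since
its anchor landmark.  Theta enters twice: a multiplicative sinusoidal rate
modulation of depth ``m`` (preferred phase ``theta_pref``), and a phase
precession term that moves the field center forward by
``A * sin(theta - theta0)`` — the field is maximally ahead at
``theta0 + 90`` degrees and crosses from behind to ahead at ``theta0``.
Spikes are drawn from the resulting inhomogeneous Poisson intensity by
thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import TrackGeometry, circular_distance
from .session import SessionTimeline, SpikeTrainSet, compute_speed


@dataclass(frozen=True)
class GeneratorConfig:
    """Session-level parameters of the generator.

    Defaults reproduce the study conditions: 200-cm corridor, landmarks at
    0/83/117 cm, reward zone L1 +/- 12 cm, gains {0.8, 1.0, 1.2} in blocks
    of 5-10 trials, 60-Hz sampling and 6-9 Hz theta.
    """

    corridor_length: float = 200.0
    landmark_positions: tuple[float, ...] = (0.0, 83.0, 117.0)
    reward_halfwidth: float = 12.0
    gains: tuple[float, ...] = (0.8, 1.0, 1.2)
    gain_block_range: tuple[int, int] = (5, 10)
    n_trials: int = 60
    sample_rate: float = 60.0
    theta_freq: float = 8.0
    theta_band: tuple[float, float] = (6.0, 9.0)
    n_ca1: int = 40
    n_v1: int = 30
    seed: int = 0
    # locomotion (free parameters of the generator, see docs/methods.md)
    speed_mean: float = 25.0
    speed_sd: float = 7.0
    speed_tau: float = 2.0
    pause_rate_hz: float = 0.02
    pause_duration_s: float = 1.5
    # licking behavior
    lick_rate_hz: float = 6.0
    lick_zone_extent: float = 14.0
    lick_shift_per_unit_gain: float = 12.5
    stray_lick_rate_hz: float = 0.03
    error_trial_prob: float = 0.08
    # shared/region error processes for V1-CA1 coupling experiments
    common_error_sd: float = 0.0
    common_error_tau: float = 0.5
    region_error_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.corridor_length <= 0 or self.sample_rate <= 0:
            raise ValueError("corridor_length and sample_rate must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.gains or any(g <= 0 for g in self.gains):
            raise ValueError("gains must be a non-empty list of positive values")
        for lm in self.landmark_positions:
            if not (0 <= lm < self.corridor_length):
                raise ValueError("landmarks must lie in [0, corridor_length)")

    @property
    def geometry(self) -> TrackGeometry:
        return TrackGeometry(
            corridor_length=self.corridor_length,
            landmarks=tuple(self.landmark_positions),
            reward_center=self.landmark_positions[0],
            reward_halfwidth=self.reward_halfwidth,
        )


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generative parameters of one synthetic neuron."""

    region: str  # "CA1" | "V1"
    anchor_cm: float  # anchoring landmark position
    anchor_distance_cm: float  # D: field distance past the anchor at g=1
    field_width_cm: float
    peak_rate_hz: float
    baseline_rate_hz: float
    distance_weight: float  # w in [0, 1]
    theta_pref_phase_deg: float
    theta_mod_depth: float  # m in [0, 1)
    precession_amplitude_cm: float  # A >= 0
    precession_offset_deg: float  # theta0
    depth_um: float
    waveform_us: float
    response_latency_s: float = 0.0
    speed_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_rate_hz < 0 or self.baseline_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.distance_weight <= 1:
            raise ValueError("distance_weight must be in [0, 1]")
        if not 0 <= self.theta_mod_depth < 1:
            raise ValueError("theta_mod_depth must be in [0, 1)")
        if self.precession_amplitude_cm < 0:
            raise ValueError("precession amplitude must be non-negative")

    def field_center(self, gain: float) -> float:
        """Visual-coordinate field center on a gain-``gain`` trial."""
        w = self.distance_weight
        return self.anchor_cm + self.anchor_distance_cm * (w * gain + (1 - w))


@dataclass
class Session:
    """A complete synthetic session: behavior, LFP, spikes, ground truth."""

    timeline: SessionTimeline
    spikes: SpikeTrainSet
    lfp: np.ndarray
    theta_phase: np.ndarray  # true generator phase, deg in [0, 360)
    ground_truth: pd.DataFrame
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# trajectory


def _gain_schedule(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-trial gains in blocks of 5-10 trials.

    Blocks alternate between medium gain (1.0 if present, else the first
    listed gain) and the other gains in random order, mirroring sessions
    where roughly a third of trials carry a manipulated gain.
    """
    gains = list(config.gains)
    medium = 1.0 if 1.0 in gains else gains[0]
    others = [g for g in gains if g != medium] or [medium]
    lo, hi = config.gain_block_range
    schedule: list[float] = []
    manipulated = rng.permutation(others).tolist()
    k = 0
    use_medium = True
    while len(schedule) < config.n_trials:
        block = int(rng.integers(lo, hi + 1))
        if use_medium:
            g = medium
        else:
            g = manipulated[k % len(manipulated)]
            k += 1
            if k % len(manipulated) == 0:
                manipulated = rng.permutation(others).tolist()
        schedule.extend([g] * block)
        use_medium = not use_medium
    return np.asarray(schedule[: config.n_trials])


def _speed_trace(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck run speed with occasional pause epochs, >= 0."""
    dt = 1.0 / config.sample_rate
    tau, sd = config.speed_tau, config.speed_sd
    target = np.full(n, config.speed_mean)
    # pause epochs: the target speed drops near zero for ~pause_duration
    n_pause = max(1, int(config.sample_rate * config.pause_duration_s))
    starts = np.flatnonzero(rng.random(n) < config.pause_rate_hz * dt)
    for s in starts:
        target[s : s + n_pause] = 1.0
    v = np.empty(n)
    v[0] = max(0.0, config.speed_mean + sd * rng.standard_normal())
    noise = sd * np.sqrt(2 * dt / tau) * rng.standard_normal(n)
    for i in range(1, n):
        v[i] = v[i - 1] + (target[i] - v[i - 1]) * dt / tau + noise[i]
        if v[i] < 0:
            v[i] = 0.0
    return v


def generate_trajectory(config: GeneratorConfig, seed: int | None = None) -> SessionTimeline:
    """Simulate wheel running, gain-coupled virtual position, licks, rewards.

    Within each trial the virtual displacement per sample is exactly
    ``gain * wheel displacement``; the gain switches only at trial
    boundaries (crossings of position 0) following the block schedule.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trial_gains = _gain_schedule(config, rng)
    L = config.corridor_length
    dt = 1.0 / config.sample_rate
    # generous speed trace: mean lap needs L / (g_min * mean speed)
    est = int(config.n_trials * L / (min(config.gains) * config.speed_mean) / dt * 1.8) + 1000
    speed = _speed_trace(est, config, rng)

    pos = np.empty(est)
    wheel = np.empty(est)
    gain_arr = np.empty(est)
    trial_arr = np.empty(est, dtype=int)
    travel = 0.0  # cumulative virtual distance
    w_acc = 0.0
    trial = 0
    n_used = est
    for i in range(est):
        g = trial_gains[trial]
        w_acc += speed[i] * dt
        travel += g * speed[i] * dt
        # the crossing sample opens the next trial (gain switches with it;
        # its displacement still used the old gain — sub-sample ambiguity)
        if travel >= (trial + 1) * L:
            trial += 1
            if trial >= config.n_trials:
                n_used = i
                break
        wheel[i] = w_acc
        pos[i] = travel % L
        gain_arr[i] = trial_gains[trial]
        trial_arr[i] = trial
    pos, wheel, gain_arr, trial_arr = (
        a[:n_used] for a in (pos, wheel, gain_arr, trial_arr)
    )
    speed = speed[:n_used]
    time = np.arange(n_used) * dt
    # one trial per lap, so corridor identity alternates with trial parity
    corridor_id = (trial_arr % 2).astype(int)

    lick, reward = _licks_and_rewards(
        time, pos, trial_arr, gain_arr, config, rng
    )
    covariates = _behavioral_covariates(speed, config, rng)
    return SessionTimeline(
        time=time,
        position=pos,
        corridor_id=corridor_id,
        wheel=wheel,
        speed=speed,
        gain=gain_arr,
        trial_id=trial_arr,
        lick=lick,
        reward=reward.astype(bool),
        covariates=covariates,
        sample_rate=config.sample_rate,
        geometry=config.geometry,
    )


def _licks_and_rewards(time, pos, trial_arr, gain_arr, config, rng):
    """Lick bouts concentrated around the reward zone, shifted per gain.

    The behavioral shift mirrors the measured lick shifts: the lick zone
    moves by ``lick_shift_per_unit_gain * (gain - 1)`` cm, i.e. the animal
    licks earlier at low gain and later at high gain.  A small fraction of
    trials carry an extra early bout (> 5 licks) away from the reward
    zone, producing early/late outcome labels downstream.
    """
    n = len(time)
    dt = 1.0 / config.sample_rate
    L = config.corridor_length
    geom = config.geometry
    lick = np.zeros(n, dtype=int)
    reward = np.zeros(n, dtype=bool)
    zone_center = geom.reward_center + config.lick_shift_per_unit_gain * (gain_arr - 1.0)
    # anticipatory licking starts slightly before the (shifted) zone center
    d = circular_distance(pos, zone_center - 4.0, L)
    in_zone = np.abs(d) <= config.lick_zone_extent
    p_lick = np.where(in_zone, config.lick_rate_hz * dt, config.stray_lick_rate_hz * dt)
    lick += rng.random(n) < p_lick

    # deliberate error bouts on a fraction of trials
    n_trials = int(trial_arr.max()) + 1
    err_trials = np.flatnonzero(rng.random(n_trials) < config.error_trial_prob)
    for t in err_trials:
        idx = np.flatnonzero(trial_arr == t)
        if len(idx) < 20:
            continue
        bout_pos = rng.uniform(40.0, 70.0)
        near = idx[np.abs(circular_distance(pos[idx], bout_pos, L)) < 8.0]
        if len(near) >= 6:
            lick[near[:8]] += 1

    # reward: first lick inside the true reward zone per trial
    in_reward = np.abs(circular_distance(pos, geom.reward_center, L)) <= geom.reward_halfwidth
    lick_idx = np.flatnonzero((lick > 0) & in_reward)
    rewarded_trials: set[int] = set()
    for i in lick_idx:
        t = trial_arr[i]
        if t not in rewarded_trials:
            rewarded_trials.add(t)
            reward[i] = True
    return lick, reward


def _behavioral_covariates(speed, config, rng):
    """Pupil size / azimuth / elevation: low-passed noise, size speed-coupled."""
    from scipy.ndimage import gaussian_filter1d

    n = len(speed)
    smooth = lambda x, sd_s: gaussian_filter1d(x, sd_s * config.sample_rate, mode="nearest")
    speed_z = (speed - speed.mean()) / (speed.std() + 1e-12)
    covs = {
        "pupil_size": 0.5 * smooth(speed_z, 0.5) + smooth(rng.standard_normal(n), 1.0) * 3.0,
        "pupil_az": smooth(rng.standard_normal(n), 0.8) * 4.0,
        "pupil_el": smooth(rng.standard_normal(n), 0.8) * 4.0,
    }
    return covs


# ---------------------------------------------------------------------------
# theta


def generate_theta(
    config: GeneratorConfig, timeline: SessionTimeline, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous theta phase (deg) and a synthetic LFP trace.

    The instantaneous frequency wanders within the 6-9 Hz band (clipped
    Ornstein-Uhlenbeck around ``theta_freq``); phase advances monotonically
    modulo 360 and the LFP is a cosine of the phase plus broadband noise,
    so band-passed LFP peaks fall at phase 0 before any re-centering.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 101)
    n = timeline.n_samples
    dt = timeline.dt
    lo, hi = config.theta_band
    tau = 1.0
    f = np.empty(n)
    f[0] = config.theta_freq
    noise = 0.35 * np.sqrt(2 * dt / tau) * rng.standard_normal(n)
    for i in range(1, n):
        f[i] = f[i - 1] + (config.theta_freq - f[i - 1]) * dt / tau + noise[i]
    # keep strictly inside the band so every cycle is 6-9 Hz
    f = np.clip(f, lo + 0.05, hi - 0.05)
    phase = (np.cumsum(f) * dt * 360.0) % 360.0
    lfp = np.cos(np.deg2rad(phase)) + 0.25 * rng.standard_normal(n)
    return phase, lfp


# ---------------------------------------------------------------------------
# spikes


def _circular_gaussian_bump(delta: np.ndarray, width: float) -> np.ndarray:
    """Unit-peak wrapped Gaussian of s.d. ``width`` at circular offset delta."""
    return np.exp(-0.5 * (delta / width) ** 2)


def neuron_intensity(
    neuron: NeuronGroundTruth,
    timeline: SessionTimeline,
    theta_phase: np.ndarray,
    common_offset: np.ndarray | None = None,
    region_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample Poisson intensity lambda(t) in Hz (non-negative)."""
    L = timeline.geometry.corridor_length
    pos = timeline.position
    if neuron.response_latency_s > 0:
        shift = int(round(neuron.response_latency_s * timeline.sample_rate))
        pos = np.concatenate([np.full(shift, pos[0]), pos[:-shift]]) if shift else pos
    x_app = pos.copy()
    if common_offset is not None:
        x_app = x_app + common_offset
    if region_offset is not None:
        x_app = x_app + region_offset
    theta = np.deg2rad(theta_phase)
    centers = neuron.anchor_cm + neuron.anchor_distance_cm * (
        neuron.distance_weight * timeline.gain + (1 - neuron.distance_weight)
    )
    prec = neuron.precession_amplitude_cm * np.sin(theta - np.deg2rad(neuron.precession_offset_deg))
    delta = circular_distance(x_app - prec, centers, L)
    lam = neuron.baseline_rate_hz + neuron.peak_rate_hz * _circular_gaussian_bump(
        delta, neuron.field_width_cm
    )
    lam = lam * (1.0 + neuron.theta_mod_depth * np.cos(theta - np.deg2rad(neuron.theta_pref_phase_deg)))
    if neuron.speed_coef != 0.0:
        v = timeline.speed / max(timeline.speed.mean(), 1e-9)
        lam = lam * np.clip(1.0 + neuron.speed_coef * (v - 1.0), 0.0, 3.0)
    assert np.all(lam >= 0), "intensity must be non-negative by construction"
    return lam


def _thin_poisson(
    lam_grid: np.ndarray, time: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning a homogeneous train."""
    lam_max = float(lam_grid.max()) * 1.0001 + 1e-9
    duration = time[-1] - time[0] + (time[1] - time[0] if len(time) > 1 else 0.0)
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(time[0], time[0] + duration, n_cand))
    lam_at = np.interp(t_cand, time, lam_grid)
    keep = rng.uniform(0, lam_max, n_cand) < lam_at
    return t_cand[keep]


def simulate_spikes(
    timeline: SessionTimeline,
    theta_phase: np.ndarray,
    neurons: list[NeuronGroundTruth],
    seed: int,
    common_offset: np.ndarray | None = None,
    region_offsets: dict[str, np.ndarray] | None = None,
) -> SpikeTrainSet:
    """Sample spike trains for a population of ground-truth neurons."""
    if not neurons:
        raise ValueError("neurons must be non-empty")
    seeds = np.random.SeedSequence(seed).spawn(len(neurons))
    spike_times = []
    for neuron, ss in zip(neurons, seeds):
        rng = np.random.default_rng(ss)
        reg = None if region_offsets is None else region_offsets.get(neuron.region)
        lam = neuron_intensity(neuron, timeline, theta_phase, common_offset, reg)
        spike_times.append(_thin_poisson(lam, timeline.time, rng))
    meta = pd.DataFrame(
        {
            "neuron_id": np.arange(len(neurons)),
            "region": [nrn.region for nrn in neurons],
            "depth_um": [nrn.depth_um for nrn in neurons],
            "waveform_us": [nrn.waveform_us for nrn in neurons],
        }
    )
    return SpikeTrainSet(spike_times, meta)


# ---------------------------------------------------------------------------
# populations and full sessions


def default_population(config: GeneratorConfig, rng: np.random.Generator) -> list[NeuronGroundTruth]:
    """A study-like mixed population of CA1 and V1 neurons.

    CA1: strongly theta-modulated place cells (m ~ 0.6), classic
    precession (A ~ 5 cm, offset ~ 200 deg).  V1: weaker theta coupling
    (m ~ 0.15) and smaller drift in the opposite-offset regime
    (270-360 deg).  Distance weights are drawn across [0, 0.8] so the
    population carries both visually-anchored and distance-anchored cells.
    """
    neurons = []
    L = config.corridor_length
    landmarks = np.asarray(config.landmark_positions)
    for i in range(config.n_ca1 + config.n_v1):
        is_ca1 = i < config.n_ca1
        center = rng.uniform(0, L)
        gaps = circular_distance(center, landmarks, L)
        anchor_idx = int(np.argmin(np.where(gaps >= 0, gaps, np.inf)))
        anchor = float(landmarks[anchor_idx])
        D = float(circular_distance(center, anchor, L) % L)
        pyramidal = rng.random() < 0.8
        neurons.append(
            NeuronGroundTruth(
                region="CA1" if is_ca1 else "V1",
                anchor_cm=anchor,
                anchor_distance_cm=D,
                field_width_cm=rng.uniform(12, 22),
                peak_rate_hz=rng.uniform(6, 14),
                baseline_rate_hz=rng.uniform(0.2, 0.8),
                distance_weight=float(np.clip(rng.uniform(0, 0.8), 0, 1)),
                theta_pref_phase_deg=float(rng.uniform(0, 360)),
                theta_mod_depth=(0.6 if is_ca1 else 0.15) * rng.uniform(0.7, 1.2),
                precession_amplitude_cm=(5.0 if is_ca1 else 2.0) * rng.uniform(0.6, 1.2),
                precession_offset_deg=float(
                    (rng.normal(200, 25) if is_ca1 else rng.uniform(270, 360)) % 360
                ),
                depth_um=float(rng.uniform(1200, 1600) if is_ca1 else rng.uniform(250, 950)),
                waveform_us=float(rng.uniform(650, 900) if pyramidal else rng.uniform(300, 550)),
            )
        )
    return neurons


def _ou_offset(n: int, sd: float, tau: float, dt: float, rng) -> np.ndarray:
    """Zero-mean OU process used as a shared position-error drive."""
    if sd <= 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    noise = sd * np.sqrt(2 * dt / tau) * rng.standard_normal(n)
    for i in range(1, n):
        x[i] = x[i - 1] * (1 - dt / tau) + noise[i]
    return x


def generate_session(
    config: GeneratorConfig,
    neurons: list[NeuronGroundTruth] | None = None,
) -> Session:
    """Full deterministic session: trajectory, theta, spikes, ground truth."""
    rng = np.random.default_rng(config.seed)
    timeline = generate_trajectory(config, config.seed)
    theta_phase, lfp = generate_theta(config, timeline, config.seed)
    if neurons is None:
        neurons = default_population(config, np.random.default_rng(config.seed + 7))
    n = timeline.n_samples
    common = _ou_offset(
        n, config.common_error_sd, config.common_error_tau, timeline.dt,
        np.random.default_rng(config.seed + 11),
    )
    region_offsets = {
        reg: _ou_offset(
            n, config.region_error_sd, config.common_error_tau, timeline.dt,
            np.random.default_rng(config.seed + 13 + k),
        )
        for k, reg in enumerate(("CA1", "V1"))
    }
    spikes = simulate_spikes(
        timeline, theta_phase, neurons, config.seed + 23,
        common_offset=common if config.common_error_sd > 0 else None,
        region_offsets=region_offsets if config.region_error_sd > 0 else None,
    )
    gt = pd.DataFrame([asdict(nrn) for nrn in neurons])
    gt.insert(0, "neuron_id", np.arange(len(neurons)))
    return Session(
        timeline=timeline,
        spikes=spikes,
        lfp=lfp,
        theta_phase=theta_phase,
        ground_truth=gt,
        config=config,
    )
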