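"""Shared fixtures: small deterministic synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from vrnav.session import (
    SessionTimeline,
    classify_trials,
    detect_lick_bouts,
    licks_from_timeline,
    segment_trials,
    speed_mask,
)
from vrnav.synth import GeneratorConfig, NeuronGroundTruth, generate_session


def make_neuron(**overrides) -> NeuronGroundTruth:
    """A well-behaved CA1 place cell; overrides tweak single parameters."""
    params = dict(
        region="CA1",
        anchor_cm=0.0,
        anchor_distance_cm=50.0,
        field_width_cm=18.0,
        peak_rate_hz=12.0,
        baseline_rate_hz=0.3,
        distance_weight=0.0,
        theta_pref_phase_deg=180.0,
        theta_mod_depth=0.0,
        precession_amplitude_cm=0.0,
        precession_offset_deg=0.0,
        depth_um=1400.0,
        waveform_us=800.0,
    )
    params.update(overrides)
    return NeuronGroundTruth(**params)


def preprocess(session):
    """Trials with outcomes, lick bouts and the speed mask for a session."""
    tl = session.timeline
    trials = segment_trials(tl)
    licks = licks_from_timeline(tl)
    bouts = detect_lick_bouts(
        licks["position"].to_numpy(),
        licks["trial_id"].to_numpy(),
        licks["rewarded"].to_numpy(),
        tl.geometry,
    )
    trials = classify_trials(bouts, trials)
    return trials, bouts, speed_mask(tl.speed)


@pytest.fixture(scope="session")
def small_session():
    """40-trial mixed-population session used by several modules."""
    cfg = GeneratorConfig(n_trials=40, n_ca1=6, n_v1=4, seed=42)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_session_prep(small_session):
    trials, bouts, mask = preprocess(small_session)
    return small_session, trials, bouts, mask


def flat_timeline(
    positions: np.ndarray,
    sample_rate: float = 60.0,
    corridor_length: float = 200.0,
    speed_value: float = 20.0,
    **geometry_kwargs,
) -> SessionTimeline:
    """Hand-built timeline with the given position trace (for toy oracles)."""
    from vrnav.geometry import TrackGeometry

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    geom = TrackGeometry(corridor_length=corridor_length, **geometry_kwargs)
    return SessionTimeline(
        time=np.arange(n) / sample_rate,
        position=positions % corridor_length,
        corridor_id=np.zeros(n, dtype=int),
        wheel=np.cumsum(np.full(n, speed_value / sample_rate)),
        speed=np.full(n, speed_value),
        gain=np.ones(n),
        trial_id=np.zeros(n, dtype=int),
        lick=np.zeros(n, dtype=int),
        reward=np.zeros(n, dtype=bool),
        covariates={},
        sample_rate=sample_rate,
        geometry=geom,
    )
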