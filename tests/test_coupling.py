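"""V1-CA1 decoding-error coupling beyond position and speed."""

import numpy as np
import pandas as pd
import pytest

from vrnav.coupling import (
    cycle_modulation_correlation,
    joint_error_map,
    mismatch_distribution,
    shuffle_within_bins,
    simultaneous_errors,
    split_thirds_control,
)
from vrnav.decoding import decode_session
from vrnav.session import speed_mask
from vrnav.synth import GeneratorConfig, generate_session

from conftest import preprocess


def coupled_session(common_sd, seed):
    cfg = GeneratorConfig(
        n_trials=50, n_ca1=22, n_v1=22, seed=seed, common_error_sd=common_sd
    )
    session = generate_session(cfg)
    trials, _, mask = preprocess(session)
    medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
    out = {}
    for region in ("CA1", "V1"):
        idx = session.spikes.region_index(region)
        out[region] = decode_session(
            [session.spikes.spike_times[i] for i in idx],
            session.timeline, trials, medium["trial_id"].to_numpy(), mask=mask,
            min_neurons=10,
        )
    sim = simultaneous_errors(
        out["V1"], out["CA1"],
        correct_trial_ids=trials.loc[trials["outcome"] == "correct", "trial_id"],
    )
    return session, trials, mask, sim


@pytest.fixture(scope="module")
def shared_noise():
    return coupled_session(6.0, seed=61)


@pytest.fixture(scope="module")
def independent_noise():
    return coupled_session(0.0, seed=62)


class TestShuffle:
    def test_marginals_preserved_per_cell(self):
        rng = np.random.default_rng(0)
        err = rng.normal(0, 10, 500)
        cells = rng.integers(0, 40, 500)
        shuffled, singles = shuffle_within_bins(err, cells, rng)
        for c in np.unique(cells):
            assert sorted(err[cells == c]) == pytest.approx(
                sorted(shuffled[cells == c])
            )

    def test_singleton_cells_left_fixed_and_counted(self):
        rng = np.random.default_rng(1)
        err = np.array([1.0, 2.0, 3.0])
        cells = np.array([0, 0, 5])
        shuffled, singles = shuffle_within_bins(err, cells, rng)
        assert singles == 1 and shuffled[2] == 3.0

    def test_zero_shuffles_rejected(self, independent_noise):
        _, _, _, sim = independent_noise
        with pytest.raises(ValueError):
            joint_error_map(
                sim["err_v1"].to_numpy(), sim["err_ca1"].to_numpy(),
                sim["actual"].to_numpy(), sim["speed"].to_numpy(), n_shuffles=0,
            )


class TestJointErrorMap:
    def test_map_normalizations(self, independent_noise):
        _, _, _, sim = independent_noise
        jm = joint_error_map(
            sim["err_v1"].to_numpy(), sim["err_ca1"].to_numpy(),
            sim["actual"].to_numpy(), sim["speed"].to_numpy(),
            n_shuffles=20, seed=2,
        )
        assert jm.measured.sum() == pytest.approx(1.0, abs=1e-9)
        assert jm.shuffled.sum() == pytest.approx(1.0, abs=1e-9)
        assert jm.difference.sum() == pytest.approx(0.0, abs=1e-9)

    def test_shared_noise_produces_diagonal_excess(self, shared_noise, independent_noise):
        maps = {}
        for name, bundle in (("shared", shared_noise), ("indep", independent_noise)):
            _, _, _, sim = bundle
            maps[name] = joint_error_map(
                sim["err_v1"].to_numpy(), sim["err_ca1"].to_numpy(),
                sim["actual"].to_numpy(), sim["speed"].to_numpy(),
                n_shuffles=30, seed=3,
            )
        assert maps["shared"].diagonal_excess() > 3 * abs(maps["indep"].diagonal_excess())
        assert maps["shared"].diagonal_excess() > 0.02

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            joint_error_map(
                np.array([1.0]), np.array([1.0]), np.array([5.0]), np.array([10.0])
            )


class TestMismatch:
    def test_identical_decoders_mass_at_zero(self, independent_noise):
        _, _, _, sim = independent_noise
        dec = sim["dec_ca1"].to_numpy()
        out = mismatch_distribution(
            dec, dec, sim["actual"].to_numpy(), sim["speed"].to_numpy(),
            n_shuffles=10, seed=4,
        )
        center = out.loc[out["mismatch_cm"].abs() <= 4.0, "measured"].sum()
        assert center > 0.5

    def test_shared_noise_more_peaked_than_shuffle(self, shared_noise):
        _, _, _, sim = shared_noise
        out = mismatch_distribution(
            sim["dec_v1"].to_numpy(), sim["dec_ca1"].to_numpy(),
            sim["actual"].to_numpy(), sim["speed"].to_numpy(),
            n_shuffles=30, seed=5,
        )
        band = out["mismatch_cm"].abs() <= 10.0
        assert out.loc[band, "difference"].sum() > 0.01


class TestSplitThirds:
    def test_shared_coupling_survives_independent_training(self, shared_noise):
        session, trials, mask, _ = shared_noise
        usable = trials.loc[trials["outcome"] == "correct", "trial_id"].to_numpy()
        idx_v1 = session.spikes.region_index("V1")
        idx_ca1 = session.spikes.region_index("CA1")
        jm = split_thirds_control(
            [session.spikes.spike_times[i] for i in idx_v1],
            [session.spikes.spike_times[i] for i in idx_ca1],
            session.timeline, trials, usable, mask=mask, n_shuffles=30, seed=6,
        )
        assert jm.diagonal_excess() > 0.01

    def test_independent_coupling_vanishes(self, independent_noise):
        session, trials, mask, _ = independent_noise
        usable = trials.loc[trials["outcome"] == "correct", "trial_id"].to_numpy()
        idx_v1 = session.spikes.region_index("V1")
        idx_ca1 = session.spikes.region_index("CA1")
        jm = split_thirds_control(
            [session.spikes.spike_times[i] for i in idx_v1],
            [session.spikes.spike_times[i] for i in idx_ca1],
            session.timeline, trials, usable, mask=mask, n_shuffles=30, seed=7,
        )
        assert abs(jm.diagonal_excess()) < 0.02

    def test_too_few_trials_rejected(self, independent_noise):
        session, trials, mask, _ = independent_noise
        with pytest.raises(ValueError):
            split_thirds_control(
                [session.spikes.spike_times[0]], [session.spikes.spike_times[1]],
                session.timeline, trials, np.array([0, 1]), mask=mask,
            )


class TestCycleModulation:
    def make_sim(self, rho, n_cycles=120, seed=0):
        """Synthetic windows whose per-cycle error amplitude is shared."""
        rng = np.random.default_rng(seed)
        rows = []
        shared = rng.gamma(2.0, 3.0, n_cycles)
        for c in range(n_cycles):
            amp_v1 = rho * shared[c] + (1 - rho) * rng.gamma(2.0, 3.0)
            amp_ca1 = rho * shared[c] + (1 - rho) * rng.gamma(2.0, 3.0)
            phases = rng.uniform(0, 360, 5)
            off = rng.uniform(0, 360)
            for ph in phases:
                rows.append(
                    {
                        "cycle_id": c,
                        "phase": ph,
                        "err_v1": amp_v1 * np.sin(np.deg2rad(ph - off))
                        + rng.normal(0, 0.5),
                        "err_ca1": amp_ca1 * np.sin(np.deg2rad(ph - off))
                        + rng.normal(0, 0.5),
                        "actual": rng.uniform(0, 200),
                        "speed": rng.uniform(10, 30),
                    }
                )
        return pd.DataFrame(rows)

    def test_shared_amplitude_drive_detected(self):
        sim = self.make_sim(rho=1.0, seed=8)
        r, p, n, null = cycle_modulation_correlation(sim, n_shuffles=50, seed=9)
        assert n >= 100 and r > np.percentile(null, 95)

    def test_independent_amplitudes_near_shuffle_level(self):
        sim = self.make_sim(rho=0.0, seed=10)
        r, p, n, null = cycle_modulation_correlation(sim, n_shuffles=50, seed=11)
        assert abs(r) < 0.3

    def test_constant_errors_rejected(self):
        sim = self.make_sim(rho=0.0, seed=12)
        sim["err_v1"] = 0.0
        sim["err_ca1"] = 0.0
        with pytest.raises(ValueError, match="degenerate|constant"):
            cycle_modulation_correlation(sim, n_shuffles=10, seed=13)

    def test_too_few_cycles_rejected(self):
        sim = self.make_sim(rho=0.0, n_cycles=10, seed=14)
        with pytest.raises(ValueError, match="cycles"):
            cycle_modulation_correlation(sim, n_shuffles=10, seed=15)
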