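"""Spatial response profiles, gain shifts, and permutation tests."""

import numpy as np
import pytest

from vrnav.geometry import circular_distance
from vrnav.profiles import (
    ResponseProfile,
    corridor_difference_test,
    estimate_gain_shift,
    gain_shift_significance,
    profile_from_maps,
    profile_significance,
    rate_change_test,
    shift_vs_position_summary,
    spatial_profile,
    variance_explained,
)
from vrnav.session import segment_trials, speed_mask
from vrnav.synth import GeneratorConfig, generate_session

from conftest import flat_timeline, make_neuron


def _profile_of(rate, bin_cm=2.0):
    n = len(rate)
    return ResponseProfile(
        bin_centers=(np.arange(n) + 0.5) * bin_cm,
        rate=np.asarray(rate, dtype=float),
        counts=np.zeros(n),
        occupancy=np.ones(n),
        valid=np.ones(n, dtype=bool),
        bin_cm=bin_cm,
        smooth_sd_cm=8.0,
    )


class TestSpatialProfile:
    def test_three_bin_direct_division_oracle(self):
        # occupancy 1/2/1 s at 60 Hz; 6 spikes in the middle 2-cm bin;
        # with no smoothing the rates are exactly 0 / 3 / 0 Hz
        pos = np.concatenate([np.full(60, 1.0), np.full(120, 3.0), np.full(60, 5.0)])
        tl = flat_timeline(pos, corridor_length=6.0, landmarks=(0.0,), reward_halfwidth=1.0)
        spike_times = tl.time[70:130:10]
        prof = spatial_profile(spike_times, tl, smooth_sd_cm=0.0)
        assert prof.rate == pytest.approx([0.0, 3.0, 0.0])

    def test_zero_spikes_gives_zero_profile(self, small_session_prep):
        session, _, _, mask = small_session_prep
        prof = spatial_profile(np.empty(0), session.timeline, mask)
        assert np.all(prof.rate == 0.0)

    def test_constant_rate_invariance(self):
        # homogeneous Poisson spikes: profile ~ r everywhere
        rng = np.random.default_rng(0)
        pos = (np.arange(120000) * 25.0 / 60.0) % 200.0
        tl = flat_timeline(pos)
        r = 8.0
        n = rng.poisson(r * tl.duration)
        spikes = np.sort(rng.uniform(0, tl.duration, n))
        prof = spatial_profile(spikes, tl)
        assert prof.rate == pytest.approx(r, rel=0.15)

    def test_empty_mask_rejected(self, small_session):
        with pytest.raises(ValueError):
            spatial_profile(
                np.array([1.0]),
                small_session.timeline,
                np.zeros(small_session.timeline.n_samples, dtype=bool),
            )

    def test_smoothed_counts_preserve_total(self):
        counts = np.random.default_rng(1).poisson(2.0, 100).astype(float)
        occ = np.ones(100)
        prof = profile_from_maps(counts, occ, 200.0, 2.0, 8.0)
        assert prof.counts.sum() == pytest.approx(counts.sum())


class TestGainShift:
    def test_identical_profiles_zero_shift(self):
        rate = np.exp(-0.5 * ((np.arange(100) - 40) / 5.0) ** 2)
        res = estimate_gain_shift(_profile_of(rate), _profile_of(rate))
        assert res.shift_cm == 0.0 and res.correlation == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [-7, -3, 1, 3, 12, 50])
    def test_inverse_to_circular_shifting(self, k):
        rng = np.random.default_rng(2)
        rate = np.convolve(rng.random(100), np.ones(5) / 5, mode="same")
        shifted = np.roll(rate, k)  # forward shift by k bins = 2k cm
        res = estimate_gain_shift(_profile_of(shifted), _profile_of(rate))
        expected = circular_distance(2.0 * k, 0.0, 200.0)
        assert res.shift_cm == pytest.approx(expected)
        # brute-force correlation oracle over all offsets
        brute = [
            np.corrcoef(shifted, np.roll(rate, j))[0, 1] for j in range(100)
        ]
        assert res.correlation == pytest.approx(max(brute), abs=1e-9)

    def test_constant_profile_flagged_invalid(self):
        res = estimate_gain_shift(_profile_of(np.ones(100)), _profile_of(np.ones(100)))
        assert not res.valid

    def test_synthetic_distance_cell_recovers_minus_ten(self):
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=21)
        s = generate_session(
            cfg, neurons=[make_neuron(distance_weight=1.0, anchor_distance_cm=50.0)]
        )
        tl = s.timeline
        mask = speed_mask(tl.speed)
        p_low = spatial_profile(s.spikes.spike_times[0], tl, mask & (tl.gain == 0.8))
        p_med = spatial_profile(s.spikes.spike_times[0], tl, mask & (tl.gain == 1.0))
        res = estimate_gain_shift(p_low, p_med)
        assert res.shift_cm == pytest.approx(-10.0, abs=4.0)


class TestVarianceExplained:
    def test_exact_scaling_explains_everything(self):
        rm = np.exp(-0.5 * ((np.arange(100) - 30) / 6.0) ** 2) + 0.1
        static, _ = variance_explained(2.0 * rm, rm, 0.0)
        assert static == pytest.approx(1.0)

    def test_orthogonal_profiles_explain_nothing(self):
        x = np.arange(100) * 2 * np.pi / 100
        static, _ = variance_explained(np.sin(x), np.cos(x), 0.0)
        assert static == pytest.approx(0.0, abs=1e-9)

    def test_shift_recovers_variance(self):
        rng = np.random.default_rng(3)
        rm = np.convolve(rng.random(100), np.ones(7) / 7, mode="same")
        rg = np.roll(rm, 3)  # shifted 6 cm
        static, with_shift = variance_explained(rg, rm, 6.0)
        assert with_shift == pytest.approx(1.0, abs=1e-9)
        assert static < with_shift
        # brute-force sum-of-squares oracle for the static ratio
        alpha = rg @ rm / (rm @ rm)
        expected_static = 1 - np.sum((rg - alpha * rm) ** 2) / np.sum((rg - rg.mean()) ** 2)
        assert static == pytest.approx(expected_static)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(10), np.arange(10.0), 0.0)


class TestPermutationTests:
    def test_strong_place_cell_is_significant(self):
        cfg = GeneratorConfig(n_trials=80, n_ca1=1, n_v1=0, seed=22)
        s = generate_session(cfg, neurons=[make_neuron(peak_rate_hz=10.0, baseline_rate_hz=1.0)])
        mask = speed_mask(s.timeline.speed)
        p, sig, obs, _ = profile_significance(
            s.spikes.spike_times[0], s.timeline, mask, n_shuffles=200, seed=1
        )
        assert sig and p < 0.01

    def test_zero_shuffles_rejected(self, small_session_prep):
        session, _, _, mask = small_session_prep
        with pytest.raises(ValueError):
            profile_significance(
                session.spikes.spike_times[0], session.timeline, mask, n_shuffles=0
            )

    def test_too_short_session_rejected(self):
        tl = flat_timeline(np.arange(0, 120, 2.0))  # one minute worth? 60 samples
        with pytest.raises(ValueError):
            profile_significance(np.array([0.5]), tl, min_shift_s=5.0)

    def test_distance_cell_gain_shift_flagged(self):
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=23)
        s = generate_session(
            cfg, neurons=[make_neuron(distance_weight=1.0, anchor_distance_cm=50.0)]
        )
        trials = segment_trials(s.timeline)
        mask = speed_mask(s.timeline.speed)
        res = gain_shift_significance(
            s.spikes.spike_times[0], s.timeline, trials, gain=0.8,
            mask=mask, n_shuffles=200, seed=2,
        )
        assert res.significant and abs(res.shift_cm + 10.0) <= 4.0

    def test_single_gain_session_rejected(self):
        cfg = GeneratorConfig(n_trials=10, gains=(1.0,), n_ca1=1, n_v1=0, seed=24)
        s = generate_session(cfg, neurons=[make_neuron()])
        trials = segment_trials(s.timeline)
        with pytest.raises(ValueError):
            gain_shift_significance(
                s.spikes.spike_times[0], s.timeline, trials, gain=0.8
            )

    def test_rate_tripling_detected(self):
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=25)
        s = generate_session(cfg, neurons=[make_neuron(speed_coef=0.0)])
        tl = s.timeline
        # amplify spikes on low-gain trials by thinning the rest
        st = s.spikes.spike_times[0]
        idx = tl.sample_of_time(st)
        keep = (tl.gain[idx] == 0.8) | (np.random.default_rng(0).random(len(st)) < 0.3)
        st2 = st[keep]
        p, sig, obs = rate_change_test(
            st2, tl, tl.gain == 0.8, tl.gain == 1.0, n_shuffles=200, seed=3
        )
        assert sig

    def test_zero_spikes_rate_change_not_flagged(self, small_session_prep):
        session, _, _, _ = small_session_prep
        tl = session.timeline
        p, sig, obs = rate_change_test(
            np.empty(0), tl, tl.gain == 0.8, tl.gain == 1.0, n_shuffles=100, seed=4
        )
        assert not sig and obs == 0.0

    def test_corridor_selective_neuron_detected(self):
        cfg = GeneratorConfig(n_trials=80, n_ca1=1, n_v1=0, seed=26)
        s = generate_session(cfg, neurons=[make_neuron()])
        tl = s.timeline
        trials = segment_trials(tl)
        st = s.spikes.spike_times[0]
        # drop half the spikes in corridor 1 -> 2x peak difference
        idx = tl.sample_of_time(st)
        keep = (tl.corridor_id[idx] == 0) | (
            np.random.default_rng(1).random(len(st)) < 0.5
        )
        p, sig, obs = corridor_difference_test(
            st[keep], tl, trials, n_shuffles=200, seed=5
        )
        assert sig

    def test_corridor_identical_tuning_not_flagged(self):
        cfg = GeneratorConfig(n_trials=80, n_ca1=1, n_v1=0, seed=27)
        s = generate_session(cfg, neurons=[make_neuron()])
        trials = segment_trials(s.timeline)
        p, sig, obs = corridor_difference_test(
            s.spikes.spike_times[0], s.timeline, trials, n_shuffles=200, seed=6
        )
        assert p > 0.01 or not sig

    def test_single_corridor_rejected(self):
        tl = flat_timeline(np.arange(0, 200, 2.0))
        trials = segment_trials(tl)
        with pytest.raises(ValueError):
            corridor_difference_test(np.array([1.0]), tl, trials)


class TestShiftSummary:
    def test_all_zero_shifts_give_zero_medians(self):
        out = shift_vs_position_summary(np.zeros(30), np.linspace(0, 199, 30))
        assert (out["median_shift_cm"] == 0.0).all()

    def test_single_neuron_median_is_its_shift(self):
        out = shift_vs_position_summary(np.array([-7.0]), np.array([55.0]))
        assert len(out) == 1 and out["median_shift_cm"].iloc[0] == -7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shift_vs_position_summary(np.empty(0), np.empty(0))

    def test_distance_population_medians_grow_between_landmarks(self):
        # ground-truth curve: shift = w*(g-1)*D with D measured from the
        # last landmark, so medians grow with distance from landmarks
        rng = np.random.default_rng(7)
        landmarks = np.array([0.0, 83.0, 117.0])
        pos = rng.uniform(0, 200, 300)
        gaps = [
            min((p - lm) % 200.0 for lm in landmarks) for p in pos
        ]
        shifts = -0.2 * np.asarray(gaps)  # w=1, g=0.8
        out = shift_vs_position_summary(shifts, pos)
        near = out[out["position_cm"].isin([10.0, 90.0, 130.0])]["median_shift_cm"]
        far = out[out["position_cm"].isin([70.0, 190.0])]["median_shift_cm"]
        assert near.abs().mean() < far.abs().mean()
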