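"""Theta phase statistics: modulation index, PPC, precession, circular tests."""

import numpy as np
import pytest

from vrnav.session import speed_mask
from vrnav.synth import GeneratorConfig, generate_session
from vrnav.theta import (
    ThetaPhaseSeries,
    circular_median_test,
    extract_theta_phase,
    field_extent_mask,
    fit_drift_sinusoid,
    layer_fraction_test,
    linear_circular_correlation,
    phase_position_profile,
    ppc,
    precession_significance,
    rayleigh_test,
    spike_phases,
    theta_rate_profile,
    theta_significance,
)

from conftest import make_neuron


def sinusoidal_phases(m, n, rng, pref_deg=180.0):
    """Phases drawn from density proportional to 1 + m*cos(theta - pref)."""
    out = np.empty(0)
    while len(out) < n:
        th = rng.uniform(0, 360, 4 * n)
        keep = rng.uniform(0, 1 + m, 4 * n) < 1 + m * np.cos(np.deg2rad(th - pref_deg))
        out = np.concatenate([out, th[keep]])
    return out[:n]


def true_phase_series(session):
    n = session.timeline.n_samples
    return ThetaPhaseSeries(
        phase=session.theta_phase,
        cycle_id=np.zeros(n, dtype=int),
        valid=np.ones(n, dtype=bool),
    )


class TestPpc:
    def test_identical_phases_give_one(self):
        assert ppc(np.full(10, 123.0)) == pytest.approx(1.0)

    def test_two_antipodal_spikes_give_minus_one(self):
        assert ppc(np.array([0.0, 180.0])) == pytest.approx(-1.0)

    def test_fewer_than_two_spikes_rejected(self):
        with pytest.raises(ValueError):
            ppc(np.array([10.0]))

    @pytest.mark.parametrize("n", [2, 17, 200, 500])
    def test_fast_form_equals_pairwise_definition(self, n):
        rng = np.random.default_rng(n)
        phases = rng.uniform(0, 360, n)
        r = np.deg2rad(phases)
        pairwise = 0.0
        for i in range(n - 1):
            pairwise += np.cos(r[i] - r[i + 1 :]).sum()
        pairwise *= 2.0 / (n * (n - 1))
        assert abs(ppc(phases) - pairwise) < 1e-10

    def test_analytic_limit_m_over_two_squared(self):
        rng = np.random.default_rng(0)
        phases = sinusoidal_phases(0.5, 20000, rng)
        assert ppc(phases) == pytest.approx(0.0625, abs=0.01)


class TestModulationIndex:
    def test_sinusoidal_rate_index_is_two_m(self):
        # m = 0.5, N ~ 5000 spikes with the generator's true phase
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=31)
        neuron = make_neuron(
            theta_mod_depth=0.5, peak_rate_hz=0.0, baseline_rate_hz=8.0
        )
        s = generate_session(cfg, neurons=[neuron])
        theta = true_phase_series(s)
        prof = theta_rate_profile(s.spikes.spike_times[0], s.timeline, theta)
        assert len(s.spikes.spike_times[0]) > 4000
        assert prof.index == pytest.approx(1.0, abs=0.1)
        assert prof.preferred_phase_deg == pytest.approx(180.0, abs=30.0)

    def test_ppc_tracks_index_quarter_squared(self):
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=32)
        neuron = make_neuron(theta_mod_depth=0.5, peak_rate_hz=0.0, baseline_rate_hz=8.0)
        s = generate_session(cfg, neurons=[neuron])
        theta = true_phase_series(s)
        prof = theta_rate_profile(s.spikes.spike_times[0], s.timeline, theta)
        val = ppc(spike_phases(s.spikes.spike_times[0], s.timeline, theta))
        assert val == pytest.approx((prof.index / 4.0) ** 2, abs=0.02)

    def test_constant_rate_index_near_zero(self):
        cfg = GeneratorConfig(n_trials=120, n_ca1=1, n_v1=0, seed=33)
        s = generate_session(
            cfg, neurons=[make_neuron(peak_rate_hz=0.0, baseline_rate_hz=8.0)]
        )
        prof = theta_rate_profile(s.spikes.spike_times[0], s.timeline, true_phase_series(s))
        assert prof.index < 0.25

    def test_zero_spikes_not_flagged(self, small_session):
        theta = true_phase_series(small_session)
        p, sig, obs, _ = theta_significance(
            np.empty(0), small_session.timeline, theta, n_shuffles=50, seed=1
        )
        assert not sig and p == 1.0

    def test_modulated_neuron_flagged(self):
        cfg = GeneratorConfig(n_trials=60, n_ca1=1, n_v1=0, seed=34)
        s = generate_session(cfg, neurons=[make_neuron(theta_mod_depth=0.3)])
        mask = speed_mask(s.timeline.speed)
        theta = extract_theta_phase(s.lfp, s.timeline.sample_rate)
        p, sig, *_ = theta_significance(
            s.spikes.spike_times[0], s.timeline, theta, mask, n_shuffles=200, seed=2
        )
        assert sig and p < 0.05


class TestSinusoidFit:
    def test_exact_noiseless_fit(self):
        th = (np.arange(18) + 0.5) * 20.0
        drift = 4.0 * np.sin(np.deg2rad(th - 180.0))
        amp, off = fit_drift_sinusoid(drift, th)
        assert amp == pytest.approx(4.0, abs=1e-9)
        assert off == pytest.approx(180.0, abs=1e-6)

    def test_constant_curve_has_zero_amplitude(self):
        amp, off = fit_drift_sinusoid(np.full(18, 2.5))
        assert amp == 0.0 and np.isnan(off)

    def test_noisy_fit_within_half_cm(self):
        rng = np.random.default_rng(4)
        th = (np.arange(18) + 0.5) * 20.0
        errs = []
        for _ in range(20):
            drift = 4.0 * np.sin(np.deg2rad(th - 90.0)) + 0.5 * rng.standard_normal(18)
            amp, _ = fit_drift_sinusoid(drift, th)
            errs.append(abs(amp - 4.0))
        assert np.mean(errs) < 0.5

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_drift_sinusoid(np.array([1.0, 2.0, 1.0]))


class TestPrecession:
    def test_no_precession_flat_drift(self):
        cfg = GeneratorConfig(n_trials=100, n_ca1=1, n_v1=0, seed=35)
        s = generate_session(
            cfg, neurons=[make_neuron(theta_mod_depth=0.3, precession_amplitude_cm=0.0)]
        )
        mask = speed_mask(s.timeline.speed)
        pp = phase_position_profile(
            s.spikes.spike_times[0], s.timeline, true_phase_series(s), mask
        )
        assert pp.amplitude_cm < 2.0

    def test_injected_precession_recovered(self):
        cfg = GeneratorConfig(n_trials=150, n_ca1=1, n_v1=0, seed=36)
        s = generate_session(
            cfg,
            neurons=[
                make_neuron(
                    theta_mod_depth=0.4,
                    precession_amplitude_cm=4.0,
                    precession_offset_deg=200.0,
                )
            ],
        )
        mask = speed_mask(s.timeline.speed)
        pp = phase_position_profile(
            s.spikes.spike_times[0], s.timeline, true_phase_series(s), mask
        )
        assert pp.amplitude_cm == pytest.approx(4.0, abs=1.0)
        assert abs((pp.offset_deg - 200.0 + 180) % 360 - 180) <= 20.0

    def test_drift_argmax_matches_exhaustive_offset_scan(self):
        rng = np.random.default_rng(5)
        from vrnav.theta import _drift_curve
        from vrnav.geometry import circular_distance as cdist

        base = np.convolve(rng.random(100), np.ones(9) / 9, mode="same")
        shifts = [-6, -2, 0, 3, 8]
        rate2d = np.vstack([np.roll(base, k) for k in shifts])
        drift = _drift_curve(rate2d, 2.0)
        mean = rate2d.mean(axis=0)
        for row, k in enumerate(shifts):
            brute = [np.corrcoef(rate2d[row], np.roll(mean, j))[0, 1] for j in range(100)]
            expected = cdist(2.0 * int(np.argmax(brute)), 0.0, 200.0)
            # sub-bin refinement may move the peak within half a bin
            assert drift[row] == pytest.approx(expected, abs=1.0)

    def test_precessing_neuron_flagged(self):
        cfg = GeneratorConfig(n_trials=150, n_ca1=1, n_v1=0, seed=37)
        s = generate_session(
            cfg,
            neurons=[make_neuron(theta_mod_depth=0.4, precession_amplitude_cm=6.0,
                                 precession_offset_deg=200.0)],
        )
        mask = speed_mask(s.timeline.speed)
        theta = extract_theta_phase(s.lfp, s.timeline.sample_rate)
        p, sig, obs, _ = precession_significance(
            s.spikes.spike_times[0], s.timeline, theta, mask, n_shuffles=200, seed=3
        )
        assert sig and p < 0.05

    def test_degenerate_single_phase_not_flagged(self, small_session):
        tl = small_session.timeline
        theta = ThetaPhaseSeries(
            phase=np.full(tl.n_samples, 90.0),
            cycle_id=np.zeros(tl.n_samples, dtype=int),
            valid=np.ones(tl.n_samples, dtype=bool),
        )
        p, sig, *_ = precession_significance(
            small_session.spikes.spike_times[0], tl, theta, n_shuffles=20, seed=4
        )
        assert not sig


class TestPhaseExtraction:
    def test_pure_tone_linear_phase(self):
        fs = 500.0
        t = np.arange(0, 60, 1 / fs)
        lfp = np.cos(2 * np.pi * 8.0 * t)
        series = extract_theta_phase(lfp, fs)
        # 360 degrees every 125 ms -> 5.76 degrees per sample at 500 Hz
        d = np.diff(series.phase[series.valid]) % 360.0
        assert np.median(d) == pytest.approx(360.0 * 8.0 / fs, abs=0.2)

    def test_sixty_ms_refractory_discards_peak(self):
        fs = 1000.0
        t = np.arange(0, 30, 1 / fs)
        lfp = np.cos(2 * np.pi * 7.0 * t)
        # inject a spurious extra peak 50 ms after each true peak
        lfp2 = lfp + 0.8 * np.cos(2 * np.pi * 7.0 * (t - 0.05)) ** 30
        series = extract_theta_phase(lfp2, fs, peak_prominence_sd=0.1)
        wraps = np.flatnonzero(np.diff(series.phase) < -180)
        periods = np.diff(wraps) / fs
        assert periods.min() >= 0.06

    def test_no_peaks_raises(self):
        with pytest.raises(ValueError):
            extract_theta_phase(np.zeros(6000), 60.0)

    def test_population_centering_puts_peak_at_180(self):
        cfg = GeneratorConfig(n_trials=60, n_ca1=5, n_v1=0, seed=38)
        neurons = [
            make_neuron(theta_mod_depth=0.6, theta_pref_phase_deg=90.0,
                        anchor_distance_cm=10.0 + 30 * i)
            for i in range(5)
        ]
        s = generate_session(cfg, neurons=neurons)
        theta = extract_theta_phase(
            s.lfp, s.timeline.sample_rate,
            population_spike_times=s.spikes.spike_times, timeline=s.timeline,
        )
        pooled = np.concatenate(s.spikes.spike_times)
        prof = theta_rate_profile(pooled, s.timeline, theta)
        assert prof.preferred_phase_deg == pytest.approx(180.0, abs=20.0)


class TestPopulationCircularStats:
    def test_rayleigh_concentrated_phases(self):
        assert rayleigh_test(np.full(50, 77.0)) < 1e-3

    def test_rayleigh_single_phase_is_one(self):
        assert rayleigh_test(np.array([10.0])) == 1.0

    def test_rayleigh_uniform_calibration(self):
        rng = np.random.default_rng(6)
        ps = [rayleigh_test(rng.uniform(0, 360, 200)) for _ in range(100)]
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8  # p roughly uniform

    def test_circular_median_identical_groups_statistic_zero(self):
        g = np.array([10.0, 50.0, 90.0, 200.0, 300.0, 355.0])
        stat, p = circular_median_test([g, g.copy()], n_shuffles=50, seed=7)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_circular_median_separated_groups_rejected(self):
        rng = np.random.default_rng(8)
        a = (rng.vonmises(np.deg2rad(80 - 180), 2.0, 100) + np.pi) * 180 / np.pi
        b = (rng.vonmises(np.deg2rad(210 - 180), 2.0, 100) + np.pi) * 180 / np.pi
        stat, p = circular_median_test([a, b], n_shuffles=200, seed=9)
        assert p < 0.05

    def test_circular_median_same_distribution_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(40):
            g = [
                (rng.vonmises(0.5, 1.5, 40) + np.pi) * 180 / np.pi for _ in range(2)
            ]
            _, p = circular_median_test(g, n_shuffles=100, seed=int(rng.integers(1 << 30)))
            rejections += p < 0.05
        assert rejections <= 7  # ~5% nominal, generous binomial bound

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            circular_median_test([np.arange(3.0), np.arange(10.0)])

    def test_layer_fractions_detected(self):
        rng = np.random.default_rng(11)
        depths = np.concatenate([rng.uniform(250, 500, 150), rng.uniform(500, 700, 150)])
        flags = np.concatenate(
            [rng.random(150) < 0.30, rng.random(150) < 0.10]
        )
        animals = np.tile([0, 1, 2], 100)
        out = layer_fraction_test(flags, depths, animals, n_shuffles=200, seed=12)
        row = out[(out["layer_a"] == "L2-4") & (out["layer_b"] == "L5")].iloc[0]
        assert row["significant"] and row["p"] < 0.05

    def test_layer_fractions_null_calibrated(self):
        rng = np.random.default_rng(13)
        depths = rng.uniform(250, 950, 200)
        flags = rng.random(200) < 0.2
        animals = np.zeros(200, dtype=int)
        out = layer_fraction_test(flags, depths, animals, n_shuffles=200, seed=14)
        assert (out["p"] > 0.01).all()

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            layer_fraction_test(
                np.array([True, False]), np.array([300.0, 310.0]), np.array([0, 0])
            )


class TestLinearCircular:
    def test_independent_phase_and_position(self):
        rng = np.random.default_rng(15)
        r, p, sig = linear_circular_correlation(
            rng.uniform(0, 360, 400), rng.uniform(0, 40, 400),
            n_shuffles=200, seed=16,
        )
        assert abs(r) < 0.2 and not sig

    def test_perfect_relation_detected(self):
        # shallow perfect relation (phase range well below a full cycle):
        # the circular-linear coefficient approaches 1 in this limit
        x = np.linspace(0, 40, 300)
        phases = 120.0 + 2.0 * x
        r, p, sig = linear_circular_correlation(phases, x, n_shuffles=200, seed=17)
        assert abs(r) > 0.9 and sig and p < 0.01

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            linear_circular_correlation(np.full(20, 10.0), np.arange(20.0))

    def test_field_extent_wraps_around_track_edge(self):
        rate = np.roll(np.exp(-0.5 * ((np.arange(100) - 50) / 4.0) ** 2), 48)
        mask = field_extent_mask(rate, 0.5)
        assert mask[98] and mask[0]  # contiguous across the wrap
        assert mask.sum() < 20
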