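"""Bayesian population decoding: posterior, CV decoding, summaries."""

import numpy as np
import pytest

from vrnav.decoding import (
    EncodingModel,
    decode_by_theta_phase,
    decode_session,
    decoded_distribution,
    error_summaries,
    fit_encoding_model,
    licks_in_decoded_coordinates,
    make_windows,
    posterior,
)
from vrnav.session import speed_mask
from vrnav.synth import GeneratorConfig, generate_session
from vrnav.theta import ThetaPhaseSeries

from conftest import make_neuron, preprocess


def toy_model(rates, prior=None):
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[1]
    prior = np.full(n, 1.0 / n) if prior is None else np.asarray(prior)
    return EncodingModel(
        rates=rates,
        prior=prior,
        bin_centers=(np.arange(n) + 0.5) * 2.0,
        bin_cm=2.0,
    )


@pytest.fixture(scope="module")
def decoding_session():
    cfg = GeneratorConfig(n_trials=60, n_ca1=40, n_v1=0, seed=51)
    session = generate_session(cfg)
    trials, _, mask = preprocess(session)
    medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
    spikes = list(session.spikes.spike_times)
    result = decode_session(
        spikes, session.timeline, trials, medium["trial_id"].to_numpy(), mask=mask
    )
    return session, trials, mask, result


class TestPosterior:
    def test_two_position_hand_oracle(self):
        # one neuron, f = (1, 10) Hz, t = 0.25 s, r = 2, uniform prior:
        # L(x) = f^2 exp(-0.25 f); P(pos 2) = 8.208 / (8.208 + 0.779) = 0.913
        model = toy_model([[1.0, 10.0]])
        post = posterior(np.array([[2.0]]), model, 0.25)
        lik = np.array([1.0**2 * np.exp(-0.25), 10.0**2 * np.exp(-2.5)])
        assert post[0] == pytest.approx(lik / lik.sum(), abs=1e-6)
        assert post[0, 1] == pytest.approx(0.913, abs=1e-3)

    def test_zero_counts_returns_prior_for_uniform_rates(self):
        prior = np.array([0.1, 0.2, 0.3, 0.4])
        model = toy_model([[5.0, 5.0, 5.0, 5.0]], prior=prior)
        post = posterior(np.array([[0.0]]), model, 0.25)
        assert post[0] == pytest.approx(prior, abs=1e-12)

    def test_normalization_and_linear_domain_agreement(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.5, 20.0, size=(5, 12))
        model = toy_model(rates)
        counts = rng.poisson(2.0, size=(20, 5)).astype(float)
        post = posterior(counts, model, 0.25)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9
        # direct (linear-domain) evaluation on one window
        f = np.maximum(rates, model.rate_floor)
        lin = model.prior * np.prod(f ** counts[3][:, None], axis=0) * np.exp(
            -0.25 * f.sum(axis=0)
        )
        assert post[3] == pytest.approx(lin / lin.sum(), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        model = toy_model([[1.0, 2.0]])
        with pytest.raises(ValueError):
            posterior(np.array([[-1.0]]), model, 0.25)
        with pytest.raises(ValueError):
            posterior(np.array([[1.0]]), model, 0.0)


class TestDecodeSession:
    def test_matched_session_median_error_below_10cm(self, decoding_session):
        _, _, _, result = decoding_session
        med = result.windows[result.windows["gain"] == 1.0]
        assert np.median(np.abs(med["error"])) < 10.0

    def test_shuffled_cell_identity_destroys_code(self, decoding_session):
        # decode the true spike counts with cell identities permuted in the
        # encoding model: the median error should approach chance (~L/4)
        from vrnav.decoding import window_counts
        from vrnav.geometry import circular_distance

        session, trials, mask, result = decoding_session
        tl = session.timeline
        rng = np.random.default_rng(1)
        medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
        model = fit_encoding_model(
            list(session.spikes.spike_times), tl,
            mask & np.isin(tl.trial_id, medium["trial_id"].to_numpy()),
        )
        windows = make_windows(tl, 0.25, mask)
        counts = window_counts(list(session.spikes.spike_times), windows, 0.25)
        counts_perm = counts[:, rng.permutation(counts.shape[1])]
        post = posterior(counts_perm, model, 0.25)
        decoded = model.bin_centers[np.argmax(post, axis=1)]
        err = circular_distance(decoded, windows["actual"].to_numpy(), result.length)
        chance = result.length / 4.0
        med_err = np.median(np.abs(err))
        assert med_err > 0.5 * chance
        assert med_err > 3 * np.median(np.abs(result.windows["error"]))

    def test_population_size_improves_accuracy(self, decoding_session):
        session, trials, mask, result160 = decoding_session
        medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
        medians = {}
        for n in (10, 40):
            res = decode_session(
                list(session.spikes.spike_times[:n]), session.timeline, trials,
                medium["trial_id"].to_numpy(), mask=mask,
            )
            medians[n] = np.median(np.abs(res.windows["error"]))
        assert medians[40] <= medians[10]

    def test_too_few_neurons_refused(self, decoding_session):
        session, trials, mask, _ = decoding_session
        with pytest.raises(ValueError, match="neurons"):
            decode_session(
                list(session.spikes.spike_times[:5]), session.timeline, trials,
                np.array([0, 1]), mask=mask,
            )

    def test_cv_heldout_not_more_accurate_than_training_fit(self, decoding_session):
        session, trials, mask, result = decoding_session
        medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
        full = decode_session(
            list(session.spikes.spike_times), session.timeline, trials,
            medium["trial_id"].to_numpy(), mask=mask, folds=1,
        )
        w_cv = result.windows[result.windows["cv_heldout"]]
        w_full = full.windows[full.windows["cv_heldout"]]
        assert np.median(np.abs(w_cv["error"])) >= np.median(np.abs(w_full["error"])) - 0.5


class TestSummaries:
    def test_decoded_distribution_columns_sum_to_one(self, decoding_session):
        _, _, _, result = decoding_session
        dist = decoded_distribution(result)
        sums = dist.sum(axis=0)
        visited = sums > 0
        assert np.abs(sums[visited] - 1.0).max() < 1e-9

    def test_distribution_concentrates_on_diagonal(self, decoding_session):
        _, _, _, result = decoding_session
        dist = decoded_distribution(result, gain=1.0)
        n = dist.shape[0]
        diag_mass = np.mean([dist[(np.arange(n) + d) % n, np.arange(n)].sum()
                             for d in (-1, 0, 1)]) * 3
        assert diag_mass > 5 * (3.0 / n)  # far above the uniform level

    def test_same_condition_correction_is_zero(self, decoding_session):
        _, _, _, result = decoding_session
        ref = error_summaries(result, 1.0)
        corrected = error_summaries(result, 1.0, reference=ref)
        assert np.nanmax(np.abs(corrected.bias)) == pytest.approx(0.0, abs=1e-9)

    def test_missing_gain_rejected(self, decoding_session):
        _, _, _, result = decoding_session
        with pytest.raises(ValueError):
            error_summaries(result, 3.0)


class TestPhaseResolvedDecoding:
    def test_constant_error_amplitude_near_zero(self, decoding_session):
        session, trials, mask, _ = decoding_session
        tl = session.timeline
        theta = ThetaPhaseSeries(
            phase=session.theta_phase,
            cycle_id=np.zeros(tl.n_samples, dtype=int),
            valid=np.ones(tl.n_samples, dtype=bool),
        )
        medium = trials[(trials["gain"] == 1.0) & (trials["outcome"] == "correct")]
        model = fit_encoding_model(
            list(session.spikes.spike_times), tl,
            mask & np.isin(tl.trial_id, medium["trial_id"].to_numpy()),
        )
        res = decode_by_theta_phase(
            list(session.spikes.spike_times), tl, model, theta, mask,
            n_shuffles=100, seed=2,
        )
        # population has no phase-coupled code: amplitude stays small
        assert res.amplitude_cm < 3.0


class TestLicksInDecodedCoordinates:
    def test_perfect_decoder_reduces_to_true_positions(self, decoding_session):
        session, _, _, result = decoding_session
        perfect = result.windows.copy()
        perfect["decoded"] = perfect["actual"]
        from vrnav.decoding import DecodingResult

        res = DecodingResult(
            windows=perfect, bin_centers=result.bin_centers,
            window_s=result.window_s, length=result.length,
        )
        out = licks_in_decoded_coordinates(session.timeline, res)
        assert len(out) >= 2 and (out["n_licks"] > 0).any()

    def test_no_licks_empty_output(self, decoding_session):
        session, _, _, result = decoding_session
        tl = session.timeline
        import copy

        tl2 = copy.copy(tl)
        tl2.lick = np.zeros(tl.n_samples, dtype=int)
        out = licks_in_decoded_coordinates(tl2, result)
        assert len(out) == 0
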