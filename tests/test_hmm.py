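import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from actiseq.hmm import (
    SPURIOUS,
    CHMMParams,
    GaussianMixtureEmissions,
    SequentialHMM,
    baum_welch_refine,
    classify_sequence,
    first_phase_train,
    forward_loglik,
    simulate_chmm,
    viterbi_decode,
)
from actiseq.markov import MarkovChain, estimate_omm
from actiseq.rejection import RejectionModel
from conftest import random_chmm


def brute_force_forward_and_viterbi(model, obs):
    """Exhaustive enumeration over all Q^T state paths."""
    q, t_len = model.n_states, len(obs)
    log_b = model.emissions.log_density(obs)
    with np.errstate(divide="ignore"):
        lp, la = np.log(model.omm.prior), np.log(model.omm.tpm)
    scores = []
    best_score, best_path = -np.inf, None
    for path in itertools.product(range(q), repeat=t_len):
        s = lp[path[0]] + log_b[0, path[0]]
        for t in range(1, t_len):
            s += la[path[t - 1], path[t]] + log_b[t, path[t]]
        scores.append(s)
        if s > best_score:
            best_score, best_path = s, path
    return logsumexp(scores), best_score, best_path


class TestOracleEquivalence:
    @pytest.mark.parametrize("q", [2, 3])
    @pytest.mark.parametrize("t_len", [2, 3, 4, 5, 6, 7])
    def test_forward_and_viterbi_match_exhaustive_enumeration(self, q, t_len):
        rng = np.random.default_rng(100 * q + t_len)
        for _ in range(3):
            model = random_chmm(rng, q, d=2, m=int(rng.integers(1, 3)))
            obs = rng.normal(0, 3, (t_len, 2))
            ll_brute, best_brute, path_brute = brute_force_forward_and_viterbi(model, obs)
            assert forward_loglik(model, obs) == pytest.approx(ll_brute, abs=1e-8)
            path, score = viterbi_decode(model, obs)
            assert score == pytest.approx(best_brute, abs=1e-8)
            assert tuple(model.labels.index(s) for s in path) == path_brute

    def test_single_state_chain_degenerates_to_density_sum(self, rng):
        model = random_chmm(rng, 1, d=2)
        obs = rng.normal(0, 2, (20, 2))
        expected = model.emissions.log_density(obs)[:, 0].sum()
        assert forward_loglik(model, obs) == pytest.approx(expected)
        assert viterbi_decode(model, obs)[0] == [model.labels[0]] * 20

    def test_length_one_sequence_base_case(self, rng):
        model = random_chmm(rng, 3, d=2)
        obs = rng.normal(0, 2, (1, 2))
        expected = logsumexp(np.log(model.omm.prior) + model.emissions.log_density(obs)[0])
        assert forward_loglik(model, obs) == pytest.approx(expected)

    def test_matches_hmmlearn_reference(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_chmm(rng, 3, d=2, m=1)
        obs = rng.normal(0, 2, (60, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = model.omm.prior
        ref.transmat_ = model.omm.tpm
        ref.means_ = model.emissions.means[:, 0, :]
        ref.covars_ = model.emissions.covariances[:, 0, :, :]
        assert forward_loglik(model, obs) == pytest.approx(ref.score(obs), abs=1e-8)
        np.testing.assert_array_equal(
            [model.labels.index(s) for s in viterbi_decode(model, obs)[0]], ref.predict(obs)
        )

    def test_dimension_mismatch_rejected(self, rng):
        model = random_chmm(rng, 2, d=3)
        with pytest.raises(ValueError, match="dimension"):
            forward_loglik(model, rng.normal(size=(5, 2)))

    def test_log_space_stability_over_long_sequences(self, rng):
        model = random_chmm(rng, 3, d=2)
        obs, _ = simulate_chmm(model, 10_000, seed=4)
        assert np.isfinite(forward_loglik(model, obs))
        path, score = viterbi_decode(model, obs)
        assert np.isfinite(score) and len(path) == 10_000


def _separated_model(q=3, d=2, self_prob=0.9, spread=6.0):
    tpm = np.full((q, q), (1 - self_prob) / (q - 1))
    np.fill_diagonal(tpm, self_prob)
    omm = MarkovChain([f"s{i}" for i in range(q)], np.full(q, 1 / q), tpm)
    means = (np.arange(q) * spread)[:, None, None] * np.ones((q, 1, d))
    covs = np.tile(np.eye(d), (q, 1, 1, 1))
    return CHMMParams(omm, GaussianMixtureEmissions(np.ones((q, 1)), means, covs))


class TestFirstPhaseTraining:
    def test_single_gaussian_means_are_exact_sample_means(self, rng):
        x = rng.normal(0, 1, (40, 2))
        labels = ["a"] * 20 + ["b"] * 20
        params = first_phase_train([(x, labels)], labels=["a", "b"])
        np.testing.assert_array_equal(params.emissions.means[0, 0], x[:20].mean(axis=0))
        np.testing.assert_array_equal(params.emissions.means[1, 0], x[20:].mean(axis=0))

    def test_transitions_equal_event_counting(self, rng):
        seqs = [list(rng.choice(["a", "b", "c"], 50)) for _ in range(3)]
        exps = [(rng.normal(0, 1, (50, 2)), s) for s in seqs]
        params = first_phase_train(exps, labels=["a", "b", "c"])
        direct = estimate_omm(seqs, labels=["a", "b", "c"])
        np.testing.assert_array_equal(params.omm.tpm, direct.tpm)
        np.testing.assert_array_equal(params.omm.prior, direct.prior)

    def test_missing_state_rejected(self, rng):
        with pytest.raises(ValueError, match="absent|no training frames"):
            first_phase_train(
                [(rng.normal(0, 1, (10, 2)), ["a"] * 10)], labels=["a", "b"]
            )

    def test_parameter_recovery_from_simulated_data(self):
        """Supervised training on a known 3-state chain recovers the
        transition matrix and emission means."""
        truth = _separated_model()
        obs, states = simulate_chmm(truth, 5000, seed=0)
        fitted = first_phase_train([(obs, states)], labels=truth.labels)
        np.testing.assert_allclose(fitted.omm.tpm, truth.omm.tpm, atol=0.03)
        np.testing.assert_allclose(
            fitted.emissions.means[:, 0, :], truth.emissions.means[:, 0, :], atol=0.1
        )


class TestViterbiDecoding:
    def test_recovers_generating_path_when_separated(self):
        model = _separated_model()
        rng = np.random.default_rng(0)
        states = ["s0"] * 10 + ["s1"] * 10 + ["s2"] * 10
        idx = [model.labels.index(s) for s in states]
        obs = model.emissions.means[idx, 0, :] + 0.01 * rng.standard_normal((30, 2))
        path, _ = viterbi_decode(model, obs)
        assert path == states


class TestBaumWelch:
    def test_loglik_monotone_nondecreasing(self, rng):
        model = _separated_model(spread=2.0)
        obs, _ = simulate_chmm(model, 400, seed=1)
        start = random_chmm(rng, 3, d=2)
        for mode in ("transitions_only", "all"):
            _, history = baum_welch_refine(start, obs, mode=mode, tol=1e-8, max_iter=15)
            assert all(b >= a - 1e-6 for a, b in zip(history, history[1:]))

    def test_fixed_point_at_generating_parameters(self):
        model = _separated_model(spread=8.0)
        obs, _ = simulate_chmm(model, 5000, seed=2)
        tol = 1e-4
        _, history = baum_welch_refine(model, obs, mode="transitions_only", tol=tol)
        first_gain = history[1] - history[0] if len(history) > 1 else 0.0
        assert first_gain < 10 * tol * abs(history[0])

    def test_transitions_adapt_to_changed_chain(self):
        """A model trained under one transition regime, refined on data from
        another, moves its TPM toward the new regime."""
        em = _separated_model(self_prob=0.9).emissions
        labels = ["s0", "s1", "s2"]
        a1 = _separated_model(self_prob=0.9).omm.tpm
        a2 = _separated_model(self_prob=0.55).omm.tpm
        model_a1 = CHMMParams(MarkovChain(labels, np.full(3, 1 / 3), a1), em)
        truth_a2 = CHMMParams(MarkovChain(labels, np.full(3, 1 / 3), a2), em)
        obs, _ = simulate_chmm(truth_a2, 1500, seed=3)
        refined, _ = baum_welch_refine(model_a1, obs, mode="transitions_only")
        before = np.abs(a1 - a2).max()
        after = np.abs(refined.omm.tpm - a2).max()
        assert after < before

    def test_full_refinement_improves_tpm_over_first_phase(self):
        """Median over seeds: second-phase refinement (mode=all) reduces the
        elementwise TPM error left by first-phase training on short data."""
        truth = _separated_model(spread=3.0)
        gains = []
        for seed in range(10):
            obs, states = simulate_chmm(truth, 300, seed=seed)
            fitted = first_phase_train([(obs, states)], labels=truth.labels, smoothing=0.5)
            err_first = np.abs(fitted.omm.tpm - truth.omm.tpm).max()
            refined, _ = baum_welch_refine(fitted, obs, mode="all", tol=1e-6, max_iter=30)
            err_refined = np.abs(refined.omm.tpm - truth.omm.tpm).max()
            gains.append(err_first - err_refined)
        assert np.median(gains) > -1e-9

    def test_invalid_mode_rejected(self, rng):
        model = random_chmm(rng, 2, d=2)
        with pytest.raises(ValueError):
            baum_welch_refine(model, rng.normal(size=(10, 2)), mode="bogus")

    def test_refined_model_satisfies_invariants(self, rng):
        model = _separated_model(spread=2.0)
        obs, _ = simulate_chmm(model, 300, seed=5)
        refined, _ = baum_welch_refine(model, obs, mode="all", max_iter=5)
        refined.omm.validate()
        refined.emissions.validate()


class TestClassifySequence:
    def test_without_rejector_equals_viterbi(self, rng):
        model = random_chmm(rng, 3, d=2)
        obs = rng.normal(0, 2, (40, 2))
        assert classify_sequence(model, obs) == viterbi_decode(model, obs)[0]

    def test_rejected_frames_labelled_and_skipped(self):
        model = _separated_model(spread=8.0)
        obs, states = simulate_chmm(model, 60, seed=6)
        obs[10] = 1e3  # one wildly implausible frame
        rejector = RejectionModel(threshold=-1e4, score_rule="max")
        out = classify_sequence(model, obs, rejector)
        assert len(out) == 60
        assert out[10] == SPURIOUS
        assert sum(1 for s in out if s == SPURIOUS) == 1

    def test_everything_rejected_is_an_error(self, rng):
        model = random_chmm(rng, 2, d=2)
        rejector = RejectionModel(threshold=np.inf, score_rule="max")
        with pytest.raises(ValueError, match="no classifiable frames"):
            classify_sequence(model, rng.normal(size=(5, 2)), rejector)


class TestModelResultsInterface:
    def test_fit_refine_summary_round_trip(self):
        truth = _separated_model(spread=5.0)
        obs, states = simulate_chmm(truth, 600, seed=7)
        model = SequentialHMM(labels=truth.labels, smoothing=0.5)
        res = model.fit([(obs, states)])
        assert res.n_train_frames == 600
        assert np.isfinite(res.train_loglik)
        decoded, _ = res.decode(obs)
        assert np.mean([d == s for d, s in zip(decoded, states)]) > 0.95
        refined = res.refine(obs)
        assert refined.refine_history  # history recorded
        text = res.summary()
        assert "Transition probability matrix" in text and "s0" in text

    def test_simulation_reproducible_by_seed(self):
        model = _separated_model()
        obs1, st1 = simulate_chmm(model, 50, seed=9)
        obs2, st2 = simulate_chmm(model, 50, seed=9)
        np.testing.assert_array_equal(obs1, obs2)
        assert st1 == st2
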