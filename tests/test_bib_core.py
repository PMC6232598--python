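"""Unit and property tests for the BIB inference engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bibswarm import bib_core as bc


def make_window(symbols, M=4, n=4):
    w = bc.DataWindow(M, n)
    for s in symbols:
        w.append(s)
    return w


class TestWindowedFrequency:
    @pytest.mark.parametrize(
        "symbols, expected",
        [
            # the worked urn example: last four of d0,d1,d1,d2,d3
            ([0, 1, 1, 2, 3], [0.0, 0.5, 0.25, 0.25]),
            ([0, 1, 1, 2], [0.25, 0.5, 0.25, 0.0]),
            # fourth step of the two-symbol urn scenario
            ([0, 0, 1, 0], [0.75, 0.25, 0.0, 0.0]),
        ],
    )
    def test_worked_examples(self, symbols, expected):
        w = make_window(symbols)
        np.testing.assert_allclose(bc.windowed_frequency(w), expected)

    def test_short_window_normalizes_over_available(self):
        w = make_window([2], M=10)
        np.testing.assert_allclose(bc.windowed_frequency(w), [0, 0, 1, 0])

    def test_empty_window_returns_zero_sentinel(self):
        w = bc.DataWindow(4, 4)
        assert not np.any(bc.windowed_frequency(w))

    def test_corrupt_symbol_rejected(self):
        w = bc.DataWindow(4, 4)
        with pytest.raises(ValueError):
            w.append(7)

    def test_alphabet_mismatch_rejected(self):
        w = bc.DataWindow(4, 4)
        with pytest.raises(ValueError):
            bc.windowed_frequency(w, bc.DataAlphabet(3))


class TestBayesUpdate:
    def test_identical_rows_leave_belief_unchanged(self):
        L = np.tile([0.3, 0.2, 0.5], (3, 1))
        b = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(bc.bayes_update(b, L, 2), b)

    def test_hand_worked_two_hypothesis_update(self):
        L = np.array([[0.8, 0.2], [0.4, 0.6]])
        out = bc.bayes_update(np.array([0.5, 0.5]), L, 0)
        np.testing.assert_allclose(out, [2 / 3, 1 / 3])

    def test_degenerate_prior_is_fixed_point(self):
        L = np.array([[0.8, 0.2], [0.4, 0.6]])
        out = bc.bayes_update(np.array([1.0, 0.0]), L, 1)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_inconsistent_observation_raises(self):
        L = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ZeroDivisionError):
            bc.bayes_update(np.array([0.5, 0.5]), L, 1)

    def test_iterated_update_matches_joint_enumeration(self):
        """Sequential posteriors equal the brute-force joint
        P(h | d_1..d_T) ∝ P(h) Π_t P(d_t | h) on every sequence of
        length <= 6 over a 3-symbol, 3-hypothesis system."""
        rng = np.random.default_rng(42)
        L = rng.random((3, 3)) + 0.05
        L /= L.sum(axis=1, keepdims=True)
        prior = rng.random(3) + 0.05
        prior /= prior.sum()
        worst = 0.0
        for T in range(1, 7):
            for seq in itertools.product(range(3), repeat=T):
                b = prior.copy()
                for d in seq:
                    b = bc.bayes_update(b, L, d)
                joint = prior * np.prod(L[:, list(seq)], axis=1)
                joint /= joint.sum()
                worst = max(worst, float(np.max(np.abs(b - joint))))
        assert worst < 1e-12


class TestHypothesisSelection:
    def test_select_hs_minimum_replaced_with_complementary_probability(self):
        rng = np.random.default_rng(0)
        b = np.array([0.5, 0.3, 0.2])
        draws = [bc.select_hs(b, rng) for _ in range(100_000)]
        hits = [d for d in draws if d is not None]
        assert set(hits) == {2}
        assert abs(len(hits) / len(draws) - 0.8) < 0.01

    def test_select_hs_zero_probability_always_replaced(self):
        rng = np.random.default_rng(1)
        assert all(bc.select_hs(np.array([1.0, 0.0]), rng) == 1 for _ in range(100))

    def test_select_hs_uniform_ties_and_rate(self):
        rng = np.random.default_rng(2)
        b = np.full(4, 0.25)
        draws = [bc.select_hs(b, rng) for _ in range(100_000)]
        hits = np.array([d for d in draws if d is not None])
        assert abs(len(hits) / len(draws) - 0.75) < 0.01
        freqs = np.bincount(hits, minlength=4) / len(hits)
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_argmax_unique_and_degenerate(self):
        rng = np.random.default_rng(3)
        assert bc.argmax_hypothesis(np.array([0.1, 0.7, 0.2]), rng) == 1
        assert bc.argmax_hypothesis(np.array([1.0, 0.0, 0.0]), rng) == 0

    def test_argmax_tie_broken_uniformly(self):
        rng = np.random.default_rng(4)
        picks = np.array(
            [bc.argmax_hypothesis(np.array([0.5, 0.5]), rng) for _ in range(100_000)]
        )
        assert abs(picks.mean() - 0.5) < 0.01


class TestIbUpdate:
    def test_row_substituted_exactly(self):
        L = bc.initial_likelihood(bc.InitialLikelihoodSpec(p=0.7, n=4))
        f = np.array([0.0, 0.5, 0.25, 0.25])
        out = bc.ib_update(L, 2, f)
        np.testing.assert_array_equal(out[2], f)
        np.testing.assert_array_equal(np.delete(out, 2, axis=0), np.delete(L, 2, axis=0))

    def test_substituting_existing_row_is_idempotent(self):
        L = bc.initial_likelihood(bc.InitialLikelihoodSpec(p=0.7, n=4))
        np.testing.assert_array_equal(bc.ib_update(L, 1, L[1]), L)

    def test_zero_sentinel_is_noop(self):
        L = bc.initial_likelihood(bc.InitialLikelihoodSpec(p=0.7, n=4))
        np.testing.assert_array_equal(bc.ib_update(L, 0, np.zeros(4)), L)

    @given(st.integers(0, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_row_sums_preserved(self, row, seed):
        rng = np.random.default_rng(seed)
        L = rng.random((4, 4)) + 1e-3
        L /= L.sum(axis=1, keepdims=True)
        f = rng.random(4) + 1e-3
        f /= f.sum()
        out = bc.ib_update(L, row, f)
        np.testing.assert_allclose(out.sum(axis=1), np.ones(4), atol=1e-9)


class TestPredictAndInitialLikelihood:
    def test_initial_likelihood_structure(self):
        L = bc.initial_likelihood(bc.InitialLikelihoodSpec(p=0.7, n=4))
        np.testing.assert_allclose(np.diag(L), 0.7)
        assert L[0, 1] == pytest.approx(0.1)
        np.testing.assert_allclose(L.sum(axis=1), 1.0)

    def test_p_one_gives_identity(self):
        np.testing.assert_array_equal(
            bc.initial_likelihood(bc.InitialLikelihoodSpec(p=1.0, n=2)), np.eye(2)
        )

    @pytest.mark.parametrize("p", [0.25, 0.1, 0.0])
    def test_non_discriminating_peak_rejected(self, p):
        with pytest.raises(ValueError):
            bc.InitialLikelihoodSpec(p=p, n=4)

    def test_predict_reads_hmax_row(self):
        L = bc.initial_likelihood(bc.InitialLikelihoodSpec(p=0.7, n=4))
        assert bc.predict(L, 0, 1) == pytest.approx(0.1)
        assert bc.predict(np.eye(3), 2, 2) == 1.0


class TestStep:
    def test_b_mode_never_modifies_likelihood(self):
        rng = np.random.default_rng(5)
        agent = bc.BIBAgent.fresh(bc.InitialLikelihoodSpec(p=0.7, n=4), M=50, seed=6, mode="b")
        L0 = agent.likelihood.copy()
        for _ in range(1000):
            bc.step(agent, int(rng.integers(4)))
        np.testing.assert_array_equal(agent.likelihood, L0)

    def test_window_grows_from_empty(self):
        agent = bc.BIBAgent.fresh(bc.InitialLikelihoodSpec(p=0.7, n=4), M=10, seed=0)
        assert len(agent.window) == 0
        bc.step(agent, 2)
        assert len(agent.window) == 1

    def test_bib_replaced_row_approximates_source_distribution(self):
        """On i.i.d. data the replaced rows converge to the source: the
        last-rewritten row is within total variation 0.2 of q (M=100)."""
        q = np.array([0.5, 0.3, 0.1, 0.1])
        rng = np.random.default_rng(7)
        agent = bc.BIBAgent.fresh(bc.InitialLikelihoodSpec(p=0.7, n=4), M=100, seed=8)
        last_replaced = None
        for _ in range(500):
            before = agent.likelihood.copy()
            try:
                bc.step(agent, int(rng.choice(4, p=q)))
            except ZeroDivisionError:
                continue  # driver policy: skip the update for that step
            changed = np.flatnonzero(np.any(agent.likelihood != before, axis=1))
            if len(changed):
                last_replaced = changed[0]
        assert last_replaced is not None
        tv = 0.5 * np.sum(np.abs(agent.likelihood[last_replaced] - q))
        assert tv < 0.2

    def test_b_only_consistency_on_matching_source(self):
        """Belief concentrates (>0.99) on the generating hypothesis
        within 100 i.i.d. observations for at least 19 of 20 seeds."""
        spec = bc.InitialLikelihoodSpec(p=0.7, n=4)
        L = bc.initial_likelihood(spec)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            agent = bc.BIBAgent.fresh(spec, M=100, seed=seed, mode="b")
            for _ in range(100):
                bc.step(agent, int(rng.choice(4, p=L[1])))
                if agent.belief[1] > 0.99:
                    wins += 1
                    break
        assert wins >= 19

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["b", "bib"]))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_normalization_invariants(self, seed, mode):
        rng = np.random.default_rng(seed)
        agent = bc.BIBAgent.fresh(
            bc.InitialLikelihoodSpec(p=0.7, n=4), M=7, seed=seed, mode=mode
        )
        for _ in range(30):
            try:
                bc.step(agent, int(rng.integers(4)))
            except ZeroDivisionError:
                pass  # inconsistent observation: update skipped, state stays valid
            assert abs(agent.belief.sum() - 1.0) < 1e-9
            np.testing.assert_allclose(agent.likelihood.sum(axis=1), 1.0, atol=1e-9)
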