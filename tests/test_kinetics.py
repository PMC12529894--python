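"""Transition statistics, equilibrium and kinetic observables."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from trajgpt import (
    MarkovChainSpec,
    StateTrajectory,
    committed_transitions,
    count_transitions,
    estimate_T,
    free_energy,
    generate,
    generate_ensemble,
    implied_timescales,
    its_vs_lag,
    kinetic_time_empirical,
    kinetic_time_from_embeddings,
    kinetic_time_table,
    mfpt,
    mfpt_empirical,
    sample_markov_chain,
    stationary,
)
from trajgpt.kinetics import ansatz_conditionals


def random_chain(K, rng, min_p=0.01):
    """A random irreducible row-stochastic matrix."""
    T = rng.dirichlet(np.ones(K), size=K) + min_p
    return T / T.sum(axis=1, keepdims=True)


class TestCountTransitions:
    def test_small_enumeration(self):
        traj = StateTrajectory(np.array([0, 1, 0, 1]))
        c = count_transitions(traj, 1)
        assert c.counts.tolist() == [[0, 2], [1, 0]]
        assert c.total == 3

    def test_constant_trajectory(self):
        traj = StateTrajectory(np.zeros(10, dtype=int), n_states=1)
        c = count_transitions(traj, 1)
        assert c.counts[0, 0] == 9 and c.total == 9

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 4, 500)
        traj = StateTrajectory(states, boundaries=np.array([200, 350]))
        for lag in (1, 3, 7):
            got = count_transitions(traj, lag).counts
            expected = np.zeros((4, 4), dtype=int)
            for seg in np.split(states, [200, 350]):
                for i in range(len(seg) - lag):
                    expected[seg[i], seg[i + lag]] += 1
            assert np.array_equal(got, expected)

    def test_pairs_never_cross_boundaries(self):
        traj = StateTrajectory(np.array([0, 0, 1, 1]), boundaries=np.array([2]))
        c = count_transitions(traj, 1)
        assert c.counts[0, 1] == 0

    def test_excessive_lag_rejected(self):
        traj = StateTrajectory(np.array([0, 1, 0]), boundaries=np.array([2]))
        with pytest.raises(ValueError):
            count_transitions(traj, 2)


class TestEstimateT:
    def test_row_normalization(self):
        from trajgpt.kinetics import TransitionCounts

        c = TransitionCounts(np.array([[9, 1], [1, 9]]), lag=1)
        est = estimate_T(c)
        assert np.allclose(est.matrix, [[0.9, 0.1], [0.1, 0.9]])

    def test_symmetric_counts_equal_reversible_estimate(self):
        from trajgpt.kinetics import TransitionCounts

        c = TransitionCounts(np.array([[4, 2], [2, 8]]), lag=1)
        assert np.allclose(estimate_T(c).matrix,
                           estimate_T(c, reversible=True).matrix)

    def test_matches_direct_ratios(self):
        rng = np.random.default_rng(2)
        traj = StateTrajectory(rng.integers(0, 5, 2000))
        c = count_transitions(traj, 1)
        est = estimate_T(c)
        direct = c.counts / c.counts.sum(axis=1, keepdims=True)
        assert np.allclose(est.matrix, direct, atol=1e-12)

    def test_unvisited_states_dropped_with_mapping(self):
        traj = StateTrajectory(np.array([0, 2, 0, 2, 2]), n_states=4)
        with pytest.warns(UserWarning, match="dropping"):
            est = estimate_T(count_transitions(traj, 1))
        assert est.retained_states.tolist() == [0, 2]
        assert est.matrix.shape == (2, 2)


class TestStationary:
    def test_symmetric_matrix_gives_uniform(self):
        T = np.array([[0.8, 0.15, 0.05], [0.15, 0.7, 0.15], [0.05, 0.15, 0.8]])
        assert np.allclose(stationary(T), 1 / 3)

    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(stationary(T), [2 / 3, 1 / 3])

    def test_fixed_point_preserved_under_powers(self):
        rng = np.random.default_rng(3)
        T = random_chain(5, rng)
        assert np.allclose(stationary(T), stationary(T @ T), atol=1e-10)

    def test_reducible_chain_names_blocks(self):
        T = np.eye(4)
        with pytest.raises(ValueError, match="block"):
            stationary(T)

    def test_detailed_balance_oracle_on_random_reversible_chains(self):
        # build reversible chains from symmetric flux matrices: pi known
        rng = np.random.default_rng(4)
        for _ in range(10):
            F = rng.uniform(0.1, 1.0, (4, 4))
            F = F + F.T
            pi_true = F.sum(axis=1) / F.sum()
            T = F / F.sum(axis=1, keepdims=True)
            assert np.allclose(stationary(T), pi_true, atol=1e-10)


class TestFreeEnergy:
    def test_uniform_is_flat_zero(self):
        assert np.allclose(free_energy(np.full(4, 0.25)), 0.0)

    def test_two_thirds_one_third_gap_is_ln2(self):
        F = free_energy(np.array([2 / 3, 1 / 3]), kT=1.0)
        assert F[0] == 0.0
        assert F[1] == pytest.approx(np.log(2.0))

    def test_zero_probability_state_is_inf_and_warned(self):
        with pytest.warns(UserWarning, match="zero probability"):
            F = free_energy(np.array([0.5, 0.5, 0.0]))
        assert np.isinf(F[2]) and np.isfinite(F[:2]).all()

    def test_kt_scales_linearly(self):
        pi = np.array([0.7, 0.3])
        assert np.allclose(free_energy(pi, kT=2.0), 2.0 * free_energy(pi, kT=1.0))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # lambda_2 = 1 - p - q = 0.8, ITS = -1/ln 0.8
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        its = implied_timescales(T, lag=1)
        assert its.shape == (1,)
        assert its[0] == pytest.approx(-1.0 / np.log(0.8))

    def test_identity_has_no_finite_timescale(self):
        assert implied_timescales(np.eye(3), lag=1).size == 0

    def test_markovian_self_consistency_under_squaring(self):
        rng = np.random.default_rng(5)
        T = random_chain(4, rng)
        its1 = implied_timescales(T, lag=1)
        its2 = implied_timescales(T @ T, lag=2)
        assert np.allclose(its1, its2, atol=1e-9)

    def test_negative_eigenvalue_warned_and_dropped(self):
        T = np.array([[0.05, 0.95], [0.95, 0.05]])  # lambda_2 = -0.9
        with pytest.warns(UserWarning, match="lag too small"):
            its = implied_timescales(T, lag=1)
        assert its.size == 0

    def test_matches_independent_eigensolve_on_battery(self):
        rng = np.random.default_rng(6)
        for K in (3, 4, 5, 6):
            T = random_chain(K, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                its = implied_timescales(T, lag=2)
            vals = np.linalg.eigvals(T)
            vals = vals[np.argsort(-np.abs(vals))][1:]  # drop the unit eigenvalue
            mags = [
                abs(v) if abs(v.imag) > 1e-12 else v.real
                for v in vals
            ]
            expected = sorted(
                (-2.0 / np.log(m) for m in mags if m > 0), reverse=True
            )
            assert np.allclose(its, expected, atol=1e-9)


class TestMfpt:
    def test_source_equals_target_is_zero(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert mfpt(T, 1, 1) == 0.0

    def test_two_state_geometric_oracle(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert mfpt(T, 0, 1) == pytest.approx(10.0)

    def test_unreachable_target_rejected(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="unreachable"):
            mfpt(T, 0, 1)

    def test_empirical_matches_linear_solve_on_metastable_chain(
        self, metastable_matrix
    ):
        traj = sample_markov_chain(MarkovChainSpec(metastable_matrix, seed=8),
                                   1_000_000)
        for (a, b) in ((0, 3), (1, 3), (0, 2)):
            analytic = mfpt(metastable_matrix, a, b)
            empirical = mfpt_empirical(traj, a, b)
            assert empirical == pytest.approx(analytic, rel=0.05)

    def test_matches_absorbing_chain_simulation(self):
        rng = np.random.default_rng(9)
        T = random_chain(3, rng)
        analytic = mfpt(T, 0, 2)
        # brute-force Monte Carlo of the absorbing chain
        hits = []
        for _ in range(4000):
            s, steps = 0, 0
            while s != 2:
                s = rng.choice(3, p=T[s])
                steps += 1
            hits.append(steps)
        assert analytic == pytest.approx(np.mean(hits), rel=0.1)

    def test_oracle_battery_random_chains(self):
        # first-step linear solve vs the fundamental-matrix closed form
        rng = np.random.default_rng(10)
        for K in (3, 4, 5, 6):
            T = random_chain(K, rng)
            for target in (0, K - 1):
                keep = [i for i in range(K) if i != target]
                N = np.linalg.inv(np.eye(K - 1) - T[np.ix_(keep, keep)])
                expected = N.sum(axis=1)
                for j, src in enumerate(keep):
                    assert mfpt(T, src, target) == pytest.approx(expected[j])


class TestCommittedTransitions:
    def test_both_runs_committed(self):
        traj = StateTrajectory(np.array([0, 0, 1, 1]))
        assert committed_transitions(traj, 0, 1, commit_time=2) == 1

    def test_commit_time_longer_than_trajectory(self):
        traj = StateTrajectory(np.array([0, 0, 1, 1]))
        assert committed_transitions(traj, 0, 1, commit_time=5) == 0

    def test_run_length_encoding_oracle(self):
        # runs: [aaa][b][aa][bbb]; at commit 2 the lone b is dropped
        traj = StateTrajectory(np.array([0, 0, 0, 1, 0, 0, 1, 1, 1]))
        assert committed_transitions(traj, 0, 1, commit_time=2) == 1
        assert committed_transitions(traj, 0, 1, commit_time=1) == 2

    def test_intermediate_states_do_not_break_a_passage(self):
        # A -> B -> D: the B crossing is not an A or D visit, so the
        # passage from committed A to committed D still counts
        traj = StateTrajectory(np.array([0, 0, 1, 2, 3, 3]), n_states=4)
        assert committed_transitions(traj, 0, 3, commit_time=2) == 1
        # but a committed visit to D is required
        traj2 = StateTrajectory(np.array([0, 0, 1, 2, 3, 1]), n_states=4)
        assert committed_transitions(traj2, 0, 3, commit_time=2) == 0

    def test_monotone_non_increasing_in_commit_time(self):
        rng = np.random.default_rng(11)
        # sticky two-state chain gives long runs
        traj = sample_markov_chain(
            MarkovChainSpec(np.array([[0.95, 0.05], [0.05, 0.95]]), seed=12),
            20_000,
        )
        counts = [committed_transitions(traj, 0, 1, ct) for ct in
                  (1, 2, 5, 10, 20, 50, 100)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_same_state_pair_rejected(self):
        traj = StateTrajectory(np.array([0, 1]))
        with pytest.raises(ValueError):
            committed_transitions(traj, 1, 1, 1)


class TestGenerate:
    def test_prefix_returned_unmodified(self, small_markov_model):
        prefix = np.array([0, 1, 2, 3, 2, 1])
        out = generate(small_markov_model, prefix, 20, rng=0)
        assert np.array_equal(out.states[:6], prefix)
        assert len(out) == 26

    def test_out_of_vocab_prefix_rejected(self, small_markov_model):
        with pytest.raises(ValueError, match="vocabulary"):
            generate(small_markov_model, np.array([0, 7]), 5)

    def test_single_step_frequencies_match_decoded_distribution(
        self, small_markov_model
    ):
        prefix = np.array([0, 0, 1])
        probs = small_markov_model.predict_proba(prefix)[0]
        out = generate_ensemble(small_markov_model, [prefix] * 10_000, 1, rng=13)
        draws = out.states.reshape(10_000, 4)[:, -1]
        freq = np.bincount(draws, minlength=4) / 10_000
        for m in range(4):
            se = np.sqrt(probs[m] * (1 - probs[m]) / 10_000)
            assert abs(freq[m] - probs[m]) <= 3 * se + 1e-9

    def test_ensemble_boundaries_recorded(self, small_markov_model):
        out = generate_ensemble(small_markov_model, [np.array([0, 1])] * 3, 4, rng=1)
        assert out.boundaries.tolist() == [6, 12]

    def test_seed_determinism(self, small_markov_model):
        a = generate(small_markov_model, np.array([1, 2]), 30, rng=5)
        b = generate(small_markov_model, np.array([1, 2]), 30, rng=5)
        assert np.array_equal(a.states, b.states)


class TestKineticTime:
    def test_symmetric_two_state_substitution(self):
        # Q_ml = Q_lm = 0.1, pi = (1/2, 1/2): t = 1/(0.05 + 0.05) = 10
        Q = np.array([[0.9, 0.1], [0.1, 0.9]])
        tab = kinetic_time_table(Q, np.array([0.5, 0.5]), "empirical")
        assert tab.times[0, 1] == pytest.approx(10.0)
        assert np.allclose(tab.times, tab.times.T)

    def test_ansatz_reduces_to_softmax_of_dot_products(self):
        # orthonormal output embeddings aligned with the inputs, C = 0
        X = np.eye(3) * 2.0
        Xhat = np.eye(3)
        Q = ansatz_conditionals(X, Xhat)
        expected = np.exp(X @ Xhat.T)
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.allclose(Q, expected, atol=1e-12)

    def test_embedding_table_tracks_empirical_table(self, small_markov_model,
                                                    metastable_traj,
                                                    metastable_matrix):
        pi = stationary(metastable_matrix)
        emb = kinetic_time_from_embeddings(small_markov_model, pi)
        emp = kinetic_time_empirical(metastable_traj)
        rho = spearmanr(emb.offdiag(), emp.offdiag()).statistic
        assert rho >= 0.8
        assert np.allclose(emb.times, emb.times.T)

    def test_empirical_table_symmetric_positive(self, metastable_traj):
        tab = kinetic_time_empirical(metastable_traj)
        assert np.allclose(tab.times, tab.times.T)
        assert (tab.times > 0).all()


class TestItsVsLag:
    def test_markov_chain_timescales_stable_across_lags(self, metastable_matrix):
        traj = sample_markov_chain(MarkovChainSpec(metastable_matrix, seed=14),
                                   500_000)
        sweep = its_vs_lag(traj, [1, 2, 5])
        slow = [sweep[lag][0] for lag in (1, 2, 5)]
        truth = implied_timescales(metastable_matrix, lag=1)[0]
        # Markovian data: ITS independent of estimation lag
        assert np.allclose(slow, truth, rtol=0.1)
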