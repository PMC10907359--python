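import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st

from helpers import brute_force_filter
from opinionflow.hmm import (
    HmmSpec,
    baum_welch,
    canonical_relabel,
    default_spec,
    derive_seeds,
    expected_observation,
    fit_hmm,
    forward_filter,
    sample_trajectory,
    simulate_ensemble,
    stationary_distribution,
)


class TestSpec:
    def test_default_parameterization(self):
        spec = default_spec()
        assert np.allclose(spec.pi, [1.0, 0.0])
        assert np.allclose(spec.A, [[0.7, 0.3], [0.3, 0.7]])
        assert np.allclose(spec.B[1], [0.1, 0.3, 0.6])  # dissatisfied regime
        assert np.allclose(spec.A.sum(axis=1), 1.0)
        assert np.allclose(spec.B.sum(axis=1), 1.0)
        assert spec.obs_values == (1.0, 0.5, 0.0)
        assert spec.state_codes == (1.0, 0.0)

    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HmmSpec(
                pi=np.array([1.0, 0.0]),
                A=np.array([[0.7, 0.4], [0.3, 0.7]]),
                B=default_spec().B,
            )

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="negative"):
            HmmSpec(
                pi=np.array([1.5, -0.5]),
                A=default_spec().A,
                B=default_spec().B,
            )

    def test_json_round_trip(self, tmp_path):
        spec = default_spec()
        spec.to_json(tmp_path / "spec.json")
        back = HmmSpec.from_json(tmp_path / "spec.json")
        assert np.allclose(back.A, spec.A) and np.allclose(back.B, spec.B)
        assert back.obs_values == spec.obs_values


class TestSampling:
    def test_absorbing_transitions_keep_initial_state(self):
        spec = replace(default_spec(), A=np.eye(2))
        traj = sample_trajectory(spec, T=200, seed=1)
        assert np.all(traj.states == 0)  # pi = (1, 0): always Continue

    def test_deterministic_emission_row(self):
        spec = replace(
            default_spec(),
            A=np.eye(2),
            B=np.array([[1.0, 0.0, 0.0], [0.1, 0.3, 0.6]]),
        )
        traj = sample_trajectory(spec, T=100, seed=2)
        assert np.all(traj.observation_values == 1.0)

    def test_same_seed_reproduces_trajectory(self):
        a = sample_trajectory(default_spec(), 50, seed=9)
        b = sample_trajectory(default_spec(), 50, seed=9)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.observations, b.observations)

    def test_long_run_transition_frequency_matches_matrix(self):
        traj = sample_trajectory(default_spec(), T=100_000, seed=3)
        s = traj.states
        from_continue = s[:-1] == 0
        stay = np.mean(s[1:][from_continue] == 0)
        assert stay == pytest.approx(0.7, abs=0.01)

    def test_empirical_emission_frequencies_within_binomial_bounds(self):
        traj = sample_trajectory(default_spec(), T=100_000, seed=4)
        for j in range(2):
            mask = traj.states == j
            n = mask.sum()
            for k in range(3):
                p = default_spec().B[j, k]
                freq = np.mean(traj.observations[mask] == k)
                assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestEnsemble:
    def test_first_step_mean_matches_closed_form(self):
        # E[o_1] = 0.6*1 + 0.3*0.5 + 0.1*0 = 0.75 from the Continue row
        summary = simulate_ensemble(default_spec(), T=2, n_runs=10_000, seed=5)
        se = np.sqrt(0.1125 / 10_000)  # Var[o_1] = 0.675 - 0.75^2
        assert abs(summary.mean_observation[0] - 0.75) < 3 * se

    def test_single_run_equals_trajectory_with_derived_seed(self):
        summary = simulate_ensemble(default_spec(), T=20, n_runs=1, seed=6)
        traj = sample_trajectory(default_spec(), 20, seed=derive_seeds(6, 1)[0])
        assert np.array_equal(summary.mean_observation, traj.observation_values)
        assert np.array_equal(summary.mean_state, traj.state_codes)

    def test_invalid_run_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_ensemble(default_spec(), T=5, n_runs=0)


class TestClosedForms:
    def test_expected_first_observation(self):
        assert expected_observation(default_spec(), t=1) == pytest.approx(0.75)

    def test_stationary_distribution_is_symmetric(self):
        assert np.allclose(
            stationary_distribution(default_spec().A), [0.5, 0.5], atol=1e-12
        )

    def test_stationary_mean_observation_is_one_half(self):
        spec = default_spec()
        pi_inf = stationary_distribution(spec.A)
        mean = pi_inf @ spec.B @ np.array(spec.obs_values)
        assert mean == pytest.approx(0.5, abs=1e-12)


class TestForwardFilter:
    def test_first_posterior_follows_initial_vector(self):
        post, _ = forward_filter(default_spec(), [1.0])  # observe Support
        assert np.allclose(post[0], [1.0, 0.0])

    def test_two_support_observations(self):
        post, _ = forward_filter(default_spec(), [1.0, 1.0])
        # predict (0.7, 0.3), reweight by (0.6, 0.1), normalize
        assert np.allclose(post[1], [0.9333, 0.0667], atol=1e-4)

    def test_uniform_emissions_reduce_to_markov_prediction(self):
        spec = replace(default_spec(), B=np.full((2, 3), 1 / 3))
        obs = [1.0, 0.5, 0.0, 1.0, 0.5]
        post, _ = forward_filter(spec, obs)
        pred = spec.pi.copy()
        for t in range(len(obs)):
            assert np.allclose(post[t], pred, atol=1e-12)
            pred = pred @ spec.A

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(11)
        spec = default_spec()
        for T in (1, 3, 5, 8):
            obs = rng.choice([1.0, 0.5, 0.0], size=T)
            post, _ = forward_filter(spec, obs)
            idx = [{1.0: 0, 0.5: 1, 0.0: 2}[o] for o in obs]
            ref = brute_force_filter(spec.pi, spec.A, spec.B, idx)
            assert np.allclose(post, ref, atol=1e-10)

    def test_posteriors_sum_to_one(self):
        obs = [1.0, 0.0, 0.5, 0.0, 1.0, 1.0]
        post, _ = forward_filter(default_spec(), obs)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_loglikelihood_matches_hmmlearn(self):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        spec = default_spec()
        # hmmlearn rejects hard-zero start probabilities; compare on a
        # perturbed but equivalent-model start vector
        spec = replace(spec, pi=np.array([0.8, 0.2]))
        model = hmmlearn_hmm.CategoricalHMM(n_components=2)
        model.startprob_ = spec.pi
        model.transmat_ = spec.A
        model.emissionprob_ = spec.B
        rng = np.random.default_rng(13)
        for T in (4, 12, 30):
            idx = rng.integers(0, 3, size=T)
            obs = [spec.obs_values[i] for i in idx]
            _, ll = forward_filter(spec, obs)
            ref = model.score(idx.reshape(-1, 1))
            assert ll == pytest.approx(ref, abs=1e-8)

    def test_observation_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            forward_filter(default_spec(), [0.7])


class TestBaumWelch:
    def _sequences(self, n, T, seed=123):
        spec = default_spec()
        return [
            sample_trajectory(spec, T, seed=s).observation_values
            for s in derive_seeds(seed, n)
        ]

    def test_truth_initialization_converges_quickly(self):
        res = baum_welch(default_spec(), self._sequences(50, 100), tol=1e-2)
        assert res.converged and res.n_iter <= 25

    def test_loglikelihood_monotone_from_poor_start(self):
        init = replace(
            default_spec(),
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.5, 0.5], [0.5, 0.5]]),
            B=np.array([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4]]),
        )
        res = baum_welch(init, self._sequences(20, 50), tol=1e-8, max_iter=50)
        ll = res.log_likelihoods
        assert all(b - a > -1e-9 for a, b in zip(ll, ll[1:]))

    def test_result_rows_are_stochastic(self):
        res = baum_welch(default_spec(), self._sequences(10, 30), tol=1e-3)
        assert np.allclose(res.spec.A.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(res.spec.B.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_emission_column_rejected(self):
        init = replace(
            default_spec(),
            B=np.array([[0.7, 0.3, 0.0], [0.4, 0.6, 0.0]]),
        )
        with pytest.raises(ValueError, match="zero mass"):
            baum_welch(init, [[0.0, 1.0, 0.5]])

    def test_canonical_relabel_orders_by_support_emission(self):
        spec = default_spec()
        swapped = replace(
            spec,
            pi=spec.pi[::-1].copy(),
            A=spec.A[::-1, ::-1].copy(),
            B=spec.B[::-1].copy(),
        )
        fixed = canonical_relabel(swapped)
        assert np.allclose(fixed.A, spec.A)
        assert np.allclose(fixed.B, spec.B)
        assert np.allclose(fixed.pi, spec.pi)

    def test_unsupervised_fit_recovers_emission_structure(self):
        res = fit_hmm(self._sequences(60, 80), n_restarts=3, seed=1, tol=1e-4)
        # Continue state must clearly favour Support over Opposed
        assert res.spec.B[0, 0] > res.spec.B[0, 2]
        assert res.spec.B[1, 2] > res.spec.B[1, 0]


@given(seed=st.integers(0, 2**20), T=st.integers(1, 30))
def test_trajectory_values_lie_in_alphabets(seed, T):
    traj = sample_trajectory(default_spec(), T=T, seed=seed)
    assert set(np.unique(traj.observation_values)) <= {0.0, 0.5, 1.0}
    assert set(np.unique(traj.state_codes)) <= {0.0, 1.0}
    assert traj.T == T
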