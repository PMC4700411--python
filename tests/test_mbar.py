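"""MBAR estimator: analytic oracles, BAR equivalence, bootstrap errors."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from abfe.mbar import (
    ConvergenceError,
    FreeEnergyEstimate,
    ReducedPotentialData,
    bootstrap_free_energy,
    combine_repeats,
    mbar_asymptotic_covariance,
    mbar_solve,
    mbar_weights,
)
from abfe.toy import sample_gaussian_states


def bar_delta_f(data: ReducedPotentialData) -> float:
    """Independent two-state oracle: Bennett's implicit equation by brentq."""
    u0 = data.u[0, :, : data.N_k[0]].T
    u1 = data.u[1, :, : data.N_k[1]].T
    w_f = u0[:, 1] - u0[:, 0]
    w_r = u1[:, 0] - u1[:, 1]
    m = math.log(data.N_k[0] / data.N_k[1])

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.minimum(x, 700.0)))

    def equation(df):
        return fermi(m + w_f - df).sum() - fermi(-m + w_r + df).sum()

    return brentq(equation, -50.0, 50.0, xtol=1e-13)


class TestMbarSolve:
    def test_identical_states_give_zero_difference(self):
        res = sample_gaussian_states([1.0, 1.0], [0.0, 0.0], 2000, seed=0)
        sol = mbar_solve(res.data)
        assert sol.f[1] == pytest.approx(0.0, abs=1e-9)

    def test_two_state_gaussian_recovers_log_sigma_ratio(self):
        # f_2 - f_1 = -ln(sigma_2 / sigma_1) = -ln 2
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 50_000, seed=1)
        sol = mbar_solve(res.data)
        assert sol.f[1] == pytest.approx(-math.log(2.0), abs=0.02)

    def test_single_solution_is_additive_over_states(self):
        res = sample_gaussian_states([1.0, 1.5, 2.0], [0.0, 0.3, 0.8], 4000, seed=2)
        sol = mbar_solve(res.data)
        assert sol.delta_f(0, 2) == pytest.approx(
            sol.delta_f(0, 1) + sol.delta_f(1, 2), abs=1e-12
        )
        # antisymmetry of any pair from one solution
        assert sol.delta_f(0, 2) == -sol.delta_f(2, 0)

    def test_weights_are_normalized(self):
        res = sample_gaussian_states([1.0, 2.0, 3.0], [0.0, 0.5, 1.0], 3000, seed=3)
        sol = mbar_solve(res.data)
        W = mbar_weights(res.data, sol)
        assert np.all(W >= 0.0)
        # per-sample mixture weights sum to one over states
        np.testing.assert_allclose(
            (W * res.data.N_k[None, :]).sum(axis=1), 1.0, atol=1e-10
        )
        # self-consistency: each state's weights sum to one
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-8)

    def test_two_state_solution_satisfies_bar_equation(self):
        res = sample_gaussian_states([1.0, 1.8], [0.0, 0.6], 20_000, seed=4)
        sol = mbar_solve(res.data)
        assert sol.f[1] == pytest.approx(bar_delta_f(res.data), abs=1e-8)

    def test_result_independent_of_sample_ordering(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 5000, seed=5)
        sol = mbar_solve(res.data)
        rng = np.random.default_rng(6)
        perm = [rng.permutation(int(n)) for n in res.data.N_k]
        shuffled = res.data.subsample(perm)
        sol_shuffled = mbar_solve(shuffled)
        np.testing.assert_allclose(sol.f, sol_shuffled.f, atol=1e-9)

    def test_nonconvergence_raises_with_residual(self):
        res = sample_gaussian_states([1.0, 3.0], [0.0, 5.0], 2000, seed=7)
        with pytest.raises(ConvergenceError) as err:
            mbar_solve(res.data, max_iterations=1)
        assert err.value.residual > 0

    def test_disjoint_states_set_overlap_warning(self):
        res = sample_gaussian_states([0.1, 0.1], [0.0, 50.0], 500, seed=8)
        sol = mbar_solve(res.data)
        assert sol.overlap_warning

    def test_asymptotic_covariance_tracks_bootstrap_on_iid_data(self):
        # diagnostic only: on independent samples the sandwich covariance
        # and the bootstrap must agree on the scale of the uncertainty
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.5], 3000, seed=21)
        sol = mbar_solve(res.data)
        sd_asym = math.sqrt(mbar_asymptotic_covariance(res.data, sol)[1, 1])
        est = bootstrap_free_energy(res.data, (0, 1), n_boot=100, seed=22)
        sd_boot = est.sd / res.data.kT
        assert 0.6 < sd_asym / sd_boot < 1.6

    def test_estimator_consistency_across_sample_sizes(self):
        # absolute error of the free-energy estimate shrinks with N
        errors = {}
        for n in (250, 4000):
            errs = []
            for seed in range(20):
                res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], n, seed=seed)
                errs.append(abs(mbar_solve(res.data).f[1] + math.log(2.0)))
            errors[n] = np.mean(errs)
        assert errors[4000] < errors[250]


class TestBootstrap:
    def test_first_replicate_is_the_original_sample(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 1000, seed=9)
        est = bootstrap_free_energy(res.data, (0, 1), n_boot=10, seed=1)
        exact = res.data.kT * mbar_solve(res.data).f[1]
        assert est.bootstrap_samples[0] == pytest.approx(exact, abs=1e-10)

    def test_same_seed_reproduces_replicates_exactly(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 800, seed=10)
        a = bootstrap_free_energy(res.data, (0, 1), n_boot=25, seed=3)
        b = bootstrap_free_energy(res.data, (0, 1), n_boot=25, seed=3)
        np.testing.assert_array_equal(a.bootstrap_samples, b.bootstrap_samples)

    def test_value_and_sd_summarize_the_replicates(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 800, seed=11)
        est = bootstrap_free_energy(res.data, (0, 1), n_boot=40, seed=4)
        assert est.value == pytest.approx(np.mean(est.bootstrap_samples))
        assert est.sd == pytest.approx(np.std(est.bootstrap_samples, ddof=1))

    def test_bootstrap_sd_tracks_repeat_experiment_scatter(self):
        # repeat-experiment oracle: over 100 seeded realizations the mean
        # bootstrap sd must lie within a factor of 2 of the empirical sd
        points, boot_sds = [], []
        for seed in range(100):
            res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 300, seed=seed)
            est = bootstrap_free_energy(res.data, (0, 1), n_boot=30, seed=seed)
            points.append(res.data.kT * mbar_solve(res.data).f[1])
            boot_sds.append(est.sd)
        empirical = np.std(points, ddof=1)
        ratio = np.mean(boot_sds) / empirical
        assert 0.5 < ratio < 2.0

    def test_coverage_of_three_sd_interval(self):
        # |error| <= 3 bootstrap sd in at least 95 of 100 seeded trials
        kT = 298.15 * 0.0019872041
        truth = -math.log(2.0) * kT
        hits = 0
        for seed in range(100):
            res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 400, seed=1000 + seed)
            est = bootstrap_free_energy(res.data, (0, 1), n_boot=30, seed=seed)
            hits += abs(est.value - truth) <= 3.0 * est.sd
        assert hits >= 95

    def test_subsampling_iid_data_shifts_estimate_within_noise(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 4000, seed=12)
        full = bootstrap_free_energy(res.data, (0, 1), n_boot=40, seed=5)
        strided = res.data.subsample(
            [np.arange(0, int(n), 2) for n in res.data.N_k]
        )
        thin = bootstrap_free_energy(strided, (0, 1), n_boot=40, seed=6)
        assert abs(full.value - thin.value) < 3.0 * math.hypot(full.sd, thin.sd)

    def test_n_boot_below_two_rejected(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 100, seed=13)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_free_energy(res.data, (0, 1), n_boot=1, seed=0)


class TestCombineRepeats:
    def test_identical_single_sample_sets(self):
        est = FreeEnergyEstimate(value=1.5, sd=0.0, bootstrap_samples=[1.5])
        pooled = combine_repeats([est, est, est])
        assert pooled.value == 1.5
        assert pooled.sd == 0.0

    def test_pooled_mean_of_two_sets(self):
        a = FreeEnergyEstimate(value=0.0, sd=0.0, bootstrap_samples=[0.0, 0.0])
        b = FreeEnergyEstimate(value=1.0, sd=0.0, bootstrap_samples=[1.0, 1.0])
        assert combine_repeats([a, b]).value == pytest.approx(0.5)

    def test_three_repeats_of_200_pool_to_600(self):
        rng = np.random.default_rng(14)
        reps = [
            FreeEnergyEstimate(value=0.0, sd=1.0, bootstrap_samples=rng.normal(size=200))
            for _ in range(3)
        ]
        pooled = combine_repeats(reps)
        assert pooled.bootstrap_samples.size == 600
        assert pooled.n_boot == 600

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_repeats([])

    def test_estimate_without_samples_rejected(self):
        with pytest.raises(ValueError, match="bootstrap samples"):
            combine_repeats([FreeEnergyEstimate(value=0.0, sd=0.1)])


class TestReducedPotentialData:
    def test_fewer_than_two_states_rejected(self):
        with pytest.raises(ValueError, match="two states"):
            ReducedPotentialData(u=np.zeros((1, 1, 5)), N_k=[5])

    def test_non_finite_potentials_rejected(self):
        u = np.zeros((2, 2, 3))
        u[0, 1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            ReducedPotentialData(u=u, N_k=[3, 3])

    def test_round_trip_through_sample_lists(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 50, seed=15)
        rows = [res.data.u[k, :, : res.data.N_k[k]].T for k in range(2)]
        rebuilt = ReducedPotentialData.from_sample_lists(rows)
        np.testing.assert_array_equal(rebuilt.u, res.data.u)
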