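"""Toy host-guest system: potential, sampling, oracles, end-to-end cycle."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from abfe.mbar import bootstrap_free_energy, mbar_solve
from abfe.restraints import internal_coordinates, restraint_energy
from abfe.schedule import LambdaSchedule, LambdaState, build_lambda_schedule
from abfe.thermo import COULOMB_CONSTANT, ThermoState
from abfe.toy import (
    DESK_DLAM_COUL,
    DESK_DLAM_VDW,
    EstimatorConfig,
    HrexConfig,
    SoftCoreParams,
    ToyModel,
    quadrature_binding_dG,
    run_full_toy_pipeline,
    run_hrex,
    sample_gaussian_states,
    softcore_pair_energy,
    toy_potential,
)

KT = 0.0019872041 * 298.15


def desk_schedule(env):
    return build_lambda_schedule(env, dlam_coul=DESK_DLAM_COUL, dlam_vdw=DESK_DLAM_VDW)


class TestToyPotential:
    def test_fully_decoupled_unrestrained_is_zero(self, toy_model):
        coords = toy_model.place(np.array([5.0, 1.0, -2.0]), np.eye(3))
        assert toy_potential(coords, 0.0, 0.0, 0.0, toy_model) == 0.0

    def test_plain_lj_zero_crossing_at_sigma(self):
        assert softcore_pair_energy(3.1, sigma=3.1, epsilon=0.4, lam_vdw=1.0) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_softcore_finite_at_contact(self):
        # lam = 0.5, alpha = 0.5, p = 1 at r = 0: 0.5*4*eps*(16 - 4) = 24 eps
        eps = 0.7
        e = softcore_pair_energy(0.0, sigma=3.0, epsilon=eps, lam_vdw=0.5)
        assert e == pytest.approx(24.0 * eps)

    def test_reduces_to_lj_plus_coulomb_at_full_coupling(self, toy_model):
        rng = np.random.default_rng(0)
        coords = toy_model.place(rng.uniform(-6, 6, 3), np.eye(3))
        e = toy_potential(coords, 0.0, 1.0, 1.0, toy_model)
        # direct pairwise reference
        diff = coords[None, :, :] - toy_model.host_coords[:, None, :]
        r = np.sqrt((diff**2).sum(axis=-1))
        sig = 0.5 * (toy_model.host_sigma[:, None] + toy_model.guest_sigma[None, :])
        epsm = np.sqrt(
            toy_model.host_epsilon[:, None] * toy_model.guest_epsilon[None, :]
        )
        lj = (4 * epsm * ((sig / r) ** 12 - (sig / r) ** 6)).sum()
        coul = (
            COULOMB_CONSTANT
            * toy_model.host_charge[:, None]
            * toy_model.guest_charge[None, :]
            / r
        ).sum()
        assert e == pytest.approx(lj + coul, rel=1e-12)

    def test_continuous_in_lambda(self, toy_model):
        coords = toy_model.place(np.array([3.0, 0.0, 1.0]), np.eye(3))
        lams = np.linspace(0.0, 1.0, 201)
        e = np.array([toy_potential(coords, 0.0, 0.0, lv, toy_model) for lv in lams])
        assert np.all(np.isfinite(e))
        assert np.max(np.abs(np.diff(e))) < 0.5  # no jumps on a fine grid

    def test_restraint_contribution_scales_linearly(self, toy_model):
        coords = toy_model.place(
            toy_model.reference_position + 0.5, toy_model.reference_rotation
        )
        e0 = toy_potential(coords, 0.0, 0.0, 0.0, toy_model)
        e1 = toy_potential(coords, 1.0, 0.0, 0.0, toy_model)
        e_half = toy_potential(coords, 0.5, 0.0, 0.0, toy_model)
        assert e_half - e0 == pytest.approx(0.5 * (e1 - e0), rel=1e-12)

    def test_lambda_outside_unit_interval_rejected(self, toy_model):
        coords = toy_model.place(np.zeros(3) + 4.0, np.eye(3))
        with pytest.raises(ValueError, match="lam_vdw"):
            toy_potential(coords, 0.0, 0.0, 1.5, toy_model)

    def test_softcore_alpha_must_be_positive(self):
        with pytest.raises(ValueError, match="alpha"):
            SoftCoreParams(alpha=0.0)

    def test_fast_restraint_path_matches_general_route(self, toy_model):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        pos = rng.uniform(-8, 8, (200, 3))
        rot = Rotation.random(200, rng=rng).as_matrix()
        coords = toy_model.place(pos, rot)
        fast = toy_model.fast_restraint_energy(coords)
        general = restraint_energy(
            internal_coordinates(toy_model.host_coords, coords), toy_model.restraint
        )
        np.testing.assert_allclose(fast, general, atol=1e-10)


class TestGaussianHarness:
    def test_identical_states_have_zero_analytic_difference(self):
        res = sample_gaussian_states([1.5, 1.5], [0.0, 0.0], 100, seed=0)
        assert res.f_analytic[1] == 0.0

    def test_sigma_ratio_sets_the_analytic_difference(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 100, seed=1)
        assert res.f_analytic[1] == pytest.approx(-math.log(2.0))

    def test_mbar_recovers_the_analytic_ladder(self):
        res = sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 4000, seed=2)
        est = bootstrap_free_energy(res.data, (0, 1), n_boot=50, seed=3)
        truth = res.data.kT * res.f_analytic[1]
        assert abs(est.value - truth) <= 3.0 * est.sd

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sample_gaussian_states([1.0, 2.0], [0.0, 0.0], 1, seed=0)


class TestHrex:
    def test_identical_hamiltonians_swap_freely(self, toy_model):
        # four identical solvent states: every swap accepted, uniform visits
        sched = LambdaSchedule(
            environment="solvent",
            states=tuple(LambdaState(0.0, 0.0, 0.0) for _ in range(4)),
        )
        result = run_hrex(
            toy_model, sched, HrexConfig(n_sweeps=2000, swap_interval=10, seed=0)
        )
        assert result.neighbor_acceptance == 1.0
        counts = result.state_visit_counts[0]
        assert counts.sum() == 200
        assert chisquare(counts).pvalue > 0.01

    def test_restrained_distance_satisfies_equipartition(self, toy_model):
        # harmonic coordinate: Var(r) = kT / K_r (decoupled, restraint only)
        model = toy_model.decoupled()
        sched = LambdaSchedule(
            environment="complex",
            states=(LambdaState(1.0, 0.0, 0.0), LambdaState(1.0, 0.0, 0.0)),
        )
        result = run_hrex(model, sched, HrexConfig(n_sweeps=12000, seed=1))
        pos = np.concatenate([result.positions[0], result.positions[1]])[200:]
        rot = np.concatenate([result.rotations[0], result.rotations[1]])[200:]
        r = internal_coordinates(model.host_coords, model.place(pos, rot))[:, 0]
        var = r.var(ddof=1)
        expected = KT / model.restraint.k_r
        # moment-based standard error with a conservative n_eff
        se = expected * math.sqrt(2.0 / (r.size / 4.0))
        assert abs(var - expected) <= 3.0 * se

    def test_two_region_occupancy_matches_boltzmann_weights(self, toy_model):
        # detailed balance: P(r < r0) for the r^2-weighted harmonic marginal
        model = toy_model.decoupled()
        sched = LambdaSchedule(
            environment="complex",
            states=(LambdaState(1.0, 0.0, 0.0), LambdaState(1.0, 0.0, 0.0)),
        )
        result = run_hrex(model, sched, HrexConfig(n_sweeps=12000, seed=2))
        pos = np.concatenate([result.positions[0], result.positions[1]])[200:]
        rot = np.concatenate([result.rotations[0], result.rotations[1]])[200:]
        r = internal_coordinates(model.host_coords, model.place(pos, rot))[:, 0]
        r0, k = model.restraint.r0, model.restraint.k_r
        dens = lambda x: x * x * math.exp(-0.5 * k * (x - r0) ** 2 / KT)
        below = quad(dens, 0.0, r0)[0]
        total = quad(dens, 0.0, r0 + 10.0)[0]
        p_expected = below / total
        p_observed = float(np.mean(r < r0))
        se = math.sqrt(p_expected * (1 - p_expected) / (r.size / 4.0))
        assert abs(p_observed - p_expected) <= 3.0 * se

    def test_coarser_spacing_lowers_neighbor_acceptance(self, toy_model):
        accs = {}
        for dlam in (0.25, 0.05):
            sched = build_lambda_schedule(
                "complex", dlam_coul=0.5, dlam_vdw=dlam, restraint_lambdas=[0.0, 1.0]
            )
            result = run_hrex(toy_model, sched, HrexConfig(n_sweeps=3000, seed=3))
            lo = sched.leg_boundaries["vdw_off"][0]
            accs[dlam] = float(
                np.mean(result.neighbor_acceptance_by_pair[lo:])
            )
        assert accs[0.25] < accs[0.05]

    def test_every_stored_sample_reproduces_its_energy_row(self, toy_model):
        result = run_hrex(
            toy_model, desk_schedule("complex"), HrexConfig(n_sweeps=1000, seed=4)
        )
        rng = np.random.default_rng(5)
        n_states = len(result.schedule)
        for _ in range(100):
            k = int(rng.integers(0, n_states))
            n = int(rng.integers(0, result.data.N_k[k]))
            stored = result.data.u[k, :, n]
            recomputed = result.recompute_u_row(k, n)
            np.testing.assert_allclose(recomputed, stored, atol=1e-8)

    def test_frozen_sampler_raises_diagnostics_error(self, toy_model):
        # an absurdly stiff restraint rejects every move: the sampler must
        # fail loudly instead of returning frozen samples
        import dataclasses

        from abfe.toy import DiagnosticsError

        stiff = dataclasses.replace(
            toy_model, restraint=toy_model.restraint.scale_force_constants(1e10)
        )
        sched = LambdaSchedule(
            environment="complex",
            states=(LambdaState(1.0, 0.0, 0.0), LambdaState(1.0, 0.0, 0.0)),
        )
        with pytest.raises(DiagnosticsError, match="calibration"):
            run_hrex(stiff, sched, HrexConfig(n_sweeps=400, seed=8))

    def test_acceptance_statistics_are_reported(self, toy_model):
        result = run_hrex(
            toy_model, desk_schedule("solvent"), HrexConfig(n_sweeps=500, seed=6)
        )
        assert 0.0 < result.move_acceptance <= 1.0
        assert 0.0 < result.any_state_jump_prob <= 1.0


class TestQuadratureOracle:
    def test_zero_coupling_reduces_to_volume_ratio(self, toy_model):
        # -kT ln(V_box / V0) for a 20 A box
        q = quadrature_binding_dG(toy_model.decoupled(), n_samples=200_000, seed=0)
        expected = -KT * math.log(20.0**3 / 1660.539)
        assert q.dG == pytest.approx(expected, abs=0.005)
        assert q.dG == pytest.approx(-0.932, abs=0.005)

    def test_doubling_standard_volume_shifts_by_kT_ln2(self, toy_model):
        q1 = quadrature_binding_dG(toy_model, n_samples=400_000, seed=1)
        big = dataclasses.replace(
            toy_model,
            thermo=ThermoState(standard_volume_A3=2 * 1660.539),
            restraint=toy_model.restraint,
        )
        q2 = quadrature_binding_dG(big, n_samples=400_000, seed=1)
        assert q2.dG - q1.dG == pytest.approx(KT * math.log(2.0), abs=1e-9)

    def test_deeper_well_binds_more_strongly(self, toy_model):
        q1 = quadrature_binding_dG(toy_model, seed=2)
        q4 = quadrature_binding_dG(
            toy_model.scaled_well(4.0), seed=2, rel_err_max=0.2
        )
        assert q4.dG < q1.dG

    def test_imprecise_integral_raises_oracle_precision_error(self, toy_model):
        from abfe.toy import OraclePrecisionError

        deep = toy_model.scaled_well(4.0)
        with pytest.raises(OraclePrecisionError, match="relative error"):
            quadrature_binding_dG(deep, n_samples=3000, seed=3)

    def test_reported_error_reflects_seed_scatter(self, toy_model):
        values = [
            quadrature_binding_dG(toy_model, n_samples=300_000, seed=s).dG
            for s in range(3)
        ]
        assert np.std(values) < 0.02


class TestFullPipeline:
    def test_identical_seed_reproduces_the_cycle_exactly(self, toy_model):
        runs = [
            run_full_toy_pipeline(
                toy_model,
                HrexConfig(n_sweeps=1500, seed=42),
                EstimatorConfig(n_boot=20, seed=42),
            )
            for _ in range(2)
        ]
        assert runs[0].dG_bind_standard == runs[1].dG_bind_standard
        assert runs[0].sd == runs[1].sd

    def test_inserting_intermediate_states_preserves_leg_free_energy(self, toy_model):
        # free energy is a state function: a denser vdW ladder must give the
        # same complex-leg total within combined noise
        results = []
        for dlam_vdw in (0.25, 0.125):
            sched = build_lambda_schedule(
                "complex", dlam_coul=0.25, dlam_vdw=dlam_vdw
            )
            run = run_hrex(toy_model, sched, HrexConfig(n_sweeps=8000, seed=7))
            est = bootstrap_free_energy(
                run.data, (len(sched) - 1, 0), n_boot=30, seed=8
            )
            results.append(est)
        a, b = results
        assert abs(a.value - b.value) <= 3.0 * math.hypot(a.sd, b.sd)
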