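"""Desk-scale host-guest system for validating the full analysis pipeline.

A rigid triatomic guest interacts with three fixed host sites through
soft-core Lennard-Jones and linearly scaled Coulomb terms, optionally held
by a Boresch restraint.  Sampling is Metropolis Monte Carlo over rigid-body
translations and rotations with Hamiltonian-exchange swap rounds between
the lambda windows (Gibbs-style random-pair mixing), which targets exactly
the same per-window Boltzmann distributions a molecular-dynamics engine
would.  Because the system is six-dimensional, the exact binding free
energy is available from stratified Monte Carlo integration of the bound
configurational integral, giving the pipeline a ground truth to be tested
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .mbar import (
    ReducedPotentialData,
    bootstrap_free_energies,
    bootstrap_free_energy,
    combine_repeats,
)
from .cycle import CycleResult, assemble_cycle
from .restraints import BoreschRestraint, boresch_analytic_dG, internal_coordinates, restraint_energy
from .schedule import LambdaSchedule, build_lambda_schedule
from .thermo import COULOMB_CONSTANT, ThermoState
from .timeseries import prepare_samples

__all__ = [
    "SoftCoreParams",
    "ToyModel",
    "HrexConfig",
    "EstimatorConfig",
    "HrexResult",
    "QuadratureResult",
    "DiagnosticsError",
    "OraclePrecisionError",
    "toy_potential",
    "softcore_pair_energy",
    "sample_gaussian_states",
    "run_hrex",
    "quadrature_binding_dG",
    "run_full_toy_pipeline",
]


def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cross product on the last axis without numpy.cross overhead."""
    return np.stack(
        (
            u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1],
            u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2],
            u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0],
        ),
        axis=-1,
    )


class DiagnosticsError(RuntimeError):
    """The sampler shows pathological behaviour (e.g. frozen moves)."""


class OraclePrecisionError(RuntimeError):
    """The quadrature oracle did not reach the requested precision."""


@dataclass(frozen=True)
class SoftCoreParams:
    """Beutler-type soft-core parameters for the vanishing vdW interaction."""

    alpha: float = 0.5
    lambda_power: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("soft-core alpha must be positive")
        if self.lambda_power < 1:
            raise ValueError("lambda power must be >= 1")


#: Desk-scale default spacings: about ten windows per decoupling leg.
DESK_DLAM_COUL = 0.25
DESK_DLAM_VDW = 0.125


@dataclass
class ToyModel:
    """Rigid triatomic guest bound to three fixed host sites.

    ``host_coords`` rows are the anchor points (c, b, a) with ``a`` the
    site closest to the guest; ``guest_geometry`` rows are the guest sites
    (A, B, C) in the body frame with A at the origin.  The guest samples
    only rigid-body translation (position of site A, bounded by the cubic
    box) and rotation.  Per-site LJ parameters are in kcal/mol and Å,
    charges in elementary charges.
    """

    guest_geometry: np.ndarray
    guest_sigma: np.ndarray
    guest_epsilon: np.ndarray
    guest_charge: np.ndarray
    host_coords: np.ndarray
    host_sigma: np.ndarray
    host_epsilon: np.ndarray
    host_charge: np.ndarray
    box_edge: float = 20.0
    restraint: BoreschRestraint | None = None
    thermo: ThermoState = field(default_factory=ThermoState)
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)
    reference_position: np.ndarray | None = None
    reference_rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in (
            "guest_geometry", "guest_sigma", "guest_epsilon", "guest_charge",
            "host_coords", "host_sigma", "host_epsilon", "host_charge",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.guest_geometry.shape != (3, 3) or self.host_coords.shape != (3, 3):
            raise ValueError("guest geometry and host coords must have shape (3, 3)")
        max_sigma = float(max(self.guest_sigma.max(), self.host_sigma.max()))
        if self.box_edge <= 4.0 * max_sigma:
            raise ValueError(
                f"box edge {self.box_edge} must exceed 4 * max sigma = {4 * max_sigma}"
            )
        if np.any(self.guest_epsilon < 0) or np.any(self.host_epsilon < 0):
            raise ValueError("epsilon values must be non-negative")
        if self.reference_position is None:
            self.reference_position = np.zeros(3)
        else:
            self.reference_position = np.asarray(self.reference_position, dtype=np.float64)
        if self.reference_rotation is None:
            self.reference_rotation = np.eye(3)
        else:
            self.reference_rotation = np.asarray(self.reference_rotation, dtype=np.float64)
        if self.restraint is None:
            ic = internal_coordinates(self.host_coords, self.place(self.reference_position, self.reference_rotation))
            self.restraint = BoreschRestraint(
                r0=float(ic[0]), theta_A0=float(ic[1]), theta_B0=float(ic[2]),
                phi_A0=float(ic[3]), phi_B0=float(ic[4]), phi_C0=float(ic[5]),
            )
        # precomputed Lorentz-Berthelot pair parameters, host-major order
        sig = 0.5 * (self.host_sigma[:, None] + self.guest_sigma[None, :])
        eps = np.sqrt(self.host_epsilon[:, None] * self.guest_epsilon[None, :])
        qq = COULOMB_CONSTANT * self.host_charge[:, None] * self.guest_charge[None, :]
        self._sigma6 = (sig**6).ravel()
        self._eps4 = (4.0 * eps).ravel()
        self._qq = qq.ravel()
        self._init_restraint_cache()

    def _init_restraint_cache(self) -> None:
        # host-side geometric constants for the fast restraint-energy path
        c, b, a = self.host_coords
        rst = self.restraint
        self._anchor_a = a
        self._ab = a - b                      # phiB b0
        self._ba = b - a                      # thetaA arm
        self._ba_len = float(np.linalg.norm(self._ba))
        b0A = b - c
        b1A = a - b
        self._n1A = _cross3(b0A, b1A)
        self._m1A = _cross3(self._n1A, b1A / np.linalg.norm(b1A))
        self._b1A = b1A
        deg = math.pi / 180.0
        self._ref_rad = np.array([
            rst.r0,
            rst.theta_A0 * deg, rst.theta_B0 * deg,
            rst.phi_A0 * deg, rst.phi_B0 * deg, rst.phi_C0 * deg,
        ])
        self._k_vec = np.array([
            rst.k_r, rst.k_theta_A, rst.k_theta_B,
            rst.k_phi_A, rst.k_phi_B, rst.k_phi_C,
        ])

    def fast_restraint_energy(self, guest_coords: np.ndarray) -> np.ndarray:
        """Restraint energy from guest site coordinates, shape (..., 3, 3).

        Numerically identical to composing :func:`internal_coordinates`
        with :func:`restraint_energy`, using cached host-side geometry.
        """
        A = guest_coords[..., 0, :]
        B = guest_coords[..., 1, :]
        C = guest_coords[..., 2, :]
        rv = A - self._anchor_a
        r = np.sqrt(np.sum(rv * rv, axis=-1))
        AB = B - A
        ab_len = np.sqrt(np.sum(AB * AB, axis=-1))
        theta_A = np.arccos(
            np.clip(np.sum(self._ba * rv, axis=-1) / (self._ba_len * r), -1.0, 1.0)
        )
        theta_B = np.arccos(
            np.clip(-np.sum(rv * AB, axis=-1) / (r * ab_len), -1.0, 1.0)
        )
        # phiA: dihedral(c, b, a, A); host-side normals cached
        n2 = _cross3(np.broadcast_to(self._b1A, rv.shape), rv)
        phi_A = np.arctan2(
            np.sum(self._m1A * n2, axis=-1), np.sum(self._n1A * n2, axis=-1)
        )
        # phiB: dihedral(b, a, A, B)
        n1 = _cross3(np.broadcast_to(self._ab, rv.shape), rv)
        n2 = _cross3(rv, AB)
        m1 = _cross3(n1, rv / r[..., None])
        phi_B = np.arctan2(np.sum(m1 * n2, axis=-1), np.sum(n1 * n2, axis=-1))
        # phiC: dihedral(a, A, B, C); shares rv x AB with phiB
        BC = C - B
        n1c = n2
        n2c = _cross3(AB, BC)
        m1c = _cross3(n1c, AB / ab_len[..., None])
        phi_C = np.arctan2(np.sum(m1c * n2c, axis=-1), np.sum(n1c * n2c, axis=-1))

        ref = self._ref_rad
        k = self._k_vec
        two_pi = 2.0 * math.pi
        d_phi_A = np.remainder(phi_A - ref[3] + math.pi, two_pi) - math.pi
        d_phi_B = np.remainder(phi_B - ref[4] + math.pi, two_pi) - math.pi
        d_phi_C = np.remainder(phi_C - ref[5] + math.pi, two_pi) - math.pi
        return 0.5 * (
            k[0] * (r - ref[0]) ** 2
            + k[1] * (theta_A - ref[1]) ** 2
            + k[2] * (theta_B - ref[2]) ** 2
            + k[3] * d_phi_A**2
            + k[4] * d_phi_B**2
            + k[5] * d_phi_C**2
        )

    def place(self, position: np.ndarray, rotation: np.ndarray) -> np.ndarray:
        """Guest site coordinates for a rigid-body pose.

        ``position`` is the lab-frame location of site A; ``rotation`` a
        3x3 matrix (or stack thereof).
        """
        position = np.asarray(position, dtype=np.float64)
        rotation = np.asarray(rotation, dtype=np.float64)
        coords = np.einsum("...ij,kj->...ki", rotation, self.guest_geometry)
        return coords + position[..., None, :]

    def pair_distances_sq(self, guest_coords: np.ndarray) -> np.ndarray:
        """Squared host-guest site distances, shape (..., 9)."""
        diff = guest_coords[..., None, :, :] - self.host_coords[..., :, None, :]
        r2 = np.sum(diff * diff, axis=-1)
        return r2.reshape(*r2.shape[:-2], 9)

    def interaction_energy(
        self,
        guest_coords: np.ndarray,
        lam_coul: float | np.ndarray,
        lam_vdw: float | np.ndarray,
    ) -> np.ndarray:
        """Host-guest nonbonded energy in kcal/mol at given couplings."""
        r2 = self.pair_distances_sq(guest_coords)
        return self.interaction_energy_from_r2(r2, lam_coul, lam_vdw)

    def interaction_energy_from_r2(
        self,
        r2: np.ndarray,
        lam_coul: float | np.ndarray,
        lam_vdw: float | np.ndarray,
    ) -> np.ndarray:
        lam_coul = np.asarray(lam_coul, dtype=np.float64)
        lam_vdw = np.asarray(lam_vdw, dtype=np.float64)
        alpha = self.softcore.alpha
        p = self.softcore.lambda_power
        r6 = r2**3
        lv = lam_vdw[..., None]
        with np.errstate(divide="ignore"):
            denom = alpha * self._sigma6 * (1.0 - lv) + r6
            e_vdw = (
                lv**p
                * self._eps4
                * (self._sigma6**2 / denom**2 - self._sigma6 / denom)
            ).sum(axis=-1)
            e_coul = lam_coul * (self._qq / np.sqrt(r2)).sum(axis=-1)
        return e_vdw + e_coul

    def restraint_energy_of(self, guest_coords: np.ndarray) -> np.ndarray:
        ic = internal_coordinates(self.host_coords, guest_coords)
        return restraint_energy(ic, self.restraint)

    def decoupled(self) -> "ToyModel":
        """Copy with all host-guest interactions switched off (the
        zero-coupling limit); the restraint definition is retained."""
        return replace(
            self,
            guest_epsilon=np.zeros(3),
            guest_charge=np.zeros(3),
            restraint=self.restraint,
        )

    def scaled_well(self, epsilon_factor: float) -> "ToyModel":
        """Copy with all epsilon values scaled by ``epsilon_factor``."""
        return replace(
            self,
            guest_epsilon=self.guest_epsilon * epsilon_factor,
            host_epsilon=self.host_epsilon * epsilon_factor,
            restraint=self.restraint,
        )

    @classmethod
    def default(cls) -> "ToyModel":
        """The reference host-guest system used throughout the tests.

        A weakly polar triatomic guest bound in a moderate well (about
        -3.17 kcal/mol at the minimum, ~5.3 kT) near the three-site host,
        in a 20 Å cubic box at 298.15 K.  The well depth is chosen so the
        bound/unbound exchange relaxes in a small fraction of a desk-scale
        sampling run while binding remains clearly distinguishable from
        the zero-coupling limit.  The reference pose is the
        energy-minimized bound configuration; the Boresch restraint is
        defined at that pose with the canonical 10 kcal/mol/Å^2 (rad^2)
        force constants, and its internal coordinates (r0 = 3.66 Å,
        thetaA0 = 75°, thetaB0 = 67°) sit far from the angular poles.
        """
        host = np.array([
            [-1.6, -2.6, 0.9],  # c
            [-0.5, -1.5, 0.0],  # b
            [0.0, 0.0, 0.0],    # a
        ])
        geom = np.array([
            [0.0, 0.0, 0.0],    # A
            [0.5, 1.42, 0.0],   # B
            [1.7, 2.0, 0.4],    # C
        ])
        return cls(
            guest_geometry=geom,
            guest_sigma=np.array([3.2, 3.0, 3.0]),
            guest_epsilon=np.array([0.40, 0.32, 0.32]),
            guest_charge=np.array([-0.12, 0.08, 0.04]),
            host_coords=host,
            host_sigma=np.array([3.0, 3.0, 3.2]),
            host_epsilon=np.array([0.40, 0.32, 0.32]),
            host_charge=np.array([0.12, -0.16, 0.04]),
            box_edge=20.0,
            reference_position=np.array([-0.515, -0.8, 3.537]),
            reference_rotation=Rotation.from_rotvec(
                [-1.2856, -1.7141, 4.0218]
            ).as_matrix(),
        )


def softcore_pair_energy(
    r: float | np.ndarray,
    sigma: float,
    epsilon: float,
    lam_vdw: float,
    softcore: SoftCoreParams | None = None,
) -> float | np.ndarray:
    """Soft-core Lennard-Jones energy of a single site pair, kcal/mol.

        E = lam^p * 4 eps * [ sigma^12 / (alpha sigma^6 (1-lam) + r^6)^2
                              - sigma^6 / (alpha sigma^6 (1-lam) + r^6) ]

    Finite at r = 0 for lam < 1; the plain LJ potential at lam = 1.
    """
    softcore = softcore or SoftCoreParams()
    if not 0.0 <= lam_vdw <= 1.0:
        raise ValueError(f"lambda_vdw must lie in [0, 1], got {lam_vdw}")
    r6 = np.asarray(r, dtype=np.float64) ** 6
    s6 = sigma**6
    with np.errstate(divide="ignore"):
        denom = softcore.alpha * s6 * (1.0 - lam_vdw) + r6
        e = lam_vdw**softcore.lambda_power * 4.0 * epsilon * (s6**2 / denom**2 - s6 / denom)
    return e if np.ndim(e) else float(e)


def toy_potential(
    configuration: np.ndarray,
    lam_restr: float,
    lam_coul: float,
    lam_vdw: float,
    model: ToyModel,
    softcore: SoftCoreParams | None = None,
) -> float | np.ndarray:
    """Total potential energy of a guest configuration, kcal/mol.

    ``configuration`` holds the lab-frame guest site coordinates, shape
    (..., 3, 3).  The energy is

        U = lam_restr * E_restraint + lam_coul * E_coulomb + E_vdw(lam_vdw)

    with the soft-core vdW term finite for every separation when
    lam_vdw < 1.
    """
    for name, lam in (("lam_restr", lam_restr), ("lam_coul", lam_coul), ("lam_vdw", lam_vdw)):
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {lam}")
    if softcore is not None and softcore != model.softcore:
        model = replace(model, softcore=softcore, restraint=model.restraint)
    coords = np.asarray(configuration, dtype=np.float64)
    e = model.interaction_energy(coords, lam_coul, lam_vdw)
    if lam_restr > 0.0:
        e = e + lam_restr * model.restraint_energy_of(coords)
    return e if np.ndim(e) else float(e)


# ---------------------------------------------------------------------------
# Gaussian validation harness


@dataclass
class GaussianStatesResult:
    data: ReducedPotentialData
    f_analytic: np.ndarray


def sample_gaussian_states(
    sigmas: Sequence[float],
    mus: Sequence[float],
    n_samples: int,
    seed: int | None = None,
    temperature_K: float = 298.15,
) -> GaussianStatesResult:
    """Exact samples from a ladder of 1-D Gaussian states.

    State k has reduced potential u_k(x) = (x - mu_k)^2 / (2 sigma_k^2),
    hence dimensionless free energy f_k = -ln(sigma_k sqrt(2 pi)).  Used to
    validate the MBAR estimator against a closed form.
    """
    sigmas = np.asarray(sigmas, dtype=np.float64)
    mus = np.asarray(mus, dtype=np.float64)
    if sigmas.shape != mus.shape or sigmas.ndim != 1:
        raise ValueError("sigmas and mus must be 1-D and equally long")
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be positive")
    if n_samples < 2:
        raise ValueError(f"need at least 2 samples per state, got {n_samples}")
    K = sigmas.size
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(K):
        x = rng.normal(mus[k], sigmas[k], size=n_samples)
        u = (x[:, None] - mus[None, :]) ** 2 / (2.0 * sigmas[None, :] ** 2)
        rows.append(u)
    f = -np.log(sigmas * math.sqrt(2.0 * math.pi))
    f = f - f[0]
    data = ReducedPotentialData.from_sample_lists(rows, temperature_K=temperature_K)
    return GaussianStatesResult(data=data, f_analytic=f)


# ---------------------------------------------------------------------------
# Hamiltonian-exchange Monte Carlo


@dataclass(frozen=True)
class HrexConfig:
    """Sampler settings for the replica-exchange Monte Carlo run.

    A sweep is one rigid-body trial move per replica; every
    ``swap_interval`` sweeps an exchange round performs
    ``swap_attempts_per_round`` random-pair state swaps (default K^2), and
    one sample per state is retained every ``sample_interval`` rounds
    (every other round by default, so retained samples are only weakly
    correlated before decorrelation analysis).
    """

    n_sweeps: int = 20000
    swap_interval: int = 10
    sample_interval: int = 2
    swap_attempts_per_round: int | None = None
    translation_step: float = 0.5
    rotation_step_deg: float = 20.0
    #: fraction of trial moves that propose a uniform reposition and
    #: reorientation in the whole box (symmetric proposal); these teleport
    #: replicas at weakly coupled states and cut positional correlation times
    jump_probability: float = 0.1
    seed: int = 0
    calibration_window: int = 200

    def __post_init__(self) -> None:
        if self.n_sweeps < 1 or self.swap_interval < 1 or self.sample_interval < 1:
            raise ValueError("sweep counts must be positive")
        if self.swap_attempts_per_round is not None and self.swap_attempts_per_round < 1:
            raise ValueError("swap_attempts_per_round must be positive")
        if self.translation_step <= 0 or self.rotation_step_deg <= 0:
            raise ValueError("move step sizes must be positive")
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValueError("jump probability must lie in [0, 1]")


@dataclass
class HrexResult:
    """Samples and diagnostics from one replica-exchange run."""

    data: ReducedPotentialData
    schedule: LambdaSchedule
    model: ToyModel
    positions: list[np.ndarray]       # per state, (n_samples, 3)
    rotations: list[np.ndarray]       # per state, (n_samples, 3, 3)
    move_acceptance: float
    neighbor_acceptance: float
    any_state_jump_prob: float
    #: per adjacent state pair (i, i+1): swap acceptance rate
    neighbor_acceptance_by_pair: np.ndarray | None = None
    #: visit counts, shape (K replicas, K states), one count per exchange round
    state_visit_counts: np.ndarray | None = None

    def recompute_u_row(self, state: int, sample: int) -> np.ndarray:
        """Re-evaluate the reduced potentials of a stored sample at all
        states (bookkeeping audit)."""
        coords = self.model.place(
            self.positions[state][sample], self.rotations[state][sample]
        )
        lam = self.schedule.as_array()
        if self.schedule.environment == "solvent":
            return np.zeros(len(self.schedule))
        r2 = self.model.pair_distances_sq(coords)
        e = self.model.interaction_energy_from_r2(
            np.broadcast_to(r2, (lam.shape[0], 9)), lam[:, 1], lam[:, 2]
        )
        e = e + lam[:, 0] * self.model.restraint_energy_of(coords)
        return e / self.model.thermo.kT


def run_hrex(
    model: ToyModel,
    schedule: LambdaSchedule,
    config: HrexConfig | None = None,
) -> HrexResult:
    """Sample every lambda window with replica-exchange Monte Carlo.

    One replica runs per state.  Between exchange rounds each replica
    performs Metropolis rigid-body moves at its current state; exchange
    rounds attempt many random state-pair swaps with Metropolis acceptance
    on the reduced-potential differences, which approximates Gibbs
    sampling of the replica-state permutation.  At the end of each round
    one sample per state is retained with its reduced potential evaluated
    at every state of the schedule.

    In the solvent environment the rigid guest has no interaction partners,
    so all reduced potentials vanish identically and the run is a pure
    bookkeeping exercise.

    Returns
    -------
    HrexResult
    """
    config = config or HrexConfig()
    K = len(schedule)
    if K < 2:
        raise ValueError("schedule must contain at least 2 states")
    lam = schedule.as_array()
    lam_r, lam_c, lam_v = lam[:, 0], lam[:, 1], lam[:, 2]
    kT = model.thermo.kT
    beta = 1.0 / kT
    solvent = schedule.environment == "solvent"
    rng = np.random.default_rng(config.seed)
    n_rounds = config.n_sweeps // config.swap_interval
    n_attempts = config.swap_attempts_per_round or K * K
    half = model.box_edge / 2.0

    # all replicas start at the bound reference pose
    pos = np.tile(model.reference_position, (K, 1)).astype(np.float64)
    rot = np.tile(model.reference_rotation, (K, 1, 1)).astype(np.float64)
    state_of_replica = np.arange(K)

    def potential_at_own_state(p: np.ndarray, r: np.ndarray) -> np.ndarray:
        if solvent:
            return np.zeros(K)
        coords = model.place(p, r)
        r2 = model.pair_distances_sq(coords)
        s = state_of_replica
        e = model.interaction_energy_from_r2(r2, lam_c[s], lam_v[s])
        return e + lam_r[s] * model.fast_restraint_energy(coords)

    u_self = potential_at_own_state(pos, rot)

    n_samples = len(range(0, n_rounds, config.sample_interval))
    samples_u = [np.empty((n_samples, K)) for _ in range(K)]
    samples_pos = [np.empty((n_samples, 3)) for _ in range(K)]
    samples_rot = [np.empty((n_samples, 3, 3)) for _ in range(K)]
    sample_idx = 0

    moves_attempted = 0
    moves_accepted = 0
    calib_accepted = 0
    neighbor_attempts = np.zeros(K - 1, dtype=np.int64)
    neighbor_accepts = np.zeros(K - 1, dtype=np.int64)
    visit_counts = np.zeros((K, K), dtype=np.int64)
    jumps = 0
    jump_opportunities = 0

    for rnd in range(n_rounds):
        # one batch of move randomness per exchange round
        S = config.swap_interval
        dts = rng.normal(0.0, config.translation_step, size=(S, K, 3))
        angles = rng.uniform(
            -math.radians(config.rotation_step_deg),
            math.radians(config.rotation_step_deg),
            size=(S, K),
        )
        axes = rng.normal(size=(S, K, 3))
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
        drots = Rotation.from_rotvec(
            (axes * angles[..., None]).reshape(-1, 3)
        ).as_matrix().reshape(S, K, 3, 3)
        jump = rng.uniform(size=(S, K)) < config.jump_probability
        jump_pos = rng.uniform(-half, half, size=(S, K, 3))
        quat = rng.normal(size=(S * K, 4))
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        jump_rot = Rotation.from_quat(quat).as_matrix().reshape(S, K, 3, 3)
        move_unif = rng.uniform(size=(S, K))
        for sweep in range(S):
            j = jump[sweep]
            new_pos = np.where(j[:, None], jump_pos[sweep], pos + dts[sweep])
            new_rot = np.where(
                j[:, None, None],
                jump_rot[sweep],
                np.einsum("kij,kjl->kil", drots[sweep], rot),
            )
            in_box = np.all(np.abs(new_pos) <= half, axis=1)
            new_u = potential_at_own_state(new_pos, new_rot)
            du = beta * (new_u - u_self)
            with np.errstate(over="ignore"):
                prob = np.exp(np.minimum(0.0, -du))
            accept = in_box & (move_unif[sweep] < prob)
            pos[accept] = new_pos[accept]
            rot[accept] = new_rot[accept]
            u_self[accept] = new_u[accept]
            moves_attempted += K
            n_acc = int(accept.sum())
            moves_accepted += n_acc
            if rnd * config.swap_interval + sweep < config.calibration_window:
                calib_accepted += n_acc

        if (
            rnd * config.swap_interval + config.swap_interval
            >= config.calibration_window
            and moves_attempted >= config.calibration_window * K
            and calib_accepted == 0
            and not solvent
        ):
            raise DiagnosticsError(
                "no Monte Carlo move was accepted during the calibration window; "
                "check step sizes and the model"
            )

        # cross-evaluate every replica at every state
        if solvent:
            u_all = np.zeros((K, K))
        else:
            coords = model.place(pos, rot)
            r2 = model.pair_distances_sq(coords)          # (K, 9)
            e_restr = model.fast_restraint_energy(coords)  # (K,)
            e_inter = model.interaction_energy_from_r2(
                r2[:, None, :], lam_c[None, :], lam_v[None, :]
            )                                             # (K replicas, K states)
            u_all = beta * (e_inter + lam_r[None, :] * e_restr[:, None])

        states_before = state_of_replica.copy()
        attempts_done = 0
        replica_idx = np.arange(K)
        while attempts_done < n_attempts:
            perm = rng.permutation(K)
            n_pairs = K // 2
            a = perm[:n_pairs]
            b = perm[n_pairs : 2 * n_pairs]
            sa = state_of_replica[a]
            sb = state_of_replica[b]
            delta = (
                u_all[a, sb] + u_all[b, sa] - u_all[a, sa] - u_all[b, sb]
            )
            with np.errstate(over="ignore"):
                p_swap = np.exp(np.minimum(0.0, -delta))
            do_swap = rng.uniform(size=n_pairs) < p_swap
            state_of_replica[a[do_swap]] = sb[do_swap]
            state_of_replica[b[do_swap]] = sa[do_swap]
            neighbor_mask = np.abs(sa - sb) == 1
            if np.any(neighbor_mask):
                lo = np.minimum(sa, sb)[neighbor_mask]
                np.add.at(neighbor_attempts, lo, 1)
                np.add.at(neighbor_accepts, lo[do_swap[neighbor_mask]], 1)
            attempts_done += n_pairs
        jumps += int((state_of_replica != states_before).sum())
        jump_opportunities += K
        visit_counts[replica_idx, state_of_replica] += 1

        # recombine cached own-state energies after the permutation changed
        if not solvent:
            u_self = kT * u_all[replica_idx, state_of_replica]

        if rnd % config.sample_interval == 0:
            replica_of_state = np.empty(K, dtype=np.intp)
            replica_of_state[state_of_replica] = replica_idx
            for l in range(K):
                r_i = replica_of_state[l]
                samples_u[l][sample_idx] = u_all[r_i]
                samples_pos[l][sample_idx] = pos[r_i]
                samples_rot[l][sample_idx] = rot[r_i]
            sample_idx += 1

    data = ReducedPotentialData.from_sample_lists(
        samples_u,
        temperature_K=model.thermo.temperature_K,
        state_labels=[f"{schedule.environment}:{i}" for i in range(K)],
    )
    return HrexResult(
        data=data,
        schedule=schedule,
        model=model,
        positions=samples_pos,
        rotations=samples_rot,
        move_acceptance=moves_accepted / max(moves_attempted, 1),
        neighbor_acceptance=float(
            neighbor_accepts.sum() / max(neighbor_attempts.sum(), 1)
        ),
        any_state_jump_prob=jumps / max(jump_opportunities, 1),
        neighbor_acceptance_by_pair=neighbor_accepts / np.maximum(neighbor_attempts, 1),
        state_visit_counts=visit_counts,
    )


# ---------------------------------------------------------------------------
# Exact oracle


@dataclass(frozen=True)
class QuadratureResult:
    """Exact standard binding free energy with Monte Carlo standard error."""

    dG: float
    se: float
    n_samples: int

    def __float__(self) -> float:
        return self.dG


def quadrature_binding_dG(
    model: ToyModel,
    n_samples: int = 1_500_000,
    seed: int = 0,
    rel_err_max: float = 0.01,
    sphere_radius: float | None = None,
) -> QuadratureResult:
    """Exact standard binding free energy of the toy model.

        dG = -kT * ln( Z_bound / (8 pi^2 V0) )

    with Z_bound the configurational integral of the fully coupled,
    unrestrained guest over the box and all orientations.  Evaluated by
    stratified Monte Carlo: a sphere around the host (where the well
    lives) and the remainder of the box are integrated separately with
    uniform sampling; the standard error of the estimate is propagated to
    the free energy.

    Raises
    ------
    OraclePrecisionError
        If the relative error of Z exceeds ``rel_err_max``.
    """
    kT = model.thermo.kT
    beta = 1.0 / kT
    rng = np.random.default_rng(seed)
    L = model.box_edge
    half = L / 2.0
    centroid = model.host_coords.mean(axis=0)
    if sphere_radius is None:
        reach = float(np.linalg.norm(model.host_coords - centroid, axis=1).max())
        geom_reach = float(np.linalg.norm(model.guest_geometry, axis=1).max())
        fits = half - float(np.abs(centroid).max())
        sphere_radius = min(reach + geom_reach + 5.0, fits)
    v_sphere = 4.0 / 3.0 * math.pi * sphere_radius**3
    v_box = L**3
    if v_sphere >= v_box:
        raise ValueError("stratification sphere does not fit in the box")

    n_a = (2 * n_samples) // 3
    n_b = n_samples - n_a

    def boltzmann(positions: np.ndarray, chunk: int = 200_000) -> np.ndarray:
        out = np.empty(positions.shape[0])
        for start in range(0, positions.shape[0], chunk):
            sl = slice(start, start + chunk)
            p = positions[sl]
            quat = rng.normal(size=(p.shape[0], 4))
            quat /= np.linalg.norm(quat, axis=1, keepdims=True)
            rots = Rotation.from_quat(quat).as_matrix()
            coords = model.place(p, rots)
            e = model.interaction_energy(coords, 1.0, 1.0)
            with np.errstate(over="ignore"):
                out[sl] = np.exp(np.minimum(-beta * e, 700.0))
        return out

    # stratum A: uniform in the sphere around the host
    dirs = rng.normal(size=(n_a, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = sphere_radius * rng.uniform(size=n_a) ** (1.0 / 3.0)
    pos_a = centroid + dirs * radii[:, None]
    # clip: sphere must stay inside the box for the strata to partition it
    if np.any(np.abs(pos_a) > half):
        raise ValueError("stratification sphere extends outside the box")
    w_a = boltzmann(pos_a)

    # stratum B: uniform in the box minus the sphere, by rejection
    collected = []
    n_need = n_b
    while n_need > 0:
        cand = rng.uniform(-half, half, size=(int(n_need * 1.5) + 16, 3))
        dist = np.linalg.norm(cand - centroid, axis=1)
        cand = cand[dist > sphere_radius][:n_need]
        collected.append(cand)
        n_need -= cand.shape[0]
    pos_b = np.concatenate(collected, axis=0)
    w_b = boltzmann(pos_b)

    mean_a, mean_b = w_a.mean(), w_b.mean()
    var_a = w_a.var(ddof=1) / n_a
    var_b = w_b.var(ddof=1) / n_b
    z_over_8pi2 = v_sphere * mean_a + (v_box - v_sphere) * mean_b
    se_z = math.sqrt(v_sphere**2 * var_a + (v_box - v_sphere) ** 2 * var_b)
    rel = se_z / z_over_8pi2
    if rel > rel_err_max:
        raise OraclePrecisionError(
            f"quadrature relative error {rel:.2%} exceeds {rel_err_max:.2%}; "
            "increase n_samples"
        )
    dG = -kT * math.log(z_over_8pi2 / model.thermo.standard_volume_A3)
    return QuadratureResult(dG=dG, se=kT * rel, n_samples=n_samples)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class EstimatorConfig:
    """Free-energy estimation settings for the pipeline.

    ``n_repeats`` independent repeats of the whole calculation are run
    and their bootstrap samples pooled per leg, so the reported
    uncertainty carries both estimator noise and repeat-to-repeat
    scatter (single-run bootstrap alone underestimates it).
    """

    discard_fraction: float = 0.1
    n_boot: int = 200
    n_repeats: int = 2
    seed: int = 0
    tolerance: float = 1e-10
    max_iterations: int = 10000


def run_full_toy_pipeline(
    model: ToyModel,
    hrex_config: HrexConfig | None = None,
    estimator_config: EstimatorConfig | None = None,
    complex_schedule: LambdaSchedule | None = None,
    solvent_schedule: LambdaSchedule | None = None,
) -> CycleResult:
    """Simulate the whole cycle on the toy system and assemble dG_bind.

    Both environments are sampled with replica-exchange Monte Carlo on
    their lambda schedules (desk-scale spacings by default: coulomb 0.25,
    vdW 0.125, the full 12-value restraint list), each window's energy
    series is equilibration-trimmed and decorrelated, leg free energies
    are estimated with bootstrapped MBAR, the whole calculation is
    repeated ``n_repeats`` times with pooled bootstrap samples, the
    analytic restraint term is added and the cycle closed.  The result is
    directly comparable to :func:`quadrature_binding_dG` on the same
    model.
    """
    hrex_config = hrex_config or HrexConfig()
    est = estimator_config or EstimatorConfig()
    if complex_schedule is None:
        complex_schedule = build_lambda_schedule(
            "complex", dlam_coul=DESK_DLAM_COUL, dlam_vdw=DESK_DLAM_VDW
        )
    if solvent_schedule is None:
        solvent_schedule = build_lambda_schedule(
            "solvent", dlam_coul=DESK_DLAM_COUL, dlam_vdw=DESK_DLAM_VDW
        )
    base_seed = int(hrex_config.seed)

    def decorrelated(result: HrexResult) -> ReducedPotentialData:
        series = result.data.own_state_series()
        if all(np.allclose(s, s[0]) for s in series):
            # degenerate environment (identically zero energies): plain trim
            n = series[0].size
            start = int(math.floor(est.discard_fraction * n))
            idx = [np.arange(start, n) for _ in series]
        else:
            idx, _ = prepare_samples(series, est.discard_fraction)
        return result.data.subsample(idx)

    i_restr_on = complex_schedule.leg_boundaries["restraint_on"][1]
    i_last = len(complex_schedule) - 1
    solv_reps, prot_ev_reps, prot_restr_reps = [], [], []
    for rep in range(est.n_repeats):
        off = 1000 * rep
        solv_run = run_hrex(
            model, solvent_schedule, replace(hrex_config, seed=base_seed + 101 + off)
        )
        comp_run = run_hrex(
            model, complex_schedule, replace(hrex_config, seed=base_seed + 202 + off)
        )
        solv_data = decorrelated(solv_run)
        comp_data = decorrelated(comp_run)

        # solvent decoupling, direction coupled -> decoupled
        solv_reps.append(
            bootstrap_free_energy(
                solv_data,
                endpoints=(0, len(solvent_schedule) - 1),
                n_boot=est.n_boot,
                seed=est.seed + 303 + off,
                tolerance=est.tolerance,
                max_iterations=est.max_iterations,
            )
        )
        # complex recoupling (decoupled+restrained -> coupled+restrained)
        # and restraint release (coupled+restrained -> coupled), sharing
        # one MBAR solution per replicate
        dg_prot_ev, dg_prot_restr = bootstrap_free_energies(
            comp_data,
            [(i_last, i_restr_on), (i_restr_on, 0)],
            n_boot=est.n_boot,
            seed=est.seed + 404 + off,
            tolerance=est.tolerance,
            max_iterations=est.max_iterations,
        )
        prot_ev_reps.append(dg_prot_ev)
        prot_restr_reps.append(dg_prot_restr)

    dg_solv_restr = boresch_analytic_dG(model.restraint, model.thermo)
    return assemble_cycle(
        {
            "dG_solv_elec_vdw": combine_repeats(solv_reps),
            "dG_solv_restr": dg_solv_restr,
            "dG_prot_elec_vdw": combine_repeats(prot_ev_reps),
            "dG_prot_restr": combine_repeats(prot_restr_reps),
        },
        thermo=model.thermo,
    )
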