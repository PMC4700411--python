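"""Multistate Bennett acceptance ratio (MBAR) estimation with bootstrap errors.

Given samples drawn from K thermodynamic states and the reduced potential of
every sample evaluated at every state, MBAR is the statistically optimal
estimator of the dimensionless free energies f_k of the states.  The solver
here uses self-consistent iteration with log-sum-exp stabilization and
switches to a damped Newton step on the (convex) MBAR objective when the
iteration stalls.  Reported uncertainties always come from bootstrap
resampling of the decorrelated data, with the first replicate being the
original sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .thermo import BOLTZMANN_KCAL_MOL_K

__all__ = [
    "ReducedPotentialData",
    "FreeEnergyEstimate",
    "MbarSolution",
    "ConvergenceError",
    "mbar_solve",
    "mbar_weights",
    "mbar_asymptotic_covariance",
    "bootstrap_free_energy",
    "bootstrap_free_energies",
    "combine_repeats",
]

#: Adjacent-state overlap below this value raises the low-overlap flag.
OVERLAP_WARNING_THRESHOLD = 1e-6


class ConvergenceError(RuntimeError):
    """MBAR self-consistency not reached within the iteration budget."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ReducedPotentialData:
    """Cross-evaluated reduced potentials u_kln for K states.

    Attributes
    ----------
    u : ndarray, shape (K, K, N_max)
        ``u[k, l, n]`` is the reduced (dimensionless) potential of sample n
        drawn from state k, evaluated at state l.  Rows beyond ``N_k[k]``
        samples are padding and ignored.
    N_k : ndarray of int, shape (K,)
        Number of valid samples per sampled state.
    temperature_K : float
        Temperature at which the reduced potentials were formed; used only
        for conversion to kcal/mol.
    state_labels : sequence of str
        Ordered identifiers of the states.
    """

    u: np.ndarray
    N_k: np.ndarray
    temperature_K: float = 298.15
    state_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.N_k = np.asarray(self.N_k, dtype=np.intp)
        if self.u.ndim != 3 or self.u.shape[0] != self.u.shape[1]:
            raise ValueError(
                f"u must have shape (K, K, N_max), got {self.u.shape}"
            )
        K = self.u.shape[0]
        if K < 2:
            raise ValueError("at least two states are required")
        if self.N_k.shape != (K,):
            raise ValueError("N_k must have one entry per state")
        if np.any(self.N_k < 0) or int(self.N_k.sum()) < 2:
            raise ValueError("sample counts must be non-negative and sum to >= 2")
        if np.any(self.N_k > self.u.shape[2]):
            raise ValueError("N_k exceeds the sample capacity of u")
        for k in range(K):
            if not np.all(np.isfinite(self.u[k, :, : self.N_k[k]])):
                raise ValueError(f"non-finite reduced potential in state {k}")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.state_labels is None:
            self.state_labels = [str(k) for k in range(K)]
        elif len(self.state_labels) != K:
            raise ValueError("state_labels length must equal K")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def kT(self) -> float:
        """Thermal energy in kcal/mol at the data temperature."""
        return BOLTZMANN_KCAL_MOL_K * self.temperature_K

    @classmethod
    def from_sample_lists(
        cls,
        u_rows_per_state: Sequence[np.ndarray],
        temperature_K: float = 298.15,
        state_labels: Sequence[str] | None = None,
    ) -> "ReducedPotentialData":
        """Build from per-state arrays of shape (N_k, K) of cross-evaluations."""
        K = len(u_rows_per_state)
        N_k = np.array([np.asarray(r).shape[0] for r in u_rows_per_state], dtype=np.intp)
        n_max = int(N_k.max()) if K else 0
        u = np.zeros((K, K, n_max), dtype=np.float64)
        for k, rows in enumerate(u_rows_per_state):
            rows = np.asarray(rows, dtype=np.float64)
            if rows.ndim != 2 or rows.shape[1] != K:
                raise ValueError(
                    f"state {k}: expected shape (N, {K}), got {rows.shape}"
                )
            u[k, :, : N_k[k]] = rows.T
        return cls(u=u, N_k=N_k, temperature_K=temperature_K, state_labels=state_labels)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (u_nl matrix of shape (N_total, K), N_k)."""
        blocks = [self.u[k, :, : self.N_k[k]].T for k in range(self.n_states)]
        return np.concatenate(blocks, axis=0), self.N_k.copy()

    def own_state_series(self) -> list[np.ndarray]:
        """Per-state time series of each sample's own-state reduced potential."""
        return [self.u[k, k, : self.N_k[k]].copy() for k in range(self.n_states)]

    def subsample(self, indices_per_state: Sequence[np.ndarray]) -> "ReducedPotentialData":
        """Return a copy retaining only the given sample indices per state."""
        rows = [
            self.u[k, :, : self.N_k[k]].T[np.asarray(idx, dtype=np.intp)]
            for k, idx in enumerate(indices_per_state)
        ]
        return ReducedPotentialData.from_sample_lists(
            rows, temperature_K=self.temperature_K, state_labels=list(self.state_labels)
        )


@dataclass
class MbarSolution:
    """Converged MBAR free energies and diagnostics.

    ``f`` are dimensionless free energies with ``f[0] == 0``.
    """

    f: np.ndarray
    n_iterations: int
    residual: float
    overlap_warning: bool = False
    overlap_matrix: np.ndarray | None = None

    def delta_f(self, i: int, j: int) -> float:
        """Dimensionless free-energy difference f_j - f_i."""
        return float(self.f[j] - self.f[i])


@dataclass
class FreeEnergyEstimate:
    """A free-energy value in kcal/mol with bootstrap uncertainty.

    When ``bootstrap_samples`` is present, ``value`` is their mean and
    ``sd`` their sample standard deviation.
    """

    value: float
    sd: float
    bootstrap_samples: np.ndarray | None = None
    method: str = "mbar-bootstrap"
    seed: int | None = None
    n_boot: int | None = None
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.bootstrap_samples is not None:
            self.bootstrap_samples = np.asarray(self.bootstrap_samples, dtype=np.float64)


def _log_denominator(u_nl: np.ndarray, f: np.ndarray, log_N: np.ndarray) -> np.ndarray:
    # log sum_k N_k exp(f_k - u_nk), stabilized
    return logsumexp(log_N[None, :] + f[None, :] - u_nl, axis=1)


def _weights(u_nl: np.ndarray, f: np.ndarray, log_N: np.ndarray) -> np.ndarray:
    """W[n, i] = exp(f_i - u_ni) / sum_k N_k exp(f_k - u_nk)."""
    log_d = _log_denominator(u_nl, f, log_N)
    return np.exp(f[None, :] - u_nl - log_d[:, None])


def _solve_flat(
    u_nl: np.ndarray,
    N_k: np.ndarray,
    tolerance: float,
    max_iterations: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Core solver on a flat (N_total, K) matrix; returns (f, n_iter, residual)."""
    K = u_nl.shape[1]
    active = N_k > 0
    if active.sum() < 2:
        raise ValueError("at least two states need samples")
    with np.errstate(divide="ignore"):
        log_N = np.where(active, np.log(np.maximum(N_k, 1)), -np.inf)
    f = np.zeros(K) if f_init is None else np.array(f_init, dtype=np.float64)
    f -= f[0]

    Nk_f = N_k.astype(np.float64)
    newton_ok = bool(np.all(N_k > 0))
    residual = np.inf
    prev_step = np.inf
    for it in range(1, max_iterations + 1):
        log_d = _log_denominator(u_nl, f, log_N)
        # self-consistent iteration is globally convergent but only linear;
        # inside the basin an undamped Newton step on the convex objective
        # converges quadratically, so switch once the SCI residual is small
        use_newton = newton_ok and residual < 2.0
        if use_newton:
            W = np.exp(f[None, :] - u_nl - log_d[:, None])
            col = W.sum(axis=0)
            g = Nk_f * (col - 1.0)
            WN = W * Nk_f[None, :]
            H = np.diag(Nk_f * col) - WN.T @ WN
            try:
                step = np.zeros(K)
                step[1:] = np.linalg.solve(H[1:, 1:], -g[1:])
            except np.linalg.LinAlgError:
                step = None
            step_ok = (
                step is not None
                and np.all(np.isfinite(step))
                and np.max(np.abs(step)) < 2.0 * prev_step
            )
            if step_ok:
                residual = float(np.max(np.abs(step)))
                prev_step = residual
                f = f + step
                f -= f[0]
                if residual < tolerance:
                    return f, it, residual
                continue
        f_new = -logsumexp(-u_nl - log_d[:, None], axis=0)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tolerance:
            return f, it, residual
    raise ConvergenceError(
        f"MBAR did not converge in {max_iterations} iterations "
        f"(residual {residual:.3e})",
        residual=residual,
    )


def mbar_solve(
    data: ReducedPotentialData,
    tolerance: float = 1e-10,
    max_iterations: int = 10000,
    f_init: np.ndarray | None = None,
    compute_overlap: bool = True,
) -> MbarSolution:
    """Solve the MBAR self-consistency equations.

    Parameters
    ----------
    data : ReducedPotentialData
    tolerance : float
        Convergence threshold on max |Δf_k| between iterations.
    max_iterations : int
        Iteration budget; exceeding it raises :class:`ConvergenceError`.
    f_init : ndarray, optional
        Warm-start free energies.
    compute_overlap : bool
        Compute the state-overlap matrix and flag vanishing adjacent
        overlap on the solution.

    Returns
    -------
    MbarSolution
        Dimensionless free energies with ``f[0] = 0``; the result is
        independent of sample ordering.
    """
    u_nl, N_k = data.flat()
    f, n_iter, residual = _solve_flat(u_nl, N_k, tolerance, max_iterations, f_init)
    overlap_warning = False
    overlap = None
    if compute_overlap:
        with np.errstate(divide="ignore"):
            log_N = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
        W = _weights(u_nl, f, log_N)
        # O[i, j] = sum_n N_j W_ni W_nj; rows sum to 1 on the solution
        overlap = W.T @ (W * N_k[None, :].astype(np.float64))
        adjacent = np.diagonal(overlap, offset=1)
        overlap_warning = bool(np.any(adjacent < OVERLAP_WARNING_THRESHOLD))
    return MbarSolution(
        f=f,
        n_iterations=n_iter,
        residual=residual,
        overlap_warning=overlap_warning,
        overlap_matrix=overlap,
    )


def mbar_asymptotic_covariance(
    data: ReducedPotentialData, solution: MbarSolution
) -> np.ndarray:
    """Asymptotic covariance of the dimensionless free energies (diagnostic).

    Sandwich (robust M-estimator) covariance H^-1 B H^-1 of the MBAR
    solution, with H the analytic Hessian of the MBAR objective and B the
    empirical covariance of the per-sample score, both evaluated at the
    solution.  Row/column 0 are zero because f_0 is the reference.

    This is a diagnostic only: it assumes independent samples and tends
    to understate the uncertainty of correlated or repeated data, so
    reported errors always come from bootstrap and repeat pooling.
    """
    u_nl, N_k = data.flat()
    K = u_nl.shape[1]
    if np.any(N_k == 0):
        raise ValueError("asymptotic covariance requires samples in every state")
    with np.errstate(divide="ignore"):
        log_N = np.log(N_k)
    W = _weights(u_nl, solution.f, log_N)
    Nk_f = N_k.astype(np.float64)
    col = W.sum(axis=0)
    WN = W * Nk_f[None, :]
    H = np.diag(Nk_f * col) - WN.T @ WN
    score = WN - Nk_f[None, :] / u_nl.shape[0]  # per-sample gradient terms
    B = score.T @ score
    H_inv = np.linalg.pinv(H[1:, 1:])
    cov = np.zeros((K, K))
    cov[1:, 1:] = H_inv @ B[1:, 1:] @ H_inv
    return cov


def mbar_weights(data: ReducedPotentialData, solution: MbarSolution) -> np.ndarray:
    """Per-sample MBAR weights W[n, i] (each row sums to 1 over i when
    scaled by N_i; columns sum to 1 on the solution)."""
    u_nl, N_k = data.flat()
    with np.errstate(divide="ignore"):
        log_N = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    return _weights(u_nl, solution.f, log_N)


def _state_rngs(seed: int | None, n_states: int) -> list[np.random.Generator]:
    # one derived stream per sampling state, fixed offset from the base seed
    base = 0 if seed is None else int(seed)
    return [np.random.default_rng([base, k]) for k in range(n_states)]


def bootstrap_free_energies(
    data: ReducedPotentialData,
    endpoint_pairs: Sequence[tuple[int, int]],
    n_boot: int = 200,
    seed: int | None = None,
    tolerance: float = 1e-10,
    max_iterations: int = 10000,
) -> list[FreeEnergyEstimate]:
    """Bootstrap MBAR free-energy differences for several endpoint pairs at once.

    Replicate 0 is computed on the unresampled data; the remaining
    replicates resample samples within each state independently with
    replacement, preserving the per-state counts.  All pairs share the
    same replicate MBAR solutions, so their uncertainties are mutually
    consistent.  Values are converted to kcal/mol with kT at the data
    temperature.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    K = data.n_states
    for i, j in endpoint_pairs:
        if not (0 <= i < K and 0 <= j < K):
            raise ValueError(f"endpoint pair ({i}, {j}) outside 0..{K - 1}")
    kT = data.kT
    u_nl, N_k = data.flat()
    offsets = np.concatenate([[0], np.cumsum(N_k)])
    rngs = _state_rngs(seed, K)

    sol0 = mbar_solve(data, tolerance=tolerance, max_iterations=max_iterations)
    f_warm = sol0.f
    replicates = np.empty((n_boot, len(endpoint_pairs)), dtype=np.float64)
    for b in range(n_boot):
        if b == 0:
            f = sol0.f
        else:
            rows = np.empty_like(u_nl)
            for k in range(K):
                n_k = int(N_k[k])
                if n_k == 0:
                    continue
                pick = rngs[k].integers(0, n_k, size=n_k)
                sl = slice(offsets[k], offsets[k + 1])
                rows[sl] = u_nl[sl][pick]
            f, _, _ = _solve_flat(
                rows, N_k, tolerance, max_iterations, f_init=f_warm
            )
        for p, (i, j) in enumerate(endpoint_pairs):
            replicates[b, p] = kT * (f[j] - f[i])

    out = []
    for p in range(len(endpoint_pairs)):
        samples = replicates[:, p]
        out.append(
            FreeEnergyEstimate(
                value=float(samples.mean()),
                sd=float(samples.std(ddof=1)),
                bootstrap_samples=samples,
                method="mbar-bootstrap",
                seed=seed,
                n_boot=n_boot,
                overlap_warning=sol0.overlap_warning,
            )
        )
    return out


def bootstrap_free_energy(
    data: ReducedPotentialData,
    endpoints: tuple[int, int] = (0, -1),
    n_boot: int = 200,
    seed: int | None = None,
    tolerance: float = 1e-10,
    max_iterations: int = 10000,
) -> FreeEnergyEstimate:
    """Bootstrap the free-energy difference between two states, in kcal/mol.

    ``endpoints`` are state indices (i, j); the reported value is the mean
    of the replicate estimates of kT (f_j - f_i) and the uncertainty their
    sample standard deviation.
    """
    i, j = endpoints
    K = data.n_states
    i %= K
    j %= K
    return bootstrap_free_energies(
        data,
        [(i, j)],
        n_boot=n_boot,
        seed=seed,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )[0]


def combine_repeats(estimates: Sequence[FreeEnergyEstimate]) -> FreeEnergyEstimate:
    """Pool bootstrap samples of repeated calculations into one estimate.

    The pooled sample set is the concatenation of the inputs' bootstrap
    samples (e.g. three repeats of 200 replicates give 600); the returned
    value and sd are the mean and sample standard deviation of the pool,
    so the uncertainty reflects both estimator noise and repeat-to-repeat
    spread.
    """
    if len(estimates) == 0:
        raise ValueError("at least one estimate is required")
    pools = []
    for est in estimates:
        if est.bootstrap_samples is None:
            raise ValueError("every estimate must carry bootstrap samples")
        pools.append(np.asarray(est.bootstrap_samples, dtype=np.float64))
    pool = np.concatenate(pools)
    sd = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    return FreeEnergyEstimate(
        value=float(pool.mean()),
        sd=sd,
        bootstrap_samples=pool,
        method="pooled-repeats",
        n_boot=pool.size,
        overlap_warning=any(e.overlap_warning for e in estimates),
    )
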