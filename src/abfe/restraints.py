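"""Boresch orientational restraints and their analytic free-energy cost.

A Boresch restraint fixes the position and orientation of a ligand relative
to three receptor anchor points (c, b, a) and three ligand anchor points
(A, B, C) through six harmonic terms: one distance r = |a-A|, two angles
thetaA = angle(b, a, A) and thetaB = angle(a, A, B), and three dihedrals
phiA = (c, b, a, A), phiB = (b, a, A, B), phiC = (a, A, B, C).

In the stiff-spring regime the free energy of imposing the restraint on a
non-interacting ligand at standard concentration has the closed form

    dG = kT * ln[ 8 pi^2 V0 * sqrt(K_r K_tA K_tB K_pA K_pB K_pC)
                  / (r0^2 sin(tA0) sin(tB0) (2 pi kT)^3) ]

which this module implements together with a 6-D quadrature of the
restrained configurational integral used as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .thermo import ThermoState

__all__ = [
    "BoreschRestraint",
    "restraint_energy",
    "internal_coordinates",
    "boresch_analytic_dG",
    "boresch_quadrature_dG",
]

DEG2RAD = math.pi / 180.0
#: (180/pi)^2 — converts kcal/mol/deg^2 force constants to kcal/mol/rad^2.
DEG_TO_RAD_FORCE = (180.0 / math.pi) ** 2

_SIN_FLOOR = 1e-6  # rad from 0 or pi at which the analytic term is singular


@dataclass(frozen=True)
class BoreschRestraint:
    """Six-degree-of-freedom harmonic restraint.

    Reference values are in Å and degrees; force constants are stored in
    kcal/mol/Å^2 (distance) and kcal/mol/rad^2 (angles and dihedrals).
    Use :meth:`from_config` to build from force constants declared per
    deg^2.
    """

    r0: float
    theta_A0: float
    theta_B0: float
    phi_A0: float
    phi_B0: float
    phi_C0: float
    k_r: float = 10.0
    k_theta_A: float = 10.0
    k_theta_B: float = 10.0
    k_phi_A: float = 10.0
    k_phi_B: float = 10.0
    k_phi_C: float = 10.0
    host_anchors: tuple[str, str, str] = ("c", "b", "a")
    guest_anchors: tuple[str, str, str] = ("A", "B", "C")

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"reference distance must be positive, got {self.r0}")
        if not 0.0 < self.theta_A0 < 180.0 or not 0.0 < self.theta_B0 < 180.0:
            raise ValueError("reference angles must lie strictly between 0 and 180 deg")
        for name in ("k_r", "k_theta_A", "k_theta_B", "k_phi_A", "k_phi_B", "k_phi_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"force constant {name} must be positive")

    @property
    def angular_force_constants(self) -> tuple[float, float, float, float, float]:
        return (self.k_theta_A, self.k_theta_B, self.k_phi_A, self.k_phi_B, self.k_phi_C)

    @classmethod
    def from_config(cls, block: dict) -> "BoreschRestraint":
        """Build from a configuration mapping.

        ``angular_units`` must be ``"rad^-2"`` (default) or ``"deg^-2"``;
        in the latter case angular force constants are multiplied by
        (180/pi)^2 to the canonical rad^-2.
        """
        block = dict(block)
        units = block.pop("angular_units", "rad^-2")
        if units not in ("rad^-2", "deg^-2"):
            raise ValueError(f"unknown angular_units {units!r}")
        factor = DEG_TO_RAD_FORCE if units == "deg^-2" else 1.0
        kwargs = {}
        for key in ("r0", "theta_A0", "theta_B0", "phi_A0", "phi_B0", "phi_C0", "k_r"):
            if key in block:
                kwargs[key] = float(block.pop(key))
        for key in ("k_theta_A", "k_theta_B", "k_phi_A", "k_phi_B", "k_phi_C"):
            if key in block:
                kwargs[key] = float(block.pop(key)) * factor
        for key in ("host_anchors", "guest_anchors"):
            if key in block:
                kwargs[key] = tuple(block.pop(key))
        if block:
            raise ValueError(f"unknown restraint keys: {sorted(block)}")
        return cls(**kwargs)

    def scale_force_constants(self, factor: float) -> "BoreschRestraint":
        return replace(
            self,
            k_r=self.k_r * factor,
            k_theta_A=self.k_theta_A * factor,
            k_theta_B=self.k_theta_B * factor,
            k_phi_A=self.k_phi_A * factor,
            k_phi_B=self.k_phi_B * factor,
            k_phi_C=self.k_phi_C * factor,
        )


def _wrap_degrees(delta: np.ndarray) -> np.ndarray:
    """Map dihedral deviations in degrees to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(delta, dtype=np.float64), 360.0)


def restraint_energy(
    coordinates: Sequence[float] | np.ndarray, restraint: BoreschRestraint
) -> float | np.ndarray:
    """Harmonic restraint energy in kcal/mol.

    Parameters
    ----------
    coordinates : array-like, shape (..., 6)
        Internal coordinates (r, thetaA, thetaB, phiA, phiB, phiC); the
        distance in Å, all angles in degrees.  Dihedral deviations are
        wrapped to (-180, 180] before squaring.
    restraint : BoreschRestraint

    Returns
    -------
    float or ndarray
        Zero at the reference geometry; 0.5 * sum K * deviation^2 otherwise.
    """
    c = np.asarray(coordinates, dtype=np.float64)
    if c.shape[-1] != 6:
        raise ValueError("coordinates must supply (r, thetaA, thetaB, phiA, phiB, phiC)")
    r = c[..., 0]
    if np.any(r <= 0):
        raise ValueError("distance r must be positive")
    dr = r - restraint.r0
    dtA = (c[..., 1] - restraint.theta_A0) * DEG2RAD
    dtB = (c[..., 2] - restraint.theta_B0) * DEG2RAD
    dpA = _wrap_degrees(c[..., 3] - restraint.phi_A0) * DEG2RAD
    dpB = _wrap_degrees(c[..., 4] - restraint.phi_B0) * DEG2RAD
    dpC = _wrap_degrees(c[..., 5] - restraint.phi_C0) * DEG2RAD
    e = 0.5 * (
        restraint.k_r * dr**2
        + restraint.k_theta_A * dtA**2
        + restraint.k_theta_B * dtB**2
        + restraint.k_phi_A * dpA**2
        + restraint.k_phi_B * dpB**2
        + restraint.k_phi_C * dpC**2
    )
    return e if e.ndim else float(e)


def _norm(v: np.ndarray) -> np.ndarray:
    return np.linalg.norm(v, axis=-1)


def _angle_deg(p: np.ndarray, q: np.ndarray, s: np.ndarray) -> np.ndarray:
    u = p - q
    w = s - q
    cosang = np.sum(u * w, axis=-1) / (_norm(u) * _norm(w))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral_deg(p0, p1, p2, p3) -> np.ndarray:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / _norm(b1)[..., None])
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def internal_coordinates(
    host_points: np.ndarray, guest_points: np.ndarray
) -> np.ndarray:
    """Boresch internal coordinates from anchor positions.

    Parameters
    ----------
    host_points : ndarray, shape (..., 3, 3)
        Rows (c, b, a) with ``a`` the anchor bonded to the restraint axis.
    guest_points : ndarray, shape (..., 3, 3)
        Rows (A, B, C) with ``A`` the primary guest anchor.

    Returns
    -------
    ndarray, shape (..., 6)
        (r, thetaA, thetaB, phiA, phiB, phiC) in Å and degrees.
    """
    h = np.asarray(host_points, dtype=np.float64)
    g = np.asarray(guest_points, dtype=np.float64)
    c, b, a = h[..., 0, :], h[..., 1, :], h[..., 2, :]
    A, B, C = g[..., 0, :], g[..., 1, :], g[..., 2, :]
    r = _norm(A - a)
    theta_A = _angle_deg(b, a, A)
    theta_B = _angle_deg(a, A, B)
    phi_A = _dihedral_deg(c, b, a, A)
    phi_B = _dihedral_deg(b, a, A, B)
    phi_C = _dihedral_deg(a, A, B, C)
    return np.stack([r, theta_A, theta_B, phi_A, phi_B, phi_C], axis=-1)


def _check_angular_singularity(restraint: BoreschRestraint) -> None:
    for theta0 in (restraint.theta_A0, restraint.theta_B0):
        t = theta0 * DEG2RAD
        if min(t, math.pi - t) < _SIN_FLOOR:
            raise ValueError(
                f"reference angle {theta0} deg is within {_SIN_FLOOR} rad of a pole; "
                "the analytic restraint term is singular"
            )


def boresch_analytic_dG(
    restraint: BoreschRestraint, thermo: ThermoState | None = None
) -> float:
    """Analytic stiff-spring free energy of restraining a non-interacting
    ligand at standard concentration, in kcal/mol.

    This is the solvent-side restraining step of the alchemical cycle: the
    positive cost of confining an ideal (decoupled) ligand from the
    standard-state volume into the six-dimensional harmonic well.
    """
    thermo = thermo or ThermoState()
    _check_angular_singularity(restraint)
    kT = thermo.kT
    prod_k = (
        restraint.k_r
        * restraint.k_theta_A
        * restraint.k_theta_B
        * restraint.k_phi_A
        * restraint.k_phi_B
        * restraint.k_phi_C
    )
    tA = restraint.theta_A0 * DEG2RAD
    tB = restraint.theta_B0 * DEG2RAD
    arg = (
        8.0
        * math.pi**2
        * thermo.standard_volume_A3
        * math.sqrt(prod_k)
        / (restraint.r0**2 * math.sin(tA) * math.sin(tB) * (2.0 * math.pi * kT) ** 3)
    )
    return kT * math.log(arg)


def boresch_quadrature_dG(
    restraint: BoreschRestraint, thermo: ThermoState | None = None
) -> float:
    """Restraining free energy by 6-D quadrature of the configurational
    integral, in kcal/mol.

    The restrained partition function factorizes over the six internal
    coordinates with Jacobian r^2 sin(thetaA) sin(thetaB); each factor is
    integrated numerically over its full domain, without the stiff-spring
    approximation.  Serves as the independent oracle for
    :func:`boresch_analytic_dG`.
    """
    thermo = thermo or ThermoState()
    _check_angular_singularity(restraint)
    kT = thermo.kT
    beta = 1.0 / kT

    def z_r() -> float:
        k = restraint.k_r
        r0 = restraint.r0
        val, _ = quad(
            lambda r: r * r * math.exp(-0.5 * beta * k * (r - r0) ** 2),
            0.0,
            r0 + 12.0 * math.sqrt(kT / k),
            limit=200,
        )
        return val

    def z_theta(theta0_deg: float, k: float) -> float:
        t0 = theta0_deg * DEG2RAD
        val, _ = quad(
            lambda t: math.sin(t) * math.exp(-0.5 * beta * k * (t - t0) ** 2),
            0.0,
            math.pi,
            limit=200,
        )
        return val

    def z_phi(k: float) -> float:
        # deviation wrapped to (-pi, pi]; integrate over one period
        val, _ = quad(
            lambda d: math.exp(-0.5 * beta * k * d * d),
            -math.pi,
            math.pi,
            limit=200,
        )
        return val

    z = (
        z_r()
        * z_theta(restraint.theta_A0, restraint.k_theta_A)
        * z_theta(restraint.theta_B0, restraint.k_theta_B)
        * z_phi(restraint.k_phi_A)
        * z_phi(restraint.k_phi_B)
        * z_phi(restraint.k_phi_C)
    )
    return -kT * math.log(z / (8.0 * math.pi**2 * thermo.standard_volume_A3))
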