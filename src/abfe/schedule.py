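"""Alchemical lambda schedules for the binding thermodynamic cycle.

Each state is a triple (lambda_restraint, lambda_coulomb, lambda_vdw) of
coupling parameters in [0, 1], 1 meaning fully on.  The complex environment
chains three legs — restraint switched on at full coupling, then charges
annihilated, then van der Waals decoupled — while the solvent environment
has only the two decoupling legs and no restraint.  Consecutive legs share
a boundary state that is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LambdaState", "LambdaSchedule", "build_lambda_schedule", "DEFAULT_RESTRAINT_LAMBDAS"]

#: Non-uniform schedule used for switching the restraint on in the complex.
DEFAULT_RESTRAINT_LAMBDAS: tuple[float, ...] = (
    0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.3, 0.5, 0.75, 1.0,
)


@dataclass(frozen=True)
class LambdaState:
    """One alchemical window: coupling values for restraint, coulomb, vdW."""

    lam_restraint: float
    lam_coulomb: float
    lam_vdw: float

    def __post_init__(self) -> None:
        for name in ("lam_restraint", "lam_coulomb", "lam_vdw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lam_restraint, self.lam_coulomb, self.lam_vdw)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered list of lambda states for one environment.

    ``leg_boundaries`` maps leg names to (first, last) state indices; legs
    share their boundary state, which is stored once.
    """

    environment: str
    states: tuple[LambdaState, ...]
    leg_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.environment not in ("complex", "solvent"):
            raise ValueError(f"environment must be 'complex' or 'solvent', got {self.environment!r}")
        if len(self.states) < 2:
            raise ValueError("a schedule needs at least 2 states")
        if self.environment == "solvent" and any(
            s.lam_restraint != 0.0 for s in self.states
        ):
            raise ValueError("solvent schedules must have lambda_restraint == 0 throughout")

    def __len__(self) -> int:
        return len(self.states)

    def as_array(self) -> np.ndarray:
        """States as an (n_states, 3) array of (restraint, coulomb, vdw)."""
        return np.array([s.as_tuple() for s in self.states], dtype=np.float64)


def _spacing_steps(dlam: float, label: str) -> int:
    if dlam <= 0 or dlam > 1:
        raise ValueError(f"{label} spacing must lie in (0, 1], got {dlam}")
    n = round(1.0 / dlam)
    if abs(n * dlam - 1.0) > 1e-9:
        raise ValueError(f"{label} spacing {dlam} does not evenly divide 1")
    return n


def _validated_restraint_lambdas(values: Sequence[float]) -> list[float]:
    lams = sorted(float(v) for v in values)
    if len(lams) < 2:
        raise ValueError("restraint lambda list needs at least 2 values")
    if lams[0] != 0.0 or lams[-1] != 1.0:
        raise ValueError("restraint lambda list must start at 0 and end at 1")
    if any(not 0.0 <= v <= 1.0 for v in lams):
        raise ValueError("restraint lambdas must lie in [0, 1]")
    if len(set(lams)) != len(lams):
        raise ValueError("restraint lambdas must be distinct")
    return lams


def build_lambda_schedule(
    environment: str,
    dlam_coul: float = 0.1,
    dlam_vdw: float = 0.05,
    restraint_lambdas: Sequence[float] = DEFAULT_RESTRAINT_LAMBDAS,
) -> LambdaSchedule:
    """Build the lambda schedule for one environment of the cycle.

    The state order follows the direction actually simulated: from the
    fully coupled physical endpoint towards the decoupled one.  For the
    complex the restraint is first switched on at full coupling, then the
    charges are annihilated, then the van der Waals interactions are
    decoupled through the soft core; the solvent has only the two
    decoupling legs.  With the default spacings (coulomb 0.1, vdW 0.05)
    and the default 12-value restraint list this yields 42 complex and 31
    solvent windows.

    Returns
    -------
    LambdaSchedule
    """
    n_coul = _spacing_steps(dlam_coul, "coulomb")
    n_vdw = _spacing_steps(dlam_vdw, "vdW")
    coul_values = [1.0 - i / n_coul for i in range(n_coul + 1)]
    vdw_values = [1.0 - i / n_vdw for i in range(n_vdw + 1)]

    states: list[LambdaState] = []
    boundaries: dict[str, tuple[int, int]] = {}
    if environment == "complex":
        lams = _validated_restraint_lambdas(restraint_lambdas)
        states.extend(LambdaState(v, 1.0, 1.0) for v in lams)
        boundaries["restraint_on"] = (0, len(states) - 1)
        start = len(states) - 1
        states.extend(LambdaState(1.0, c, 1.0) for c in coul_values[1:])
        boundaries["coulomb_off"] = (start, len(states) - 1)
        start = len(states) - 1
        states.extend(LambdaState(1.0, 0.0, v) for v in vdw_values[1:])
        boundaries["vdw_off"] = (start, len(states) - 1)
    elif environment == "solvent":
        states.extend(LambdaState(0.0, c, 1.0) for c in coul_values)
        boundaries["coulomb_off"] = (0, len(states) - 1)
        start = len(states) - 1
        states.extend(LambdaState(0.0, 0.0, v) for v in vdw_values[1:])
        boundaries["vdw_off"] = (start, len(states) - 1)
    else:
        raise ValueError(f"environment must be 'complex' or 'solvent', got {environment!r}")

    return LambdaSchedule(
        environment=environment, states=tuple(states), leg_boundaries=boundaries
    )
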