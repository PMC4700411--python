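"""Assembly of the binding free energy from the legs of the alchemical cycle.

The standard binding free energy is the signed sum of four legs — solvent
decoupling, analytic solvent-side restraining, complex-side recoupling and
complex-side restraint release — plus any additive corrections (e.g. the
finite-size charge correction applied from externally computed residual
integrated potentials).  Leg uncertainties combine as the root sum square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .mbar import FreeEnergyEstimate
from .thermo import ThermoState

__all__ = [
    "ChargeCorrection",
    "CycleResult",
    "IncompleteCycleError",
    "apply_charge_correction",
    "assemble_cycle",
    "combine_binding_modes",
]

LEG_NAMES = ("dG_solv_elec_vdw", "dG_solv_restr", "dG_prot_elec_vdw", "dG_prot_restr")


class IncompleteCycleError(ValueError):
    """A leg required to close the thermodynamic cycle is missing."""


@dataclass(frozen=True)
class ChargeCorrection:
    """Finite-size electrostatics correction from per-frame residual
    integrated potential (RIP) values, in kcal/mol.

    Only the mean enters the cycle; a warning flag is raised when the
    frame-to-frame standard deviation reaches ``warn_threshold``.
    """

    per_frame_values: tuple[float, ...]
    mean: float
    sd: float
    warn_threshold: float = 0.05

    @property
    def warning(self) -> bool:
        return self.sd >= self.warn_threshold


def apply_charge_correction(
    per_frame_values: Sequence[float], warn_threshold: float = 0.05
) -> ChargeCorrection:
    """Summarize per-frame RIP values into the additive cycle correction."""
    values = np.asarray(per_frame_values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("at least one per-frame value is required")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ChargeCorrection(
        per_frame_values=tuple(float(v) for v in values),
        mean=float(values.mean()),
        sd=sd,
        warn_threshold=warn_threshold,
    )


def _as_estimate(value: FreeEnergyEstimate | float) -> FreeEnergyEstimate:
    if isinstance(value, FreeEnergyEstimate):
        return value
    return FreeEnergyEstimate(value=float(value), sd=0.0, method="analytic")


@dataclass
class CycleResult:
    """Per-leg free energies and the assembled standard binding free energy.

    All values are in kcal/mol.  ``dG_bind_standard`` equals the signed sum
    of the four legs plus the corrections; its ``sd`` is the root sum
    square of the leg uncertainties.
    """

    dG_solv_elec_vdw: FreeEnergyEstimate
    dG_solv_restr: FreeEnergyEstimate
    dG_prot_elec_vdw: FreeEnergyEstimate
    dG_prot_restr: FreeEnergyEstimate
    corrections: dict[str, float] = field(default_factory=dict)
    dG_bind_standard: float = 0.0
    sd: float = 0.0
    thermo: ThermoState = field(default_factory=ThermoState)

    def legs(self) -> dict[str, FreeEnergyEstimate]:
        return {name: getattr(self, name) for name in LEG_NAMES}

    def to_dict(self) -> dict:
        out = {
            "dG_bind_standard_kcal_mol": self.dG_bind_standard,
            "sd_kcal_mol": self.sd,
            "temperature_K": self.thermo.temperature_K,
            "corrections_kcal_mol": dict(self.corrections),
            "legs": {
                name: {"value_kcal_mol": est.value, "sd_kcal_mol": est.sd}
                for name, est in self.legs().items()
            },
        }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def summary_table(self) -> str:
        lines = [f"{'leg':<22}{'dG (kcal/mol)':>14}{'sd':>8}"]
        for name, est in self.legs().items():
            lines.append(f"{name:<22}{est.value:>14.3f}{est.sd:>8.3f}")
        for name, value in self.corrections.items():
            lines.append(f"{name:<22}{value:>14.3f}{'':>8}")
        lines.append(
            f"{'dG_bind_standard':<22}{self.dG_bind_standard:>14.3f}{self.sd:>8.3f}"
        )
        return "\n".join(lines)


def assemble_cycle(
    legs: Mapping[str, FreeEnergyEstimate | float],
    corrections: Mapping[str, float] | None = None,
    thermo: ThermoState | None = None,
) -> CycleResult:
    """Close the thermodynamic cycle from its four legs.

    Parameters
    ----------
    legs : mapping
        Must contain ``dG_solv_elec_vdw``, ``dG_solv_restr``,
        ``dG_prot_elec_vdw`` and ``dG_prot_restr``, each a
        :class:`FreeEnergyEstimate` or a plain float (analytic legs), all
        expressed in the cycle direction (solvent decoupling, solvent
        restraining, complex recoupling, complex restraint release).
    corrections : mapping, optional
        Named additive terms in kcal/mol (charge correction, long-range
        dispersion, ...), added as-is with no uncertainty contribution.

    Returns
    -------
    CycleResult
    """
    thermo = thermo or ThermoState()
    missing = [name for name in LEG_NAMES if name not in legs]
    if missing:
        raise IncompleteCycleError(f"missing cycle legs: {missing}")
    estimates = {name: _as_estimate(legs[name]) for name in LEG_NAMES}
    corr = {str(k): float(v) for k, v in (corrections or {}).items()}
    total = sum(est.value for est in estimates.values()) + sum(corr.values())
    sd = float(np.sqrt(sum(est.sd**2 for est in estimates.values())))
    return CycleResult(
        **estimates,
        corrections=corr,
        dG_bind_standard=float(total),
        sd=sd,
        thermo=thermo,
    )


def combine_binding_modes(
    mode_estimates: Sequence[FreeEnergyEstimate | float],
    thermo: ThermoState | None = None,
    n_resamples: int = 10000,
    seed: int | None = None,
) -> FreeEnergyEstimate:
    """Combine per-binding-mode free energies into one value.

    The combined binding free energy is the Boltzmann sum

        dG_comb = -kT * ln( sum_i exp(-dG_i / kT) )

    evaluated with log-sum-exp stabilization; it never exceeds the lowest
    mode and approaches it as the gaps to the other modes grow.  When the
    modes carry bootstrap samples, the uncertainty is propagated by
    drawing one bootstrap value per mode (paired, with replacement) and
    recombining, ``n_resamples`` times.
    """
    if len(mode_estimates) == 0:
        raise ValueError("at least one binding mode is required")
    thermo = thermo or ThermoState()
    kT = thermo.kT
    estimates = [_as_estimate(m) for m in mode_estimates]
    values = np.array([e.value for e in estimates], dtype=np.float64)
    combined = float(-kT * logsumexp(-values / kT))

    pools = [e.bootstrap_samples for e in estimates]
    if all(p is not None and len(p) > 0 for p in pools):
        rng = np.random.default_rng(seed)
        draws = np.column_stack(
            [np.asarray(p)[rng.integers(0, len(p), size=n_resamples)] for p in pools]
        )
        resampled = -kT * logsumexp(-draws / kT, axis=1)
        sd = float(resampled.std(ddof=1))
    else:
        sd = 0.0
    return FreeEnergyEstimate(
        value=combined, sd=sd, method="multimode-boltzmann", seed=seed
    )
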