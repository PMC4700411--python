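"""Thermodynamic reference state and physical constants.

All public energies in this package are in kcal/mol; reduced (dimensionless)
potentials appear only inside the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL_MOL_K = 0.0019872041

#: Coulomb constant in kcal Å / (mol e^2).
COULOMB_CONSTANT = 332.06

#: Volume per molecule at 1 mol/L standard concentration, in Å^3.
STANDARD_VOLUME_A3 = 1660.539


@dataclass(frozen=True)
class ThermoState:
    """Temperature and standard-state volume defining the reference state.

    Parameters
    ----------
    temperature_K : float
        Absolute temperature in kelvin.
    standard_volume_A3 : float
        Volume per molecule defining the standard concentration
        (1660.539 Å^3 corresponds to 1 mol/L).
    """

    temperature_K: float = 298.15
    standard_volume_A3: float = STANDARD_VOLUME_A3

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_K}")
        if self.standard_volume_A3 <= 0:
            raise ValueError(
                f"standard-state volume must be positive, got {self.standard_volume_A3}"
            )

    @property
    def kT(self) -> float:
        """Thermal energy kT in kcal/mol."""
        return BOLTZMANN_KCAL_MOL_K * self.temperature_K
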