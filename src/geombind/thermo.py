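"""Thermodynamic state and the package-wide unit system.

Units are fixed to Å, ps, amu and kcal/mol throughout.  With these units a
force of 1 kcal/(mol·Å) accelerates 1 amu by ``KCAL_PER_MOL_ACCEL`` Å/ps².
Angles are degrees in every public interface (matching the conventional
kcal/(mol·degree²) force constants) and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

# 1 kcal/mol expressed in amu·Å²/ps²
KCAL_PER_MOL_ACCEL = 418.4

# Standard-state volume: one molecule per V° corresponds to the 1 M
# reference concentration C° = 1/1661 Å⁻³.
STANDARD_VOLUME_A3 = 1661.0

DEG_PER_RAD = 57.29577951308232


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature β = 1/(k_B T).

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin; must be positive.
    """

    temperature: float = 300.0
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        object.__setattr__(self, "beta", 1.0 / (KB * self.temperature))

    @property
    def kt(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return KB * self.temperature
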