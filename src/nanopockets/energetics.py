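"""Free-energy differences from binding-constant ratios.

For two association constants measured at the same temperature, the
difference in binding free energy is ΔΔG = R·T·ln(K_high / K_low); with
K in M⁻¹ and T in kelvin the result is returned in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

#: Molar gas constant, J/(mol K) (CODATA).
R_GAS = 8.314462618


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class BindingConstant:
    """Association constant (M⁻¹) at a given temperature (K)."""

    value: float
    temperature: float = 298.15

    def __post_init__(self):
        if self.value <= 0:
            raise EnergeticsError(f"binding constant must be > 0, got {self.value}")
        if self.temperature <= 0:
            raise EnergeticsError(f"temperature must be > 0, got {self.temperature}")


def delta_g_from_ratio(k_high: float, k_low: float,
                       temperature: float = 298.15) -> float:
    """R·T·ln(k_high / k_low) in kJ/mol (negative when k_high < k_low)."""
    if k_high <= 0 or k_low <= 0:
        raise EnergeticsError("binding constants must be > 0")
    if temperature <= 0:
        raise EnergeticsError(f"temperature must be > 0, got {temperature}")
    return R_GAS * temperature * log(k_high / k_low) / 1000.0
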