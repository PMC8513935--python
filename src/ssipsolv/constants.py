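"""Physical constants and model-wide settings.

All free energies in this package are in kJ mol^-1, concentrations in
mol L^-1 and temperatures in K.  The surface-site interaction model is
parameterised at 298 K; the temperature is user-overridable but none of
the shipped empirical parameters are temperature dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

GAS_CONSTANT = 8.3145
"""Molar gas constant R, J mol^-1 K^-1."""

STANDARD_TEMPERATURE = 298.15
"""Default temperature, K."""

REFERENCE_SS_ENTROPY = 6.0
"""RT ln[S.S] for a typical non-polar solvent, kJ mol^-1.

This is the constant that appears in the solvent-competition expression
for 1:1 H-bond complexation, originally calibrated in carbon
tetrachloride where the effective solvent-solvent interaction
concentration [S.S] is about 10 M.
"""

TARGET_SSIP_CONCENTRATION = 220.0
"""Benchmark total SSIP concentration of a pure liquid, mol L^-1.

Anchored on liquid water: 4 interaction points per molecule at 55 M.
Used as an advisory check on how many interaction points a molecule
should carry.
"""


@dataclass(frozen=True)
class ModelConstants:
    """Bundle of the model's global constants.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K (default 298.15).
    gas_constant : float
        R in J mol^-1 K^-1.
    reference_ss_entropy : float
        RT ln[S.S] for the non-polar reference, kJ mol^-1 (default 6.0).
    target_ssip_concentration : float
        Benchmark liquid-phase SSIP concentration, mol L^-1 (default 220).
    """

    temperature: float = STANDARD_TEMPERATURE
    gas_constant: float = GAS_CONSTANT
    reference_ss_entropy: float = REFERENCE_SS_ENTROPY
    target_ssip_concentration: float = TARGET_SSIP_CONCENTRATION

    @property
    def rt(self) -> float:
        """RT in kJ mol^-1 (2.479 at 298.15 K)."""
        return self.gas_constant * self.temperature / 1000.0

    def rt_ln(self, concentration: float) -> float:
        """RT ln(c) in kJ mol^-1 for a concentration in mol L^-1."""
        if concentration <= 0:
            raise ValueError(f"concentration must be positive, got {concentration}")
        return self.rt * math.log(concentration)


DEFAULT_CONSTANTS = ModelConstants()
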