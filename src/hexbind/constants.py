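"""Physical constants shared across the package.

Units: energies in kcal/mol, distances in Å, concentrations in mol/L
unless a function states otherwise.
"""

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.98720e-3

#: Default absolute temperature (K) for free-energy <-> K_d conversions.
DEFAULT_TEMPERATURE = 300.0

#: Volume per molecule at a 1 M standard state, in Å^3
#: (1 L / N_A = 1e27 Å^3 / 6.02214e23).
V0_STANDARD_STATE = 1660.539


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
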