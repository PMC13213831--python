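"""Physical constants and unit conventions.

All free energies and works inside the package are in kcal/mol. Engine
output (xvg traces) defaults to kJ/mol and is converted once, at
integration time.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Conversion factor, kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Default temperature (K) for the benchmark systems.
DEFAULT_TEMPERATURE = 298.15


def kT(temperature: float) -> float:
    """Thermal energy RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
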