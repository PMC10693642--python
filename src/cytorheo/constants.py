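"""Physical constants and unit helpers.

The package works in micrometres, seconds and pascals throughout.  Thermal
energy is therefore carried in Pa*um^3 (1 J = 1e18 Pa*um^3), which makes the
Stokes-Einstein expressions dimensionally closed in (um, s, Pa).
"""

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23

#: default experiment temperature, K (room temperature; configurable everywhere)
DEFAULT_TEMPERATURE_K = 294.0

#: canonical F-actin mass per length, G-actin subunits per micrometre of filament
ACTIN_SUBUNITS_PER_UM = 370.0


def thermal_energy(temperature_k: float) -> float:
    """kB*T in Pa*um^3 for use with lengths in um and moduli in Pa."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return BOLTZMANN_J_PER_K * temperature_k * 1e18
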