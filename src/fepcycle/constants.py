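"""Physical constants and default conditions shared across the package.

All energies in this package are kcal/mol; temperatures are Kelvin.
"""

#: Boltzmann constant times Avogadro's number, kcal/(mol K).
KB_KCAL_MOL_K: float = 1.987204259e-3

#: Default simulation temperature (K). Matches the Langevin-thermostat
#: temperature used for the molecular-dynamics style protocols this package's
#: toy sampler emulates.
DEFAULT_T_SIM: float = 303.15

#: Default temperature for binding/protonation thermodynamics (K), i.e. 25 C,
#: the calorimetry temperature.
DEFAULT_T_BINDING: float = 298.15


def beta(T: float) -> float:
    """Return 1/(kB T) in mol/kcal for temperature ``T`` in Kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return 1.0 / (KB_KCAL_MOL_K * T)
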