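"""Physical constants and element tables shared across the toolkit.

All energies are kcal/mol, all lengths Angstrom, temperatures Kelvin.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL: float = 1.9872e-3

#: Coulomb conversion factor, kcal Angstrom mol^-1 e^-2.
COULOMB_KCAL: float = 332.0637

#: Default temperature (K) for Boltzmann inversion and work averaging.
DEFAULT_TEMPERATURE: float = 300.0

#: Van der Waals radii (Angstrom) for the elements that occur in protein and
#: cofactor structures.  Values follow the Bondi compilation commonly used by
#: surface-area and pore-profiling codes.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "MG": 1.73,
    "ZN": 1.39,
    "FE": 1.52,
}

#: Radius assigned to elements missing from :data:`VDW_RADII`.
DEFAULT_VDW_RADIUS: float = 1.70


def beta(temperature: float) -> float:
    """Return 1/(kB*T) in mol/kcal for a temperature in Kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL * temperature)
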