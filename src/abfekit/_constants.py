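"""Physical constants and unit conversions used throughout the package.

Internal conventions: energies in kcal/mol, distances in Angstrom, angles in
radians, times in ps, temperatures in K, concentrations in molar.
"""

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA, as used by GROMACS/pymbar).
KB_KCAL = 0.0019872041

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Standard-state volume in Angstrom^3 corresponding to c = 1 M
#: (1 / (N_A * 1 mol/L) expressed in A^3 per molecule).
V_STANDARD = 1660.54

#: Default simulation/analysis temperature in K.
DEFAULT_TEMPERATURE = 298.15


def kt_kcal(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at *temperature* (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature


def kj_to_kcal(x):
    """Convert kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    """Convert kcal/mol to kJ/mol."""
    return x * KJ_PER_KCAL
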