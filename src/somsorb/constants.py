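"""Physical constants in the unit system used throughout (nm, kJ/mol, e, K)."""

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314e-3

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_KJ_NM_PER_MOL_E2 = 138.9354

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Default reaction-field relative permittivity outside the cutoff sphere.
DEFAULT_EPS_RF = 61.0

#: Default non-bonded interaction cutoff, nm.
DEFAULT_CUTOFF = 1.4


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy R*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature
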