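"""Physical constants.

All free energies in this package are in kJ/mol, distances in nm and
temperatures in K, matching the conventions of molecular-simulation free
energy work.
"""

#: Molar gas constant in kJ mol^-1 K^-1 (CODATA 2018).
R = 8.314462618e-3

#: Molar gas constant in J mol^-1 K^-1, used for Henry's-law unit conversions.
R_SI = 8.314462618


def kT(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R * temperature
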