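"""Physical constants and unit conventions.

Internal units throughout the package: energies in kcal/mol, lengths in
Angstrom (A), time in ps, temperature in K.  Masses are expressed in
kcal/mol ps^2 / A^2 so that kinetic energy m v^2 / 2 comes out in kcal/mol.
"""

#: Boltzmann constant in kcal/mol/K.
KB: float = 0.0019872

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B T in kcal/mol (~0.596 kcal/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
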