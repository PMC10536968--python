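"""Physical constants and unit conventions.

Energies are kJ/mol throughout, temperatures in K, times in ps, lengths in
nm, angles in degrees on the canonical interval [-180, 180).
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008314463

DEFAULT_TEMPERATURE = 300.0  # K


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(kB*T) in mol/kJ."""
    return 1.0 / (KB * temperature)
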