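"""Unit system and physical constants.

The whole package works in the AKMA-like unit set common to biomolecular
force fields: energies in kcal/mol, lengths in Å, time in fs, masses in
amu, temperatures in K, charges in elementary charges.
"""

#: Boltzmann constant, kcal/(mol·K). Equals the molar gas constant R in
#: these units, so it is used for both per-particle and per-mole relations.
KB = 0.0019872041

#: Coulomb prefactor, kcal·Å/(mol·e²): U = COULOMB * q_i q_j / r.
COULOMB = 332.0637

#: 1 amu·Å²/fs² expressed in kcal/mol (= 1e7 J/mol / 4184 J/kcal).
#: Converts kinetic energy m v² and force/mass ratios between unit sets.
MASS_ENERGY = 1.0e7 / 4184.0

#: Standard-state volume per molecule at 1 M, Å³.
STANDARD_VOLUME = 1660.5392


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB * temperature
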