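"""Internal unit system and physical constants.

Energies are eV, lengths Å, times fs, masses amu throughout the package.
kcal mol⁻¹ appears only at reporting boundaries (free energies, MAD metrics).
"""

# 1 eV expressed in kcal/mol, used at reporting boundaries only.
EV_TO_KCAL_PER_MOL = 23.0605
KCAL_PER_MOL_TO_EV = 1.0 / EV_TO_KCAL_PER_MOL

# Boltzmann constant, eV/K.
KB = 8.617333262e-5

# 1 amu·Å²/fs² in eV: kinetic energy (eV) = 0.5 * m[amu] * v[Å/fs]² * AMU_A2_FS2_TO_EV
AMU_A2_FS2_TO_EV = 1.66053906660e-27 * 1e10 / 1.602176634e-19  # ≈ 103.6427

# Coulomb prefactor e²/(4πε₀) in eV·Å.
COULOMB_EV_A = 14.399645

ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.0026,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "X": 10.0,  # generic toy species
}

# Covalent radii (Å), Cordero et al. values for the supported elements.
COVALENT_RADII = {
    "H": 0.31,
    "He": 0.28,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "S": 1.05,
    "Cl": 1.02,
    "Ar": 1.06,
    "X": 0.76,
}

# Factor on the sum of covalent radii used when perceiving bonds.
BOND_SCALE = 1.2


def mass_of(symbol: str) -> float:
    """Atomic mass in amu, raising a clear error for unknown species."""
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {symbol!r}") from None


def covalent_radius_of(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None
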