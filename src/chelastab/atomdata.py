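"""Frozen atomic data tables.

The tables are deliberately stored in the repository (not pulled from an
external package) so that bond graphs and promolecular densities are
bit-reproducible across environments.

``COVALENT_RADII``
    Single-bond covalent radii in Angstrom (Cordero et al. self-consistent
    set; sp3 value for carbon). Used for distance-based bond perception.

``FIRST_IONIZATION_EV``
    First ionization energies in eV (CRC values). These set the asymptotic
    decay length of the promolecular atomic density: far from a neutral atom
    the density falls off as exp(-2*sqrt(2*I)*r) in atomic units, so
    lambda = 1 / (2*sqrt(2*I)) a.u.

``ATOMIC_NUMBER``
    Proton count; used as the amplitude scale of the promolecular density.
"""

from __future__ import annotations

from .errors import UnknownElementError

BOHR_A = 0.529177210903  # Angstrom per bohr
HARTREE_EV = 27.211386245988

COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
    "La": 2.07,
    "Ac": 2.15,
}

FIRST_IONIZATION_EV: dict[str, float] = {
    "H": 13.598,
    "B": 8.298,
    "C": 11.260,
    "N": 14.534,
    "O": 13.618,
    "F": 17.423,
    "Na": 5.139,
    "Mg": 7.646,
    "P": 10.487,
    "S": 10.360,
    "Cl": 12.968,
    "K": 4.341,
    "Ca": 6.113,
    "Br": 11.814,
    "I": 10.451,
    "La": 5.577,
    "Ac": 5.380,
}

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1,
    "B": 5,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "Na": 11,
    "Mg": 12,
    "P": 15,
    "S": 16,
    "Cl": 17,
    "K": 19,
    "Ca": 20,
    "Br": 35,
    "I": 53,
    "La": 57,
    "Ac": 89,
}


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise UnknownElementError(symbol, "covalent radii") from None


def decay_length_A(symbol: str) -> float:
    """Asymptotic density decay length, Angstrom: lambda = 1/(2*sqrt(2I)) a.u."""
    try:
        i_ev = FIRST_IONIZATION_EV[symbol]
    except KeyError:
        raise UnknownElementError(symbol, "ionization energy") from None
    i_au = i_ev / HARTREE_EV
    return BOHR_A / (2.0 * (2.0 * i_au) ** 0.5)


def density_amplitude(symbol: str) -> float:
    """Amplitude of the promolecular exponential (a.u.); scales with Z."""
    try:
        return float(ATOMIC_NUMBER[symbol])
    except KeyError:
        raise UnknownElementError(symbol, "atomic number") from None
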