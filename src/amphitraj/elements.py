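"""Built-in periodic table: masses, electron counts and X-ray form factors.

Covers the elements that occur in lipid/peptide/water systems plus the
common counter-ions.  Masses are CODATA/IUPAC standard atomic weights in
amu; ``Z`` is the electron count of the neutral atom, which doubles as the
q-independent X-ray scattering length in electron units.
"""

from __future__ import annotations

import numpy as np

#: element symbol -> (standard atomic weight / amu, atomic number Z)
PERIODIC_TABLE: dict[str, tuple[float, int]] = {
    "H": (1.008, 1),
    "D": (2.014, 1),
    "He": (4.0026, 2),
    "Li": (6.94, 3),
    "B": (10.81, 5),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "F": (18.998, 9),
    "Na": (22.990, 11),
    "Mg": (24.305, 12),
    "Al": (26.982, 13),
    "Si": (28.085, 14),
    "P": (30.974, 15),
    "S": (32.06, 16),
    "Cl": (35.45, 17),
    "K": (39.098, 19),
    "Ca": (40.078, 20),
    "Mn": (54.938, 25),
    "Fe": (55.845, 26),
    "Cu": (63.546, 29),
    "Zn": (65.38, 30),
    "Br": (79.904, 35),
    "I": (126.904, 53),
}

# Cromer-Mann 4-Gaussian coefficients (a1..a4, b1..b4, c) from the
# International Tables for Crystallography vol. C, for the neutral atoms
# that matter here.  f(q) = sum_k a_k exp(-b_k (q/4pi)^2) + c, f(0) ~ Z.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "Na": ((4.76260, 3.17360, 1.26740, 1.11280),
           (3.28500, 8.84220, 0.313600, 129.424), 0.676000),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "Cl": ((11.4604, 7.19640, 6.25560, 1.64550),
           (0.010400, 1.16620, 18.5194, 47.7784), -9.5574),
    "K": ((8.21860, 7.43980, 1.05190, 0.865900),
          (12.7949, 0.774800, 213.187, 41.6841), 1.42280),
}


class UnknownElementError(KeyError):
    """Raised when an element symbol cannot be resolved."""


def normalize_symbol(symbol: str) -> str:
    """Canonical 'Xx' capitalisation of an element symbol."""
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def element_mass(symbol: str) -> float:
    sym = normalize_symbol(symbol)
    try:
        return PERIODIC_TABLE[sym][0]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def element_number(symbol: str) -> int:
    """Electron count Z of the neutral atom."""
    sym = normalize_symbol(symbol)
    try:
        return PERIODIC_TABLE[sym][1]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


# names that denote monatomic ions when atom name == residue name in a PDB
_ION_NAMES = {"CL": "Cl", "NA": "Na", "MG": "Mg", "K": "K", "CA": "Ca",
              "ZN": "Zn", "FE": "Fe", "BR": "Br", "IOD": "I", "CLA": "Cl",
              "SOD": "Na", "POT": "K"}


def element_from_atom_name(name: str, residue_name: str = "") -> str:
    """Infer an element symbol from an atom name.

    The leading alphabetic characters are used.  Bare ion entries (atom
    name matching the residue name, e.g. CL/CL) resolve to the ion's
    element; otherwise the one-letter reading wins so that protein names
    like ``CA`` (alpha-carbon) resolve to carbon, not calcium.
    """
    stripped = "".join(ch for ch in name.strip() if ch.isalpha())
    if not stripped:
        raise UnknownElementError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if upper == residue_name.strip().upper() and upper in _ION_NAMES:
        return _ION_NAMES[upper]
    one = normalize_symbol(stripped[0])
    if one in PERIODIC_TABLE:
        return one
    two = normalize_symbol(stripped[:2])
    if two in PERIODIC_TABLE:
        return two
    raise UnknownElementError(f"cannot infer element from atom name {name!r}")


def cromer_mann_factor(symbol: str, q: np.ndarray) -> np.ndarray:
    """q-dependent atomic form factor f(q) in electron units.

    Falls back to the constant Z for elements without tabulated
    coefficients (only exotic species in this package's scope).
    """
    sym = normalize_symbol(symbol)
    q = np.asarray(q, dtype=float)
    if sym not in CROMER_MANN:
        return np.full_like(q, float(element_number(sym)))
    a, b, c = CROMER_MANN[sym]
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.full_like(q, c)
    for ak, bk in zip(a, b):
        f = f + ak * np.exp(-bk * s2)
    return f
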