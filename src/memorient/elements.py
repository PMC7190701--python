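"""Element bookkeeping: symbols, masses, atomic numbers, and inference from PDB records.

Masses are standard atomic weights (IUPAC 2021, rounded); atomic numbers are used as
electron counts in density profiles (partial charges are deliberately ignored).
"""

from __future__ import annotations

import numpy as np

#: standard atomic weight, g/mol
MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "BR": 79.904,
    "I": 126.904, "SE": 78.971,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "BR": 35, "SE": 34, "I": 53,
}

#: residue names that denote monatomic ions (element == residue identity)
ION_RESIDUES = {
    "NA": "NA", "NA+": "NA", "SOD": "NA", "CL": "CL", "CL-": "CL", "CLA": "CL",
    "K": "K", "K+": "K", "POT": "K", "MG": "MG", "MG2": "MG", "CA": "CA",
    "CAL": "CA", "ZN": "ZN", "FE": "FE", "FE2": "FE", "FE3": "FE",
}

_SINGLE = {"H", "C", "N", "O", "P", "S", "F", "K", "I"}


class UnknownElementError(ValueError):
    pass


def infer_element(atom_name: str, element_field: str = "", residue_name: str = "") -> str:
    """Resolve an element symbol for a PDB atom record.

    The element column (77-78) wins when present and valid.  Otherwise fall back to
    atom-name heuristics: leading digits are stripped (``1HB`` is a hydrogen), ion
    residues force the two-letter ion element, and two-letter symbols (``FE`` of a
    heme) are recognised before the single-letter organic set.
    """
    ef = element_field.strip().upper()
    if ef:
        if ef in ATOMIC_NUMBERS:
            return ef
        raise UnknownElementError(f"unrecognised element symbol {element_field!r}")
    rn = residue_name.strip().upper()
    if rn in ION_RESIDUES:
        return ION_RESIDUES[rn]
    name = atom_name.strip().upper().lstrip("0123456789'")
    alpha = ""
    for ch in name:
        if ch.isalpha():
            alpha += ch
        else:
            break
    if not alpha:
        raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")
    if alpha[0] == "H":
        return "H"
    two = alpha[:2]
    # two-letter metals/halides that cannot be confused with organic naming
    if two in {"FE", "ZN", "MG", "MN", "BR", "SE", "NI", "CU"} and two in ATOMIC_NUMBERS:
        return two
    one = alpha[0]
    if one in _SINGLE:
        return one
    if two in ATOMIC_NUMBERS:
        return two
    raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")


def masses_of(elements: np.ndarray) -> np.ndarray:
    """Vector of atomic masses for an array of element symbols."""
    try:
        return np.array([MASSES[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise UnknownElementError(f"no mass for element {exc.args[0]!r}") from exc


def atomic_numbers_of(elements: np.ndarray) -> np.ndarray:
    """Vector of atomic numbers (electron counts) for an array of element symbols."""
    try:
        return np.array([ATOMIC_NUMBERS[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise UnknownElementError(f"no atomic number for element {exc.args[0]!r}") from exc
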