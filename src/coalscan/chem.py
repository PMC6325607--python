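"""Monoisotopic mass calculus for peptides.

Masses are monoisotopic throughout: each residue contributes the mass of its
most abundant isotopologue, a peptide adds one water for its termini, and an
ion of charge ``z`` carries ``z`` protons.  These are the conventions of the
database-search settings used for peptide identification ("mass value,
monoisotopic mass"), and the defaults reproduce printed theoretical m/z
columns to within a few mDa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "WATER_MONO",
    "PROTON_MASS",
    "ResidueMassTable",
    "DEFAULT_MASS_TABLE",
    "monoisotopic_mass",
    "mz",
    "neutral_mass",
]

#: Monoisotopic mass of H2O (Da).
WATER_MONO = 18.0105646863
#: Mass of the proton (Da), used for charging ions.
PROTON_MASS = 1.00727646688

# Standard IUPAC monoisotopic residue masses (Da) for the 20 amino acids.
_RESIDUE_MONO = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue monoisotopic masses plus the water and proton constants.

    The default instance covers the 20 standard residues; users with
    nonstandard residues can supply an extended mapping.
    """

    residues: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MONO))
    water: float = WATER_MONO
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        missing = set(_RESIDUE_MONO) - set(self.residues)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residues.values()):
            raise ValueError("residue masses must be positive")
        if abs(self.water - 18.010565) > 1e-5:
            raise ValueError("water mass outside monoisotopic expectation")
        if abs(self.proton - 1.007276) > 1e-5:
            raise ValueError("proton mass outside expectation")

    def __getitem__(self, residue: str) -> float:
        return self.residues[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.residues


DEFAULT_MASS_TABLE = ResidueMassTable()


def monoisotopic_mass(
    sequence: str,
    site_deltas: Mapping[int, float] | None = None,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass of a peptide with optional site mass deltas.

    Parameters
    ----------
    sequence
        Residue string in one-letter code.
    site_deltas
        Mapping of 1-based position within ``sequence`` to a mass delta (Da),
        e.g. ``{12: 57.02146}`` for a carbamidomethylated cysteine.
    table
        Residue mass table; the default is the standard monoisotopic table.

    Returns
    -------
    float
        Sum of residue masses plus one water plus all deltas, in Da.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = table.water
    for i, letter in enumerate(sequence, start=1):
        try:
            total += table[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue {letter!r} at position {i}"
            ) from None
    if site_deltas:
        for pos, delta in site_deltas.items():
            if not 1 <= pos <= len(sequence):
                raise ValueError(
                    f"site delta position {pos} outside 1..{len(sequence)}"
                )
            total += delta
    return total


def mz(neutral: float, charge: int, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of a neutral mass protonated to the given positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * table.proton) / charge


def neutral_mass(observed_mz: float, charge: int, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral mass recovered from an observed m/z at a known charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return observed_mz * charge - charge * table.proton
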