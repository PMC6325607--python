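"""Protein records, FASTA input and Lys-C in-silico digestion.

Lys-C (lysyl endopeptidase) cleaves C-terminal of every lysine, including
K-P bonds, which is why it is preferred over trypsin for mapping
cysteine-containing peptides of GAPDH: the two diagnostic peptides
(the Cys149/Cys153 peptide and the Cys288 peptide) fall out of a clean
K-bounded tiling of the subunit sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _fasta

from .chem import DEFAULT_MASS_TABLE, ResidueMassTable

__all__ = [
    "ProteinRecord",
    "PeptideSpan",
    "read_fasta",
    "digest",
    "write_digest_tsv",
]

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and description."""

    identifier: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.identifier!r} contains non-standard residues: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideSpan:
    """A digested peptide located on its parent protein.

    Positions are 1-based and inclusive, numbered from the first residue of
    the supplied sequence.  An integer ``offset`` added to ``start``/``end``
    lets users reproduce literature numbering when their FASTA starts
    differently (e.g. lacks the initiator methionine).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span bounds inconsistent with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")
        # under canonical Lys-C rules every internal K is a missed cleavage;
        # with K-P cleavage suppressed some internal K are not cut sites,
        # so only over-declaration is an error here
        internal_k = self.sequence[:-1].count("K")
        if self.missed_cleavages > internal_k:
            raise ValueError(
                f"span {self.start}-{self.end} declares {self.missed_cleavages} "
                f"missed cleavages but contains only {internal_k} internal K"
            )

    def cysteine_positions(self) -> tuple[int, ...]:
        """1-based positions (protein numbering) of cysteines in the span."""
        return tuple(
            self.start + i for i, aa in enumerate(self.sequence) if aa == "C"
        )


def read_fasta(path: str | Path | io.TextIOBase) -> list[ProteinRecord]:
    """Read a (multi-record, line-wrapped) FASTA file into protein records."""
    records = []
    with _fasta.read(str(path) if isinstance(path, (str, Path)) else path) as reader:
        for description, sequence in reader:
            identifier = description.split()[0] if description else ""
            records.append(
                ProteinRecord(
                    identifier=identifier,
                    description=description,
                    sequence=sequence.upper(),
                )
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def digest(
    protein: ProteinRecord,
    max_missed: int = 1,
    cleave_before_proline: bool = True,
) -> list[PeptideSpan]:
    """Lys-C in-silico digestion with up to ``max_missed`` missed cleavages.

    Cleavage is C-terminal of every K; by Lys-C's canonical specificity K-P
    bonds are cleaved too (set ``cleave_before_proline=False`` to suppress
    them).  Returns spans ordered by start position then length; the
    zero-missed-cleavage spans tile the protein exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    # cleavage sites: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] == "K" and (cleave_before_proline or seq[i] != "P"):
            cuts.append(i)
    cuts.append(len(seq))

    spans: list[PeptideSpan] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 1 + max_missed + 1, len(cuts))):
            start, end = cuts[a], cuts[b]
            spans.append(
                PeptideSpan(
                    protein_id=protein.identifier,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=b - a - 1,
                )
            )
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def write_digest_tsv(spans: Iterable[PeptideSpan], path: str | Path) -> None:
    """Write digestion results as TSV (protein, start, end, sequence, missed)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tsequence\tmissed_cleavages\n")
        for s in spans:
            fh.write(
                f"{s.protein_id}\t{s.start}\t{s.end}\t{s.sequence}\t{s.missed_cleavages}\n"
            )
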