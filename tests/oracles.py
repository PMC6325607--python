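"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: peptide masses are
summed from elemental compositions and atomic masses, digestion and
peptidoform counting are brute-force enumerations.
"""

from __future__ import annotations

import itertools

# monoisotopic atomic masses (Da)
_ATOM = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# residue (amino acid minus water) elemental compositions
_RESIDUE_FORMULA = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}


def atomic_peptide_mass(sequence: str, extra_deltas: float = 0.0) -> float:
    """Peptide neutral monoisotopic mass summed atom by atom."""
    atoms: dict[str, int] = {"H": 2, "O": 1}  # terminal water
    for aa in sequence:
        for el, n in _RESIDUE_FORMULA[aa].items():
            atoms[el] = atoms.get(el, 0) + n
    return sum(_ATOM[el] * n for el, n in atoms.items()) + extra_deltas


def brute_force_lysc(sequence: str, max_missed: int) -> list[tuple[int, int, str]]:
    """All Lys-C peptides (1-based inclusive spans) by brute-force concatenation
    of up to max_missed+1 adjacent zero-missed fragments."""
    frags: list[tuple[int, int]] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa == "K" and i < len(sequence) - 1:
            frags.append((start, i + 1))
            start = i + 1
    frags.append((start, len(sequence)))
    out = []
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed + 1, len(frags))):
            a, b = frags[i][0], frags[j][1]
            out.append((a + 1, b, sequence[a:b]))
    return sorted(out)


def brute_force_form_count(n_cys: int, n_states: int, allow_disulfide: bool) -> int:
    """Count assignments of one state per cysteine plus disulphide pairings."""
    count = 0
    for assignment in itertools.product(range(n_states), repeat=n_cys):
        count += 1
    if allow_disulfide:
        for pair in itertools.combinations(range(n_cys), 2):
            for assignment in itertools.product(range(n_states), repeat=n_cys - 2):
                count += 1
    return count
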