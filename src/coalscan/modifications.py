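"""Cysteine modification catalog, peptidoform enumeration and precursor matching.

The redox state of a GAPDH cysteine after an alkylation workflow is one of a
small closed set: carbamidomethyl (IAM block of a free thiol), propionamide
(acrylamide gel artifact), trioxidation (overoxidation to sulfonic acid),
dimedone adduct (trapped sulfenic acid), S-CoAlation (mixed disulphide with
coenzyme A, +765.1 Da) or an intramolecular disulphide pairing two cysteines
of the same peptide (-2 H).  Enumerating every assignment of these states
over a peptide's cysteines and matching the resulting neutral masses against
observed precursor ions is how modified peptides are identified from the
MS1 survey scans.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import DEFAULT_MASS_TABLE, ResidueMassTable, monoisotopic_mass, mz
from .proteins import PeptideSpan

__all__ = [
    "ModificationSpec",
    "DEFAULT_CATALOG",
    "DISULFIDE",
    "ModifiedPeptideForm",
    "PrecursorObservation",
    "PrecursorMatch",
    "make_form",
    "enumerate_forms",
    "match_precursors",
    "identification_table",
    "read_observations_csv",
    "load_catalog",
]


@dataclass(frozen=True)
class ModificationSpec:
    """A named cysteine modification with exact and nominal mass deltas.

    ``kind`` is ``"per_site"`` for modifications of a single cysteine and
    ``"pairwise"`` for an intramolecular disulphide consuming two cysteines
    of the same peptide (its delta is applied once per pair).
    """

    name: str
    target: str = "C"
    exact_delta: float = 0.0
    nominal_delta: int = 0
    kind: str = "per_site"

    def __post_init__(self) -> None:
        if abs(self.exact_delta - self.nominal_delta) >= 0.5:
            raise ValueError(
                f"{self.name}: exact delta {self.exact_delta} is further than "
                f"0.5 Da from nominal {self.nominal_delta}"
            )
        if self.kind not in ("per_site", "pairwise"):
            raise ValueError(f"unknown modification kind {self.kind!r}")


CAM = ModificationSpec("CAM", "C", 57.02146, 57)
PROPIONAMIDE = ModificationSpec("PA", "C", 71.03711, 71)
TRIOXIDATION = ModificationSpec("SO3H", "C", 47.98474, 48)
DIMEDONE = ModificationSpec("dimedone", "C", 138.06808, 138)
COALATION = ModificationSpec("CoAlation", "C", 765.09956, 765)
DISULFIDE = ModificationSpec("disulphide", "C", -2.01565, -2, kind="pairwise")

#: The modification set of the identification workflow.
DEFAULT_CATALOG: tuple[ModificationSpec, ...] = (
    CAM,
    PROPIONAMIDE,
    TRIOXIDATION,
    DIMEDONE,
    COALATION,
    DISULFIDE,
)


@dataclass(frozen=True)
class ModifiedPeptideForm:
    """A peptide span with one modification state per cysteine.

    ``site_states`` maps 1-based protein positions of cysteines to per-site
    specs; ``disulfide_pairs`` holds position pairs bonded intramolecularly.
    A cysteine in a disulphide pair carries no per-site state.
    """

    peptide: PeptideSpan
    site_states: Mapping[int, ModificationSpec] = field(default_factory=dict)
    disulfide_pairs: frozenset[tuple[int, int]] = frozenset()
    neutral_mass: float = 0.0

    def __post_init__(self) -> None:
        paired = {p for pair in self.disulfide_pairs for p in pair}
        if paired & set(self.site_states):
            raise ValueError("disulphide-bonded cysteine also carries a per-site state")
        cys = set(self.peptide.cysteine_positions())
        outside = (set(self.site_states) | paired) - cys
        if outside:
            raise ValueError(f"modification positions {sorted(outside)} are not cysteines")

    @property
    def coalated_positions(self) -> tuple[int, ...]:
        return tuple(
            sorted(p for p, s in self.site_states.items() if s.name == "CoAlation")
        )

    def modification_names(self) -> str:
        parts = [
            f"{self.site_states[p].name}" for p in sorted(self.site_states)
        ] + ["disulphide" for _ in self.disulfide_pairs]
        return ", ".join(parts) if parts else "unmodified"

    def annotated_sequence(self) -> str:
        """Sequence with per-site states interleaved, e.g. ``...C(+CAM)...``."""
        out = []
        paired = {p for pair in self.disulfide_pairs for p in pair}
        for i, aa in enumerate(self.peptide.sequence):
            pos = self.peptide.start + i
            out.append(aa)
            if pos in self.site_states:
                spec = self.site_states[pos]
                sign = "+" if spec.exact_delta >= 0 else ""
                out.append(f"({sign}{spec.name})")
            elif pos in paired:
                out.append("(-S-S-)")
        return "".join(out)


def _form_mass(
    peptide: PeptideSpan,
    site_states: Mapping[int, ModificationSpec],
    pairs: Iterable[tuple[int, int]],
    table: ResidueMassTable,
) -> float:
    deltas: dict[int, float] = {}
    for pos, spec in site_states.items():
        deltas[pos - peptide.start + 1] = spec.exact_delta
    base = monoisotopic_mass(peptide.sequence, deltas, table)
    return base + sum(DISULFIDE.exact_delta for _ in pairs)


def make_form(
    peptide: PeptideSpan,
    site_states: Mapping[int, ModificationSpec] | None = None,
    disulfide_pairs: Iterable[tuple[int, int]] = (),
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> ModifiedPeptideForm:
    """Build a form with its neutral mass populated."""
    site_states = dict(site_states or {})
    pairs = frozenset(tuple(sorted(p)) for p in disulfide_pairs)
    return ModifiedPeptideForm(
        peptide=peptide,
        site_states=site_states,
        disulfide_pairs=pairs,
        neutral_mass=_form_mass(peptide, site_states, pairs, table),
    )


def enumerate_forms(
    peptide: PeptideSpan,
    catalog: Sequence[ModificationSpec] = DEFAULT_CATALOG,
    max_coalations: int | None = 1,
    allow_disulfide: bool = True,
    allow_unmodified_cys: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[ModifiedPeptideForm]:
    """Enumerate every modified form of a peptide over a modification catalog.

    Every assignment of one per-site state per cysteine is produced, plus —
    when ``allow_disulfide`` and the catalog contains a pairwise spec — every
    choice of two cysteines bonded as an intramolecular disulphide with the
    remaining cysteines taking per-site states.  Free (unmodified) cysteines
    are excluded by default because the workflows alkylate all free thiols
    with IAM before digestion; set ``allow_unmodified_cys`` to include them.

    ``max_coalations`` caps CoA mixed disulphides per peptide (default one,
    matching how multiply CoAlated peptides are not observed).
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    per_site = [m for m in catalog if m.kind == "per_site" and m.target == "C"]
    pairwise = [m for m in catalog if m.kind == "pairwise"]
    cys = peptide.cysteine_positions()
    if not cys:
        return []

    states: list[ModificationSpec | None] = list(per_site)
    if allow_unmodified_cys:
        states.append(None)

    forms: list[ModifiedPeptideForm] = []
    seen: set[tuple] = set()

    def add(site_states: dict[int, ModificationSpec], pairs: frozenset) -> None:
        n_coa = sum(1 for s in site_states.values() if s.name == "CoAlation")
        if max_coalations is not None and n_coa > max_coalations:
            return
        key = (tuple(sorted((p, s.name) for p, s in site_states.items())), pairs)
        if key in seen:
            return
        seen.add(key)
        forms.append(
            ModifiedPeptideForm(
                peptide=peptide,
                site_states=site_states,
                disulfide_pairs=pairs,
                neutral_mass=_form_mass(peptide, site_states, pairs, table),
            )
        )

    for assignment in itertools.product(states, repeat=len(cys)):
        site_states = {
            pos: spec for pos, spec in zip(cys, assignment) if spec is not None
        }
        add(site_states, frozenset())

    if allow_disulfide and pairwise:
        for pair in itertools.combinations(cys, 2):
            remaining = [p for p in cys if p not in pair]
            for assignment in itertools.product(states, repeat=len(remaining)):
                site_states = {
                    pos: spec
                    for pos, spec in zip(remaining, assignment)
                    if spec is not None
                }
                add(site_states, frozenset({tuple(sorted(pair))}))
    return forms


@dataclass(frozen=True)
class PrecursorObservation:
    """An observed MS1 precursor ion."""

    mz: float
    charge: int
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class PrecursorMatch:
    """A form matched to an observation at some charge, with signed error."""

    form: ModifiedPeptideForm
    observation: PrecursorObservation
    theoretical_mz: float
    error: float  # observed - theoretical, Da (on the m/z scale)


def read_observations_csv(path: str | Path) -> list[PrecursorObservation]:
    """Read precursor observations from CSV with columns mz, charge[, intensity]."""
    df = pd.read_csv(path)
    for col in ("mz", "charge"):
        if col not in df.columns:
            raise ValueError(f"observations CSV missing column {col!r}")
    obs = []
    for i, row in df.iterrows():
        try:
            obs.append(
                PrecursorObservation(
                    mz=float(row["mz"]),
                    charge=int(row["charge"]),
                    intensity=float(row["intensity"]) if "intensity" in df.columns else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"observations CSV row {i + 2}: {exc}") from exc
    return obs


def match_precursors(
    forms: Sequence[ModifiedPeptideForm],
    observations: Sequence[PrecursorObservation],
    tolerance: float = 0.5,
    charge_range: tuple[int, int] = (1, 4),
    ms1_window: tuple[float, float] | None = (1000.0, 1600.0),
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[PrecursorMatch]:
    """Match modified forms against observed precursors within a Da tolerance.

    A match is emitted for every (form, observation) pair whose theoretical
    m/z at the observation's charge lies within ``tolerance`` Da of the
    observed m/z, provided the observed m/z sits inside the MS1 survey
    window and the charge lies inside ``charge_range``.  The signed error
    (observed - theoretical) is recorded, mirroring an identification
    table's error column.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    lo_z, hi_z = charge_range
    matches: list[PrecursorMatch] = []
    for obs in observations:
        if not lo_z <= obs.charge <= hi_z:
            continue
        if ms1_window is not None and not ms1_window[0] <= obs.mz <= ms1_window[1]:
            continue
        for form in forms:
            theo = mz(form.neutral_mass, obs.charge, table)
            err = obs.mz - theo
            if abs(err) <= tolerance:
                matches.append(
                    PrecursorMatch(
                        form=form, observation=obs, theoretical_mz=theo, error=err
                    )
                )
    matches.sort(
        key=lambda m: (m.form.peptide.start, m.theoretical_mz, abs(m.error))
    )
    return matches


def identification_table(matches: Sequence[PrecursorMatch]) -> pd.DataFrame:
    """Tabulate precursor matches, one row per distinct match.

    Columns mirror a modified-peptide identification table: positions,
    annotated sequence, modification names, theoretical and observed m/z,
    charge and signed error.  Duplicate matches collapse to one row; rows
    are sorted by span start then theoretical m/z.
    """
    rows = []
    for m in matches:
        rows.append(
            {
                "positions": f"{m.form.peptide.start}-{m.form.peptide.end}",
                "sequence": m.form.annotated_sequence(),
                "modifications": m.form.modification_names(),
                "theoretical_mz": round(m.theoretical_mz, 4),
                "observed_mz": m.observation.mz,
                "charge": m.observation.charge,
                "error_da": round(m.error, 4),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "positions",
            "sequence",
            "modifications",
            "theoretical_mz",
            "observed_mz",
            "charge",
            "error_da",
        ],
    )
    if not df.empty:
        df = df.drop_duplicates().reset_index(drop=True)
        start = df["positions"].str.split("-").str[0].astype(int)
        df = (
            df.assign(_start=start)
            .sort_values(["_start", "theoretical_mz"])
            .drop(columns="_start")
            .reset_index(drop=True)
        )
    return df


def load_catalog(path: str | Path) -> list[ModificationSpec]:
    """Load a modification catalog from a YAML/JSON-style config file.

    The file holds a list of records with fields name, target, exact_delta,
    nominal_delta and kind.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ValueError("catalog file must contain a list of modification records")
    return [
        ModificationSpec(
            name=rec["name"],
            target=rec.get("target", "C"),
            exact_delta=float(rec["exact_delta"]),
            nominal_delta=int(rec["nominal_delta"]),
            kind=rec.get("kind", "per_site"),
        )
        for rec in data
    ]
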