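"""b/y fragment ladders with CoA remnant chemistry, diagnostic neutral-loss
scanning, spectrum annotation and modification-site localization.

Under CID, the CoA moiety of a CoAlated peptide fragments preferentially at
its phosphodiester and pantetheine bonds.  The precursor therefore sheds
characteristic neutral fragments of nominally 410, 428 and 508 Da (with
hydrogen-shift variants at 409, 427 and 507), while the complementary CoA
remnant — nominally +258, +338 or +356 Da — stays attached to the modified
cysteine and shows up on the b/y backbone ions.  Each loss/remnant pair sums
to the full CoAlation delta (~765 Da) to within the ambiguity of one
transferred hydrogen.  Scanning an MS/MS spectrum for the three precursor
neutral losses is the diagnostic screen for CoAlated peptides; the b/y
ladder with remnant variants then localizes the modified cysteine.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import DEFAULT_MASS_TABLE, ResidueMassTable
from .modifications import ModifiedPeptideForm

__all__ = [
    "CoAFragRules",
    "DEFAULT_RULES",
    "FragmentIon",
    "MS2Spectrum",
    "ScanResult",
    "Annotation",
    "fragment_ladder",
    "diagnostic_scan",
    "annotate_spectrum",
    "localize_site",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class CoAFragRules:
    """Diagnostic CoA fragmentation chemistry.

    ``losses`` are the nominal neutral losses from the precursor; each has a
    hydrogen-shift ``variant`` one Da below.  ``remnants`` are the nominal
    deltas retained on the CoAlated cysteine.  Loss and remnant are paired in
    order: losses[i] + remnants[i] ~ full CoAlation delta.
    """

    losses: tuple[float, ...] = (410.0, 428.0, 508.0)
    loss_variants: tuple[float, ...] = (409.0, 427.0, 507.0)
    remnants: tuple[float, ...] = (356.0, 338.0, 258.0)
    full_delta: float = 765.09956

    def __post_init__(self) -> None:
        if len(self.losses) != len(self.remnants):
            raise ValueError("losses and remnants must pair up")
        for loss, rem in zip(self.losses, self.remnants):
            if not 764.0 <= loss + rem <= 766.0:
                raise ValueError(
                    f"loss {loss} + remnant {rem} does not reconstruct the "
                    "CoAlation delta within 2 Da"
                )


DEFAULT_RULES = CoAFragRules()

#: remnant-state labels for FragmentIon
_REMNANT_STATES = ("fullCoA", "remnant258", "remnant338", "remnant356")


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b or y backbone ion, possibly carrying a CoA remnant."""

    series: str  # "b" | "y"
    ordinal: int
    charge: int
    remnant_state: str  # "none" | "fullCoA" | "remnant258" | "remnant338" | "remnant356"
    mz: float

    @property
    def label(self) -> str:
        tag = "" if self.remnant_state == "none" else f"[{self.remnant_state}]"
        z = "+" * self.charge
        return f"{self.series}{self.ordinal}{tag}{z}"


@dataclass
class MS2Spectrum:
    """A centroided MS/MS spectrum with its precursor."""

    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def precursor_neutral_mass(self, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
        if self.precursor_charge is None:
            raise ValueError("precursor charge is required")
        z = self.precursor_charge
        return self.precursor_mz * z - z * table.proton


@dataclass(frozen=True)
class LossHit:
    """One matched diagnostic neutral-loss peak."""

    loss: float  # nominal loss family (410/428/508)
    variant_used: float  # the loss value that actually matched (e.g. 409)
    product_charge: int
    expected_mz: float
    matched_mz: float
    intensity: float


@dataclass(frozen=True)
class ScanResult:
    """Outcome of the CoA diagnostic neutral-loss scan of one spectrum."""

    hits: tuple[LossHit, ...]
    n_losses_matched: int
    is_coalated_candidate: bool


@dataclass(frozen=True)
class MatchedFragment:
    ion: FragmentIon
    observed_mz: float
    intensity: float


@dataclass(frozen=True)
class Annotation:
    """b/y annotation of a spectrum against one peptidoform."""

    matched: tuple[MatchedFragment, ...]
    coverage: float
    n_theoretical_positions: int
    precursor_consistent: bool = True


def _cumulative_masses(
    form: ModifiedPeptideForm, table: ResidueMassTable
) -> tuple[list[float], set[int], tuple[int, int] | None]:
    """Per-residue masses with per-site deltas applied.

    Returns (residue masses incl. deltas, 0-based indices of CoAlated
    residues, 0-based (i, j) span of a disulphide pair if present).
    """
    pep = form.peptide
    masses = [table[aa] for aa in pep.sequence]
    coa_idx: set[int] = set()
    for pos, spec in form.site_states.items():
        i = pos - pep.start
        masses[i] += spec.exact_delta
        if spec.name == "CoAlation":
            coa_idx.add(i)
    ring: tuple[int, int] | None = None
    for a, b in form.disulfide_pairs:
        i, j = a - pep.start, b - pep.start
        # pairwise delta assigned to the N-terminal partner; ring suppression
        # below keeps split fragments from ever separating the pair
        masses[i] += -2.01565
        ring = (min(i, j), max(i, j))
    return masses, coa_idx, ring


def fragment_ladder(
    form: ModifiedPeptideForm,
    max_fragment_charge: int = 1,
    rules: CoAFragRules = DEFAULT_RULES,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
    emit_ring_ions: bool = False,
) -> list[FragmentIon]:
    """Theoretical b/y ions of a modified peptidoform.

    All b1..b(n-1) and y1..y(n-1) ions at charges 1..``max_fragment_charge``
    are produced.  For every ion containing a CoAlated cysteine, four extra
    variants are emitted: the full CoAlation mass and the three nominal CoA
    remnants (+258/+338/+356) replacing it — CID moves most of the CoA mass
    off the backbone, so remnant ions dominate real spectra.  For a
    disulphide-ringed form, cleavage sites inside the ring are suppressed
    by default (the ring holds the two halves together); pass
    ``emit_ring_ions=True`` for ring-opened ladders.
    """
    pep = form.peptide
    n = len(pep.sequence)
    if n < 2:
        raise ValueError("peptide must have at least 2 residues to fragment")
    masses, coa_idx, ring = _cumulative_masses(form, table)
    remnant_deltas = {
        "remnant258": 258.0,
        "remnant338": 338.0,
        "remnant356": 356.0,
    }

    ions: list[FragmentIon] = []
    for i in range(1, n):  # cleavage between residues i-1 and i (0-based)
        if ring is not None and not emit_ring_ions and ring[0] <= i - 1 < ring[1]:
            continue
        b_mass = sum(masses[:i])
        y_mass = sum(masses[i:]) + table.water
        b_coa = coa_idx & set(range(i))
        y_coa = coa_idx & set(range(i, n))
        for z in range(1, max_fragment_charge + 1):
            for series, frag_mass, has_coa in (
                ("b", b_mass, bool(b_coa)),
                ("y", y_mass, bool(y_coa)),
            ):
                ordinal = i if series == "b" else n - i
                mz_val = (frag_mass + z * table.proton) / z
                ions.append(FragmentIon(series, ordinal, z, "none", mz_val))
                if has_coa:
                    # variants re-express the CoAlated cysteine's delta:
                    # "none" above already carries the full exact delta via
                    # site masses, so keep it as fullCoA and add remnants
                    ions[-1] = FragmentIon(series, ordinal, z, "fullCoA", mz_val)
                    for state, delta in remnant_deltas.items():
                        variant = (
                            frag_mass - rules.full_delta + delta + z * table.proton
                        ) / z
                        ions.append(FragmentIon(series, ordinal, z, state, variant))
    return ions


def diagnostic_scan(
    spectrum: MS2Spectrum,
    rules: CoAFragRules = DEFAULT_RULES,
    tolerance: float = 1.0,
    min_losses: int = 2,
    min_rel_intensity: float = 0.05,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> ScanResult:
    """Scan a spectrum for the CoA diagnostic precursor neutral losses.

    For each nominal loss (and its hydrogen-shift variant) and each assumed
    product charge from the precursor charge down to 1, the scanner looks
    for a peak at ``(M_prec - L + z'*proton)/z'`` within ``tolerance`` Da,
    where ``M_prec`` is the precursor neutral mass.  A loss family counts as
    matched when any of its variants/charges hits a peak at or above
    ``min_rel_intensity`` of the base peak.  The spectrum is flagged a
    CoAlated candidate when at least ``min_losses`` distinct loss families
    match.
    """
    if spectrum.precursor_charge is None:
        raise ValueError("precursor charge is required for a diagnostic scan")
    m_prec = spectrum.precursor_neutral_mass(table)
    base = spectrum.base_peak_intensity
    threshold = min_rel_intensity * base
    hits: list[LossHit] = []
    matched_families: set[float] = set()
    mz_arr, int_arr = spectrum.mz, spectrum.intensity
    for loss, variant in zip(rules.losses, rules.loss_variants):
        for loss_value in (loss, variant):
            for z in range(spectrum.precursor_charge, 0, -1):
                expected = (m_prec - loss_value + z * table.proton) / z
                idx = _nearest_peak(mz_arr, expected, tolerance)
                if idx is None:
                    continue
                if int_arr[idx] < threshold:
                    continue
                hits.append(
                    LossHit(
                        loss=loss,
                        variant_used=loss_value,
                        product_charge=z,
                        expected_mz=expected,
                        matched_mz=float(mz_arr[idx]),
                        intensity=float(int_arr[idx]),
                    )
                )
                matched_families.add(loss)
    n = len(matched_families)
    return ScanResult(
        hits=tuple(hits),
        n_losses_matched=n,
        is_coalated_candidate=n >= min_losses,
    )


def _nearest_peak(mz_arr: np.ndarray, target: float, tolerance: float) -> int | None:
    """Index of the closest peak within tolerance, or None."""
    if mz_arr.size == 0:
        return None
    i = bisect.bisect_left(mz_arr.tolist(), target)
    best, best_d = None, tolerance
    for j in (i - 1, i):
        if 0 <= j < mz_arr.size:
            d = abs(mz_arr[j] - target)
            if d <= best_d:
                best, best_d = j, d
    return best


def annotate_spectrum(
    spectrum: MS2Spectrum,
    form: ModifiedPeptideForm,
    fragment_tolerance: float = 0.5,
    max_fragment_charge: int = 1,
    precursor_tolerance: float = 0.5,
    rules: CoAFragRules = DEFAULT_RULES,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> Annotation:
    """Annotate a spectrum's peaks with a form's theoretical b/y ladder.

    Matching is greedy nearest-peak within ``fragment_tolerance``, each
    observed peak consumed at most once (ions are tried in descending
    intensity of their best candidate peak).  Coverage is the fraction of
    distinct (series, ordinal) backbone positions in the theoretical ladder
    that matched at any charge or remnant state.
    """
    ions = fragment_ladder(form, max_fragment_charge, rules, table)
    positions = {(ion.series, ion.ordinal) for ion in ions}
    consistent = True
    if spectrum.precursor_charge is not None:
        theo_prec = (
            form.neutral_mass + spectrum.precursor_charge * table.proton
        ) / spectrum.precursor_charge
        if abs(theo_prec - spectrum.precursor_mz) > precursor_tolerance:
            consistent = False
    if spectrum.mz.size == 0:
        return Annotation((), 0.0, len(positions), consistent)

    # candidate (ion, peak) pairs, best intensity first, greedy assignment
    candidates: list[tuple[float, int, FragmentIon]] = []
    for ion in ions:
        idx = _nearest_peak(spectrum.mz, ion.mz, fragment_tolerance)
        if idx is not None:
            candidates.append((float(spectrum.intensity[idx]), idx, ion))
    candidates.sort(key=lambda t: (-t[0], t[2].label))
    used: set[int] = set()
    matched: list[MatchedFragment] = []
    for intensity, idx, ion in candidates:
        if idx in used:
            # peak taken; look for another peak in tolerance
            alt = _nearest_free_peak(spectrum.mz, ion.mz, fragment_tolerance, used)
            if alt is None:
                continue
            idx, intensity = alt, float(spectrum.intensity[alt])
        used.add(idx)
        matched.append(MatchedFragment(ion, float(spectrum.mz[idx]), intensity))
    covered = {(m.ion.series, m.ion.ordinal) for m in matched}
    coverage = len(covered) / len(positions) if positions else 0.0
    return Annotation(tuple(matched), coverage, len(positions), consistent)


def _nearest_free_peak(
    mz_arr: np.ndarray, target: float, tolerance: float, used: set[int]
) -> int | None:
    i = bisect.bisect_left(mz_arr.tolist(), target)
    best, best_d = None, tolerance
    for j in range(max(0, i - 4), min(mz_arr.size, i + 4)):
        if j in used:
            continue
        d = abs(mz_arr[j] - target)
        if d <= best_d:
            best, best_d = j, d
    return best


@dataclass(frozen=True)
class LocalizationResult:
    """Ranked site assignments for one spectrum."""

    ranking: tuple[tuple[ModifiedPeptideForm, float], ...]
    tie: bool

    @property
    def best(self) -> ModifiedPeptideForm:
        return self.ranking[0][0]


def localize_site(
    spectrum: MS2Spectrum,
    candidates: Sequence[ModifiedPeptideForm],
    fragment_tolerance: float = 0.5,
    max_fragment_charge: int = 1,
    rules: CoAFragRules = DEFAULT_RULES,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> LocalizationResult:
    """Rank isobaric site-permutation candidates against one spectrum.

    Candidates must share the peptide and total mass (site permutations of
    the same modification set).  Each candidate is scored by the summed
    intensity of matched *site-determining* ions — theoretical ions whose
    m/z is not shared (within a small epsilon) by every other candidate.
    An explicit tie flag is set when the top scores are equal, mirroring
    the honest outcome when no site-determining ion was observed (as for
    the in vivo CoAlated peptide whose modified cysteine could not be
    assigned).
    """
    if len(candidates) < 2:
        raise ValueError("nothing to localize: need at least 2 candidate forms")
    pep0 = candidates[0].peptide
    for c in candidates[1:]:
        if c.peptide != pep0:
            raise ValueError("candidates must share the same peptide")
        if abs(c.neutral_mass - candidates[0].neutral_mass) > 1e-6:
            raise ValueError("candidates must be isobaric site permutations")

    ladders = [
        fragment_ladder(c, max_fragment_charge, rules, table) for c in candidates
    ]
    eps = 1e-6
    # an ion m/z shared by all ladders carries no site information
    common: set[float] | None = None
    for ladder in ladders:
        rounded = {round(ion.mz / eps) for ion in ladder}
        common = rounded if common is None else common & rounded

    scores: list[float] = []
    for ladder in ladders:
        site_ions = [ion for ion in ladder if round(ion.mz / eps) not in common]
        used: set[int] = set()
        score = 0.0
        for ion in sorted(site_ions, key=lambda x: x.mz):
            idx = _nearest_free_peak(spectrum.mz, ion.mz, fragment_tolerance, used)
            if idx is not None:
                used.add(idx)
                score += float(spectrum.intensity[idx])
        scores.append(score)

    order = sorted(range(len(candidates)), key=lambda i: -scores[i])
    ranking = tuple((candidates[i], scores[i]) for i in order)
    tie = len(scores) > 1 and scores[order[0]] == scores[order[1]]
    return LocalizationResult(ranking=ranking, tie=tie)


def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read centroided MS/MS spectra from a Mascot generic format file."""
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            spectra.append(
                MS2Spectrum(
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MS2Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (BEGIN IONS blocks with PEPMASS/CHARGE rows)."""
    entries = []
    for s in spectra:
        params = {"title": s.title or "spectrum", "pepmass": s.precursor_mz}
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def annotation_to_records(annotation: Annotation) -> list[dict]:
    """Flatten an annotation to JSON/TSV-ready records."""
    return [
        {
            "ion": m.ion.label,
            "series": m.ion.series,
            "ordinal": m.ion.ordinal,
            "charge": m.ion.charge,
            "remnant_state": m.ion.remnant_state,
            "theoretical_mz": round(m.ion.mz, 4),
            "observed_mz": round(m.observed_mz, 4),
            "intensity": m.intensity,
        }
        for m in annotation.matched
    ]
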