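"""Workflow orchestration: identification and redox-biochemistry runs.

Two workflows tie the stages together.  ``run_identify`` chains FASTA
digestion, modified-form enumeration, precursor matching, CoA diagnostic
neutral-loss scanning, spectrum annotation and site localization into an
identification report.  ``run_biochem`` fits whatever kinetics, titration,
initial-rate and intact-mass CSV inputs are supplied, one JSON report per
analysis.  Both are deterministic given inputs and configuration, and log
input/output counts of every stage to stderr.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fragments, intact, kinetics, modifications, proteins, titration
from .fragments import DEFAULT_RULES
from .kinetics import ActivityTimeCourse
from .modifications import DEFAULT_CATALOG
from .titration import TitrationPoint

__all__ = ["RunConfig", "run_identify", "run_biochem"]

log = logging.getLogger("coalscan")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the identification workflow's
    acquisition and search settings (0.5 Da tolerances, MS1 window
    1000-1600, charges 1-4, one missed cleavage)."""

    fasta: Path | None = None
    mgf: Path | None = None
    precursors: Path | None = None
    timecourses: Path | None = None
    titration: Path | None = None
    initial_rates: Path | None = None
    intact_peaks: Path | None = None
    catalog_file: Path | None = None
    precursor_tolerance: float = 0.5
    fragment_tolerance: float = 0.5
    diagnostic_tolerance: float = 1.0
    min_losses: int = 2
    min_rel_intensity: float = 0.05
    charge_range: tuple[int, int] = (1, 4)
    ms1_window: tuple[float, float] = (1000.0, 1600.0)
    max_missed_cleavages: int = 1
    max_coalations: int | None = 1
    native_molar_mass: float = kinetics.TETRAMER_MASS_DA
    seed: int = 0
    outdir: Path = Path("coalscan-out")

    def __post_init__(self) -> None:
        for name in ("precursor_tolerance", "fragment_tolerance", "diagnostic_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ms1_window[0] >= self.ms1_window[1]:
            raise ValueError("MS1 window low bound must be below high bound")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value YAML config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("charge_range", "ms1_window"):
            if key in data:
                data[key] = tuple(data[key])
        for key in (
            "fasta", "mgf", "precursors", "timecourses", "titration",
            "initial_rates", "intact_peaks", "catalog_file", "outdir",
        ):
            if key in data and data[key] is not None:
                data[key] = Path(data[key])
        return cls(**data)


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"{what} input not configured")
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return Path(path)


def run_identify(config: RunConfig) -> dict:
    """Run the identification workflow; returns the report dict.

    Writes identification TSV/JSON and a diagnostic-scan report under
    ``config.outdir``.  Missing inputs raise FileNotFoundError naming the
    path; an empty match list is a success with a warning.
    """
    fasta = _require(config.fasta, "FASTA")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = (
        modifications.load_catalog(config.catalog_file)
        if config.catalog_file
        else list(DEFAULT_CATALOG)
    )
    records = proteins.read_fasta(fasta)
    log.info("identify: %d protein(s) read", len(records))

    spans = []
    for rec in records:
        spans.extend(proteins.digest(rec, config.max_missed_cleavages))
    cys_spans = [s for s in spans if "C" in s.sequence]
    log.info("identify: %d peptide spans, %d with cysteine", len(spans), len(cys_spans))

    forms = []
    for span in cys_spans:
        forms.extend(
            modifications.enumerate_forms(
                span, catalog, max_coalations=config.max_coalations
            )
        )
    log.info("identify: %d modified forms enumerated", len(forms))

    matches = []
    if config.precursors is not None:
        obs = modifications.read_observations_csv(_require(config.precursors, "precursors"))
        matches = modifications.match_precursors(
            forms,
            obs,
            tolerance=config.precursor_tolerance,
            charge_range=config.charge_range,
            ms1_window=config.ms1_window,
        )
        log.info("identify: %d observations -> %d precursor matches", len(obs), len(matches))
        if not matches:
            log.warning("identify: no precursor matches within tolerance")

    table = modifications.identification_table(matches)
    table.to_csv(outdir / "identification.tsv", sep="\t", index=False)

    scan_reports = []
    annotations = []
    if config.mgf is not None:
        spectra = fragments.read_mgf(_require(config.mgf, "MGF"))
        log.info("identify: %d MS/MS spectra read", len(spectra))
        for i, spec in enumerate(spectra):
            scan = fragments.diagnostic_scan(
                spec,
                DEFAULT_RULES,
                tolerance=config.diagnostic_tolerance,
                min_losses=config.min_losses,
                min_rel_intensity=config.min_rel_intensity,
            )
            scan_reports.append(
                {
                    "spectrum": spec.title or f"spectrum-{i}",
                    "precursor_mz": spec.precursor_mz,
                    "precursor_charge": spec.precursor_charge,
                    "n_losses_matched": scan.n_losses_matched,
                    "coalated_candidate": scan.is_coalated_candidate,
                    "hits": [
                        {
                            "loss": h.loss,
                            "variant": h.variant_used,
                            "charge": h.product_charge,
                            "matched_mz": h.matched_mz,
                        }
                        for h in scan.hits
                    ],
                }
            )
            # annotate against precursor-consistent forms; localize when the
            # candidates are isobaric site permutations
            cand = [
                f
                for f in forms
                if spec.precursor_charge is not None
                and abs(
                    (f.neutral_mass / spec.precursor_charge + fragments.DEFAULT_MASS_TABLE.proton)
                    - spec.precursor_mz
                )
                <= config.precursor_tolerance
            ]
            for f in cand:
                ann = fragments.annotate_spectrum(
                    spec, f, fragment_tolerance=config.fragment_tolerance
                )
                annotations.append(
                    {
                        "spectrum": spec.title or f"spectrum-{i}",
                        "form": f.annotated_sequence(),
                        "coverage": ann.coverage,
                        "n_matched": len(ann.matched),
                    }
                )
            iso = [
                c
                for c in cand
                if abs(c.neutral_mass - cand[0].neutral_mass) <= 1e-6
            ] if cand else []
            if len(iso) >= 2:
                loc = fragments.localize_site(
                    spec, iso, fragment_tolerance=config.fragment_tolerance
                )
                scan_reports[-1]["localization"] = {
                    "best": loc.best.annotated_sequence(),
                    "tie": loc.tie,
                    "scores": [
                        {"form": f.annotated_sequence(), "score": s}
                        for f, s in loc.ranking
                    ],
                }
        log.info(
            "identify: %d/%d spectra flagged CoAlated-candidate",
            sum(r["coalated_candidate"] for r in scan_reports),
            len(scan_reports),
        )

    report = {
        "n_proteins": len(records),
        "n_spans": len(spans),
        "n_forms": len(forms),
        "n_matches": len(matches),
        "identification": table.to_dict(orient="records"),
        "scans": scan_reports,
        "annotations": annotations,
    }
    with open(outdir / "identification.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _read_timecourses_csv(path: Path) -> list[ActivityTimeCourse]:
    df = pd.read_csv(path)
    needed = {"condition", "concentration_M", "time_s", "activity_pct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: time-course CSV missing columns {sorted(missing)} (row 1)"
        )
    courses = []
    for (cond, conc), grp in df.groupby(["condition", "concentration_M"], sort=False):
        grp = grp.sort_values("time_s")
        courses.append(
            ActivityTimeCourse(
                condition=str(cond),
                concentration=float(conc),
                times=tuple(float(t) for t in grp["time_s"]),
                activities=tuple(float(a) for a in grp["activity_pct"]),
            )
        )
    return courses


def run_biochem(config: RunConfig) -> dict:
    """Run the biochemistry workflow on whichever CSV inputs are configured.

    Produces one JSON report per analysis (kinetics, pKa, Michaelis-Menten,
    intact mass) under ``config.outdir`` and returns the combined dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if config.timecourses is not None:
        path = _require(config.timecourses, "time-course")
        courses = _read_timecourses_csv(path)
        log.info("biochem: %d time courses read", len(courses))
        # group by condition label prefix (reagent family) for the 2nd stage
        families: dict[str, list[ActivityTimeCourse]] = {}
        for tc in courses:
            family = tc.condition.rsplit(" ", 2)[0]
            families.setdefault(family, []).append(tc)
        kin_report = {}
        for family, tcs in families.items():
            stage1, stage2 = kinetics.fit_inactivation_series(tcs)
            kin_report[family] = {
                "k2_per_M_s": stage2.k2,
                "k2_se": stage2.k2_se,
                "per_concentration": [
                    {
                        "condition": tc.condition,
                        "concentration_M": tc.concentration,
                        "k_obs_per_s": r.k_obs,
                        "k_obs_se": r.k_obs_se,
                        "t_half_s": r.t_half,
                        "t_half_interpolated_s": r.t_half_interpolated(),
                    }
                    for tc, r in zip(tcs, stage1)
                ],
            }
        report["kinetics"] = kin_report
        with open(outdir / "kinetics.json", "w") as fh:
            json.dump(kin_report, fh, indent=2)

    if config.titration is not None:
        path = _require(config.titration, "titration")
        df = pd.read_csv(path)
        for col in ("pH", "activity_pct"):
            if col not in df.columns:
                raise ValueError(f"{path}: titration CSV missing column {col!r} (row 1)")
        points = [
            TitrationPoint(float(r["pH"]), float(r["activity_pct"]))
            for _, r in df.iterrows()
        ]
        res = titration.ThiolTitrationModel(points).fit()
        pka_report = {
            "pka": res.pka,
            "pka_se": res.pka_se,
            "top_pct": res.top,
            "bottom_pct": res.bottom,
        }
        report["pka"] = pka_report
        with open(outdir / "pka.json", "w") as fh:
            json.dump(pka_report, fh, indent=2)

    if config.initial_rates is not None:
        path = _require(config.initial_rates, "initial-rate")
        df = pd.read_csv(path)
        for col in ("substrate_mM", "rate_U_per_mg"):
            if col not in df.columns:
                raise ValueError(f"{path}: rate CSV missing column {col!r} (row 1)")
        res = kinetics.MichaelisMentenModel(
            df["substrate_mM"].to_numpy(), df["rate_U_per_mg"].to_numpy()
        ).fit(native_molar_mass=config.native_molar_mass)
        mm_report = {
            "vmax_U_per_mg": res.vmax,
            "vmax_se": res.vmax_se,
            "km_mM": res.km_mm,
            "km_se": res.km_se,
            "kcat_per_s": res.kcat,
            "kcat_over_km_per_M_s": res.kcat_over_km,
            "native_molar_mass_g_mol": res.native_molar_mass,
        }
        report["michaelis_menten"] = mm_report
        with open(outdir / "michaelis_menten.json", "w") as fh:
            json.dump(mm_report, fh, indent=2)

    if config.intact_peaks is not None:
        path = _require(config.intact_peaks, "intact-mass")
        peaks = intact.read_peaks_csv(path)
        if len(peaks) < 2:
            raise ValueError(f"{path}: need at least a reference and one treated peak")
        reference, treated = peaks[0], peaks[1:]
        intact_report = intact.shift_report(reference, treated)
        if len(peaks) == 2:
            intact_report["occupancy"] = intact.occupancy(
                peaks[0].intensity, peaks[1].intensity
            )
        report["intact"] = intact_report
        with open(outdir / "intact.json", "w") as fh:
            json.dump(intact_report, fh, indent=2)

    return report
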