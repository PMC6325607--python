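"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its config: the same config (seed
included) yields the identical output, so closed-loop tests — generate with
known truth, run the analysis, compare — are exactly reproducible.  The
spectra emulate centroided CID spectra of modified peptides (b/y ladder,
CoA remnant ions, precursor-minus-loss peaks, m/z jitter, uniform noise
peaks over the m/z 50-2000 acquisition window); the kinetics, titration
and initial-rate generators evaluate the corresponding closed-form models
with multiplicative or additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_MASS_TABLE, ResidueMassTable, mz as _mz
from .fragments import DEFAULT_RULES, CoAFragRules, MS2Spectrum, fragment_ladder
from .kinetics import ActivityTimeCourse
from .modifications import (
    CAM,
    COALATION,
    DEFAULT_CATALOG,
    ModifiedPeptideForm,
    PrecursorObservation,
    make_form,
)
from .proteins import PeptideSpan, ProteinRecord
from .titration import TitrationPoint

__all__ = [
    "SpectrumSynthConfig",
    "KineticsSynthConfig",
    "TitrationSynthConfig",
    "MMSynthConfig",
    "gen_ms2",
    "gen_timecourses",
    "gen_titration",
    "gen_mm",
    "table1_fixture",
    "write_fixture_dir",
]

#: MS2 acquisition window for noise peaks (m/z).
MS2_WINDOW = (50.0, 2000.0)


@dataclass(frozen=True)
class SpectrumSynthConfig:
    """Recipe for one synthetic CID spectrum of a modified peptidoform."""

    form: ModifiedPeptideForm
    precursor_charge: int = 2
    max_fragment_charge: int = 1
    include_losses: bool = True
    intensity_model: str = "uniform"  # "uniform" | "random"
    jitter_sd: float = 0.05  # Da
    n_noise_peaks: int = 30
    noise_ceiling: float = 0.2  # fraction of base peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.intensity_model not in ("uniform", "random"):
            raise ValueError("intensity model must be 'uniform' or 'random'")


def gen_ms2(
    config: SpectrumSynthConfig,
    rules: CoAFragRules = DEFAULT_RULES,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> MS2Spectrum:
    """Synthesise a centroided CID spectrum from a modified peptidoform.

    Signal peaks are the full theoretical b/y ladder (with CoA remnant
    variants when the form is CoAlated) and, when enabled and the form is
    CoAlated, the three precursor-minus-CoA-loss peaks at the precursor
    charge.  Every signal peak is jittered N(0, jitter_sd); noise peaks are
    uniform over m/z 50-2000 with intensity uniform below the configured
    ceiling.
    """
    rng = np.random.default_rng(config.seed)
    form = config.form
    ions = fragment_ladder(form, config.max_fragment_charge, rules, table)
    signal_mz = [ion.mz for ion in ions]

    base = 100.0
    if config.intensity_model == "uniform":
        intensities = [base] * len(signal_mz)
    else:
        intensities = list(rng.uniform(0.3 * base, base, size=len(signal_mz)))

    precursor_mz = _mz(form.neutral_mass, config.precursor_charge, table)
    if config.include_losses and form.coalated_positions:
        z = config.precursor_charge
        m_prec = form.neutral_mass
        for loss in rules.losses:
            signal_mz.append((m_prec - loss + z * table.proton) / z)
            intensities.append(0.8 * base)

    signal_mz = np.asarray(signal_mz, dtype=float)
    if config.jitter_sd > 0:
        signal_mz = signal_mz + rng.normal(0.0, config.jitter_sd, signal_mz.size)

    noise_mz = rng.uniform(*MS2_WINDOW, size=config.n_noise_peaks)
    noise_int = rng.uniform(0.0, config.noise_ceiling * base, size=config.n_noise_peaks)

    return MS2Spectrum(
        precursor_mz=precursor_mz,
        precursor_charge=config.precursor_charge,
        mz=np.concatenate([signal_mz, noise_mz]),
        intensity=np.concatenate([np.asarray(intensities), noise_int]),
        title=f"synthetic:{form.annotated_sequence()}",
    )


@dataclass(frozen=True)
class KineticsSynthConfig:
    """Recipe for a family of pseudo-first-order inactivation time courses.

    Defaults emulate the CoASSCoA inactivation series: k2 = 3.0 M-1 s-1
    over 250-1000 uM on a 0-20 min sampling grid.
    """

    k2: float = 3.0  # 1/(M s)
    concentrations: tuple[float, ...] = (250e-6, 500e-6, 750e-6, 1000e-6)  # M
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 1201, 60))  # s
    rel_noise_sd: float = 0.0
    seed: int = 0
    label: str = "CoASSCoA-like"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")


def gen_timecourses(config: KineticsSynthConfig) -> list[ActivityTimeCourse]:
    """A(t) = 100 exp(-k2 C t) (1 + eps), eps ~ N(0, rel_noise_sd), seeded.

    Noise is multiplicative Gaussian truncated at zero activity.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    courses = []
    for conc in config.concentrations:
        a = 100.0 * np.exp(-config.k2 * conc * t)
        if config.rel_noise_sd > 0:
            a = a * (1.0 + rng.normal(0.0, config.rel_noise_sd, t.size))
            a = np.clip(a, 0.0, None)
        courses.append(
            ActivityTimeCourse(
                condition=f"{config.label} {conc * 1e6:.0f} uM",
                concentration=float(conc),
                times=tuple(t),
                activities=tuple(float(x) for x in a),
            )
        )
    return courses


@dataclass(frozen=True)
class TitrationSynthConfig:
    """Recipe for a sigmoidal pH-activity titration (IAM protection assay)."""

    pka: float = 5.82
    top: float = 100.0
    bottom: float = 0.0
    ph_grid: tuple[float, ...] = tuple(
        float(x) for x in np.linspace(4.0, 9.0, 12)
    )
    noise_sd: float = 0.0  # percentage points, additive
    seed: int = 0

    def __post_init__(self) -> None:
        if not min(self.ph_grid) <= self.pka <= max(self.ph_grid):
            raise ValueError("pH grid must span the pKa")


def gen_titration(config: TitrationSynthConfig) -> list[TitrationPoint]:
    """Evaluate the single-site sigmoid plus additive Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    pts = []
    for ph in config.ph_grid:
        r = config.bottom + (config.top - config.bottom) / (
            1.0 + 10.0 ** (ph - config.pka)
        )
        if config.noise_sd > 0:
            r += rng.normal(0.0, config.noise_sd)
        pts.append(TitrationPoint(ph=float(ph), residual_pct=float(max(r, 0.0))))
    return pts


@dataclass(frozen=True)
class MMSynthConfig:
    """Recipe for a Michaelis-Menten initial-rate set (G3P-like defaults)."""

    vmax: float = 152.0  # U/mg
    km: float = 1.23  # mM
    substrate_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0)
    rel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not min(self.substrate_grid) <= self.km <= max(self.substrate_grid):
            raise ValueError("substrate grid must span Km")


def gen_mm(config: MMSynthConfig) -> pd.DataFrame:
    """Rates v = Vmax S/(Km + S) (1 + eps) on the substrate grid."""
    rng = np.random.default_rng(config.seed)
    s = np.asarray(config.substrate_grid, dtype=float)
    v = config.vmax * s / (config.km + s)
    if config.rel_noise_sd > 0:
        v = np.clip(v * (1.0 + rng.normal(0.0, config.rel_noise_sd, s.size)), 0.0, None)
    return pd.DataFrame({"substrate_mM": s, "rate_U_per_mg": v})


# ---------------------------------------------------------------------------
# the bundled identification fixture


#: The two cysteine-containing Lys-C peptides of the GAPDH subunit.
PEPTIDE_CYS149_153 = "YEGQDIVSNASCTTNCLAPLAK"  # spans 138-159
PEPTIDE_CYS288 = "GVLGYTEDDVVSTDFNGEVCTSVFDAK"  # spans 269-295

#: Observed precursor ions of the modified peptides (m/z, charge) as read
#: off the MS1 survey scans under oxidant stress.
OBSERVED_PRECURSORS = (
    (1040.765, 3),  # CoAlation + CAM
    (1148.556, 2),  # intramolecular disulphide
    (1202.076, 2),  # trioxidation + CAM
    (1206.580, 2),  # CAM + CAM
    (1213.596, 2),  # CAM + propionamide
    (1462.677, 2),  # Cys288 peptide, CAM
)


def _scaffold_protein() -> ProteinRecord:
    """Synthetic scaffold protein embedding the two diagnostic peptides.

    A stand-in for the full subunit sequence (which is user-supplied and
    never required here): alanine filler with lysines placed so that Lys-C
    digestion yields the two printed peptides at their literature
    coordinates 138-159 and 269-295, putting the cysteines at 149, 153
    and 288.
    """
    seq = ["A"] * 300
    seq[136] = "K"  # position 137 ends the upstream filler peptide
    seq[137:159] = list(PEPTIDE_CYS149_153)
    seq[267] = "K"  # position 268
    seq[268:295] = list(PEPTIDE_CYS288)
    return ProteinRecord(
        identifier="synthetic-gapdh-scaffold",
        description="synthetic scaffold embedding the Cys149/153 and Cys288 Lys-C peptides",
        sequence="".join(seq),
    )


def table1_fixture(seed: int = 0) -> dict:
    """The bundled identification fixture.

    Returns a dict with the scaffold protein, the two diagnostic peptide
    spans, the enumerated modified forms, the observed precursor list, and
    a synthetic CID spectrum of the CoAlated (CoA on Cys149, CAM on
    Cys153) form at charge 3+.
    """
    protein = _scaffold_protein()
    span1 = PeptideSpan(protein.identifier, 138, 159, PEPTIDE_CYS149_153, 0)
    span2 = PeptideSpan(protein.identifier, 269, 295, PEPTIDE_CYS288, 0)
    coalated = make_form(span1, {149: COALATION, 153: CAM})
    spectrum = gen_ms2(
        SpectrumSynthConfig(
            form=coalated,
            precursor_charge=3,
            include_losses=True,
            jitter_sd=0.02,
            n_noise_peaks=20,
            seed=seed,
        )
    )
    observations = [
        PrecursorObservation(mz=m, charge=z) for m, z in OBSERVED_PRECURSORS
    ]
    return {
        "protein": protein,
        "spans": (span1, span2),
        "coalated_form": coalated,
        "observations": observations,
        "spectrum": spectrum,
    }


def write_fixture_dir(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full synthetic input bundle (FASTA, MGF, CSVs) to a directory."""
    from .fragments import write_mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fix = table1_fixture(seed=seed)
    paths: dict[str, Path] = {}

    fasta = outdir / "protein.fasta"
    protein = fix["protein"]
    with open(fasta, "w") as fh:
        fh.write(f">{protein.identifier} {protein.description}\n")
        for i in range(0, len(protein.sequence), 60):
            fh.write(protein.sequence[i : i + 60] + "\n")
    paths["fasta"] = fasta

    mgfp = outdir / "spectra.mgf"
    write_mgf([fix["spectrum"]], mgfp)
    paths["mgf"] = mgfp

    obs = outdir / "precursors.csv"
    pd.DataFrame(
        [{"mz": o.mz, "charge": o.charge} for o in fix["observations"]]
    ).to_csv(obs, index=False)
    paths["precursors"] = obs

    kin = outdir / "timecourses.csv"
    rows = []
    for label, cfg in (
        ("CoASSCoA", KineticsSynthConfig(seed=seed, label="CoASSCoA-like")),
        (
            "GSSG",
            KineticsSynthConfig(
                k2=0.34,
                concentrations=(2.5e-3, 5.0e-3, 7.5e-3, 10e-3),
                seed=seed + 1,
                label="GSSG-like",
            ),
        ),
    ):
        for tc in gen_timecourses(cfg):
            for t, a in zip(tc.times, tc.activities):
                rows.append(
                    {
                        "condition": tc.condition,
                        "concentration_M": tc.concentration,
                        "time_s": t,
                        "activity_pct": a,
                    }
                )
    pd.DataFrame(rows).to_csv(kin, index=False)
    paths["timecourses"] = kin

    titr = outdir / "titration.csv"
    pts = gen_titration(TitrationSynthConfig(seed=seed))
    pd.DataFrame(
        [{"pH": p.ph, "activity_pct": p.residual_pct} for p in pts]
    ).to_csv(titr, index=False)
    paths["titration"] = titr

    mm = outdir / "initial_rates.csv"
    gen_mm(MMSynthConfig(seed=seed)).to_csv(mm, index=False)
    paths["initial_rates"] = mm

    intact = outdir / "intact_peaks.csv"
    pd.DataFrame(
        [
            {"mass": 35363.0, "intensity": 30.0, "label": "native"},
            {"mass": 36134.0, "intensity": 70.0, "label": "CoASSCoA-treated"},
        ]
    ).to_csv(intact, index=False)
    paths["intact"] = intact

    return paths
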