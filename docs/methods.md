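# Methods

## Mass calculus and digestion

Peptide masses are monoisotopic: the neutral mass is the sum of standard
IUPAC residue masses (5-decimal precision, hard-coded in `chem.py` and
cross-checked against pyteomics in the test suite), one water for the
termini, and any site deltas. Ions carry protons (1.007276 Da each). With
these constants the theoretical m/z of the reported modified peptides of
the GAPDH subunit land about +0.004 above the printed values at 2+; the
constants behind the printed column (proton vs hydrogen mass, rounding) are
not recoverable, so the offset is documented rather than calibrated away
and comparisons use a 0.005 absolute tolerance.

Lys-C digestion cleaves C-terminal of every lysine, including K-P bonds
(toggle `cleave_before_proline`), with up to a configurable number of
missed cleavages (default 1, matching the search settings of the
identification workflow). Residue numbering is 1-based from the first
residue of the supplied sequence; callers whose FASTA differs from
literature numbering can offset the span coordinates.

## Modification catalog and peptidoform enumeration

The default cysteine catalog is carbamidomethyl (+57.02146), propionamide
(+71.03711), trioxidation (+47.98474), dimedone (+138.06808), CoAlation
(+765.09956) and the pairwise intramolecular disulphide (−2.01565, applied
once per pair). Free cysteines are excluded from enumeration by default:
the sample-preparation workflows alkylate all free thiols with
iodoacetamide before digestion, so an unmodified cysteine is not an
expected state (flag `allow_unmodified_cys` reinstates it). Disulphides
pair cysteines of the same peptide only; cross-peptide links are out of
scope. At most one CoAlation per peptide by default (`max_coalations=None`
lifts the cap; the combinatorial count law s^c + C(c,2)·s^(c−2) holds with
the cap lifted).

Precursor matching emits every (form, observation, charge) combination
within the Da tolerance (default 0.5) and inside the MS1 survey window
(default m/z 1000–1600); when several forms tie for one observation all are
reported, ranked by |error| — the honest representation of an ambiguous
site, as for the in vivo CoAlated peptide where the modified cysteine
could not be assigned.

## CoA-diagnostic fragmentation

CID preferentially fragments the CoA moiety, so CoAlated precursors shed
neutral fragments of nominally 410, 428 and 508 Da while the complementary
remnant (+356, +338, +258 on the cysteine) rides on backbone ions; each
pair reconstructs the full ~765 Da delta to within the ambiguity of one
transferred hydrogen, which is why the H-shift loss variants 409/427/507
are accepted on equal footing and neither variant is privileged.
Loss/remnant matching uses nominal integer masses with a ±1.0 Da window;
backbone b/y ions use exact deltas at the workflow's stated 0.5 Da
tolerance. Neutral-loss product ions are searched at the precursor charge
and all lower charges (a conservative superset; the product charge state
is not determinable from the source spectra). A spectrum is flagged a
CoAlated candidate when at least `min_losses` (default 2) distinct loss
families match at ≥5% of the base peak; the two-loss default exists
because a dense b/y ladder can coincidentally fall inside a single ±1 Da
loss window.

Fragment ladders of disulphide-ringed forms suppress cleavage sites inside
the ring by default (the ring holds both halves together);
`emit_ring_ions=True` produces ring-opened ladders. Annotation is greedy
nearest-peak matching with each observed peak consumed at most once;
coverage is the fraction of distinct backbone cleavage positions matched.
Site localization scores each isobaric candidate by the intensity-weighted
count of matched site-determining ions (ions whose m/z differs between
candidates) — a transparent counting score, not a probabilistic
localization model, reflecting that the original identifications were by
manual inspection of annotated ladders. Equal top scores set an explicit
tie flag rather than picking a winner.

## Kinetics

Activity units follow the NADH assay: U = ΔA340/min /(ε·l)·V in µmol/min
with ε340 = 6220 M⁻¹cm⁻¹. Inactivation time courses are fitted as
A(t) = A0·exp(−k_obs·t) by nonlinear least squares on the linear scale
(log-linear regression is available but biases heteroscedastic
percent-scale noise); a non-decreasing course yields k_obs = 0 with a
warning. The second-stage regression of k_obs on concentration is forced
through the origin because reagent-free controls show no inactivation; an
intercept option exists for diagnostics. Half-times are reported both as
ln2/k_obs and by direct interpolation of the 50% crossing, since published
half-time tables are typically curve readings rather than fit outputs, and
the two conventions need not agree for biphasic decays.

Michaelis–Menten fits use nonlinear least squares with Km initialised at
the median substrate concentration. kcat is computed per native tetramer
(141 452 g/mol = 4 × 35 363) by default — the convention under which a
Vmax of 152 U/mg gives kcat ≈ 358 s⁻¹, mutually consistent with the
enzyme's reported turnover number — with a per-subunit mode available.

## Titration and thiol counting

The IAM-protection titration is fitted as a single-site descending sigmoid
in pH (Hill coefficient fixed at 1; a single ionizing thiol). The top
plateau is fixed at 100% by default because activities are normalised to
the no-IAM maximum; whether to fix it is genuinely open, so `fix_top=None`
frees it. Thiols per subunit come from Beer–Lambert with
ε412 = 14 150 M⁻¹cm⁻¹ and a 1 cm default path.

## Intact mass

Linear-MALDI readings of a ~35 kDa subunit are only accurate to a few Da,
so a shift is called CoAlation-consistent within ±10 Da of the exact
765.10 Da delta. Occupancy is modified/(modified+unmodified) peak
intensity; whether source figures used heights or areas is unknowable from
peak lists, so centroided intensities are taken as given. Peak-picking and
matrix-adduct deconvolution are out of scope.

## Synthetic data

Generators are pure functions of their config (seed included).
Spectra: the full theoretical ladder with remnant variants, the three
precursor-minus-loss peaks at the precursor charge for CoAlated forms,
Gaussian m/z jitter (default SD 0.05 Da, typical of ion-trap-TOF
centroids), and uniform noise peaks over the m/z 50–2000 acquisition
window. Kinetics: A(t) = 100·exp(−k2·C·t)·(1+ε) with multiplicative
Gaussian noise truncated at zero, on a 0–20 min grid at the four
concentrations used for each reagent series (250–1000 µM for the CoA
disulphide, 2.5–10 mM for glutathione disulphide). Titration: the sigmoid
on 12 pH points spanning 4–9 with additive noise in percentage points.
Initial rates: 8 substrate concentrations spanning 0.1–10 mM around Km.

What the generators do **not** emulate: isotope envelopes, chromatographic
co-elution, charge-state envelopes, real fragmentation efficiencies and
intensity structure, instrument drift, or biological replication scatter.
Passing closed-loop tests therefore demonstrates correctness of the
arithmetic, fitting and decision logic under the stated noise models —
not performance on real LC-MS/MS data, and the in vivo biology (which
peptides are CoAlated in stressed cells) is represented only by the
fixture-based identification workflow.

## Numerical choices and degenerate inputs

- Nearest-peak lookup is binary search with explicit tolerance; greedy
  annotation resolves collisions toward the more intense candidate.
- Zero-tolerance matching keeps exact equality only.
- Empty spectra annotate to coverage 0 without error; empty observation
  lists match to empty results; a cysteine-free peptide enumerates to an
  empty form list.
- Fits at zero noise recover generator truth to solver precision
  (relative 1e-6 or better); these exact-recovery identities are the
  regression tests for the fitting stack.
- Problem sizes throughout (21-point time courses, 12-point titrations,
  8-point rate curves, 100-seed Monte-Carlo checks) mirror desk-scale
  versions of the corresponding experiments and keep the whole suite
  under a minute.

## Known limitations

- No FDR/decoy control, retention-time modelling or quantification in the
  identification workflow; it is a targeted re-analysis tool, not a search
  engine.
- Localization scores are comparable only within one spectrum.
- The second-order model assumes strictly pseudo-first-order decay;
  biphasic inactivation shows up as disagreement between fitted and
  interpolated half-times rather than being modelled.
- Average-mass mode, isotope envelopes and other proteases are
  deliberately absent.
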