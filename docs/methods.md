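# Methods

## Scope and data model

The pipeline analyses a *study*: one or more chemicals tested on an
ascending dose ladder (µM, with dose 0 the vehicle control) across six
assays, each delivered as a tidy CSV table with units embedded in the
column names (`dose_uM`, `cell_area_um2`, `ocr_pmol_min`, `ecar_mph_min`).
All instrument-level processing (image segmentation, flow gating, band
quantification) is upstream: the pipeline consumes measurement tables, not
raw images, FCS files or blots.

## Dose-response engine

Every endpoint is reduced to a `DoseResponseSeries`: per-dose replicate
values plus the vehicle group.  Three stages:

1. **Trend.** A cubic smoothing spline is fitted to per-dose means over
   log₁₀(dose + pseudo-dose), with weights proportional to replicate counts
   and the penalty chosen by generalized cross-validation
   (`scipy.interpolate.make_smoothing_spline`).  The pseudo-dose is the
   lowest non-zero dose divided by 10, placing the vehicle one decade below
   the ladder.  Fewer than four distinct doses: no spline, per-dose means
   only.  The spline summarises the curve; the decision statistics below
   are pointwise, which matches how NOEL/LOELs are defined.

2. **Per-dose departure test.** For each non-zero dose, a two-sided
   bootstrap test of the mean departure from the vehicle.  The statistic is
   the Welch t; its null distribution is built by resampling, with
   replacement, the pooled within-group-centered residuals of the two
   groups (valid under the null that the groups share one distribution).
   p = (1 + #{|t*| ≥ |t|}) / (B + 1) with B = 2000 resamples by default, so
   the smallest attainable p is 1/(B+1).  Two numerical choices matter at
   the n = 3 replicate scale typical of these assays:

   * residuals are sorted before resampling, making every p-value invariant
     to replicate ordering;
   * a variance ridge equal to 1% of the pooled residual variance (scaled
     by 1/n₁ + 1/n₂) is added to the resampled standard error.  Without it,
     with-replacement draws occasionally produce near-identical residual
     sets whose t* explodes, corrupting the reference tail; with it,
     simulated type-I error is 6.0–6.5% at nominal 5% for n = 3–5 on both
     normal and binomial-count scales (measured by the calibration suite),
     and an arbitrarily separated pair of groups attains the minimal p.

   Bootstrap seeds derive from CRC32(chemical|endpoint) XOR the global
   seed — data-independent, so results are reproducible and order-invariant.
   Degenerate zero-variance comparisons are resolved exactly (p minimal or
   1).

3. **Decision rule.** LOEL = lowest dose with p ≤ α (default α = 0.05);
   NOEL = highest tested dose strictly below the LOEL.  No multiplicity
   correction is applied across doses or endpoints by default, matching the
   per-dose significance-star convention of this assay family; a Holm
   option exists (`holm=True`).  Consequently the familywise chance of at
   least one false LOEL on a k-dose inert ladder is ≈ 1 − (1 − α)ᵏ, not α —
   users who need familywise control should enable Holm.

## Cytotoxicity and the reference concentration

RPD = 100 · log₂(post_t/pre_t) / log₂(post_c/pre_c), replicate-paired with
the vehicle where labels match (mean vehicle doubling otherwise).  The
vehicle is pinned at 100%; a vehicle that fails to double is an error.  The
reference concentration for fold-change extraction is the dose where the
mean RPD curve crosses 50%, interpolated **linearly in log₁₀(dose)**
between the bracketing tested doses — log-linear matches the geometric
spacing of dose ladders; a `nearest` rule (lowest tested dose at ≤ 50%) is
available since either reading of "the concentration inducing a 50%
reduction" is defensible.  Curves that never reach 50% anchor at the top
tested dose.  Non-monotone curves crossing 50% more than once use the
lowest crossing, with a warning.

## Morphology quintiles

Thresholds are derived only from vehicle-control cells of the matching
stratum (vehicle × cell line × exposure duration).  Each control replicate
is subsampled without replacement (seeded per replicate label) to the
smallest replicate's cell count, so every culture day contributes equally;
the 20/40/60/80th percentiles of the pooled sample (linear interpolation
between order statistics) become the four cuts.  Classification intervals
are half-open and lower-closed — a cell exactly at a cut belongs to the
upper category; the convention is arbitrary but fixed and documented.
Occupancy of each category is computed per replicate and dose and handed to
the dose-response engine; the category-level significance count and the
median-area treated:control ratio both feed reporting, and the median ratio
is the morphology fold used in ISC scoring (an occupancy-based alternative
can be swapped in by scoring custom fold tables).  Extra shape measures
(perimeter, solidity, form factor) classify identically if supplied as
additional `<measure>_um2`-style columns but do not enter the score.

## Cell cycle

Gated events over {G1, S, G2} become percentages of the three-phase
simplex; an optional `other_events` gate (sub-G1/debris) is excluded.  Each
phase's percentage is dose-response tested; **G2 arrest** is flagged when a
significant G2 *increase* co-occurs with a significant *decrease* in G1 or
S.  A historical vehicle bank (per vehicle type) may stand in when no
concurrent dose-0 rows exist; concurrent controls take priority.

## Signalling and expression

Densitometry folds are lane-normalised (target/loading) and divided by the
mean vehicle ratio.  qRT-PCR uses the comparative-Cq method with
amplification efficiency fixed at 2 (configurable per call; efficiencies
are rarely reported for this assay family).  Before testing, log₂ folds are
**mean-centered per replicate** across each gene × chemical series —
centering removes additive separate-day batch offsets exactly, and the
calibration suite demonstrates strictly higher LOEL power with centering
than without under replicate offsets of 0.5 log₂ units.  Per-gene (rather
than per-replicate) centering variants exist in the literature; the
per-replicate form is implemented because the batch structure of these
studies is replicate = culture day.

## Bioenergetics

Basal OCR and ECAR folds are treated mean / vehicle mean per axis.  The
energy phenotype is a quadrant label — energetic (both up), quiescent (both
down), aerobic (OCR up, ECAR down), glycolytic (OCR down, ECAR up) — with a
±10% tolerance band around (1, 1) as the only route to "unchanged"; a fold
of exactly 1 on one axis counts as "up" (a measure-zero tie, fixed by
convention).  Profile clustering is agglomerative on z-scored axes, Ward
linkage and Euclidean distance by default (both configurable; the linkage
and metric used in the original SPSS analyses of such data are typically
unreported), with per-dose condition points rather than pooled per-chemical
points.  The composite-score flux slice is a single magnitude:
exp(mean(|ln OCR-fold|, |ln ECAR-fold|)), the geometric mean of
inversion-adjusted folds, ≥ 1 by construction; an OCR-only mode exists.

## ISC scoring

Twelve endpoint folds are extracted at the reference dose (log-dose linear
interpolation of the per-dose fold profile when the reference is not a
tested dose; clamped at the ladder ends).  Transform: invert folds < 1,
square-root everything except the two area endpoints, multiply by the
endpoint's scaling-group constant.  Weights follow the equal-technique
rule: weight(e) = (max endpoint count over techniques) / (endpoint count of
e's technique), giving 3 / 1.5 / 1 on the standard panel and equal
per-technique totals of 3.  The score is the weighted sum of (scaled) slice
values; with all folds at 1 it equals the panel-wide baseline constant
Σwₑ·scale = 18 at unit scales.  Display scales default to 1 for all three
groups ({MN, seahorse}, {areas, westerns}, {genes, phases}) — the grouping
only matters when users set non-unit scales for slice visualisation, and a
common multiplier across all groups provably preserves ranking.  Missing
endpoints enter at fold 1 with a `missing` flag and a warning, so absence
can never raise a score.  Ranks are dense, descending, ties broken
lexicographically.  The radial profile rendering draws slice radius
proportional to slice value and angular width proportional to weight, with
dashed one-fold baseline circles per scaling group.

## Synthetic studies

The generator emulates the statistical structure each stage assumes:

| table | model |
|---|---|
| CBMN | binomial MN counts, p from a Hill curve (baseline 0.8%), over 9000 binucleates/replicate; cell counts give RPD = 50% at the archetype's cytotoxic EC50 |
| morphology | lognormal cell (median 180 µm², σ 0.35) and nuclear (90 µm², σ 0.30) areas; treatment shifts the log-location by a Hill term; nuclear < cell enforced by resampling |
| cell cycle | Dirichlet-multinomial over {G1 55%, S 25%, G2 20%}, concentration 300, 36 000 events per dose across 3 replicates; arrest raises G2 with proportional G1/S depletion |
| qRT-PCR | reference Cq 18, baseline ΔCq 6, target Cq shifted by −log₂(fold); well noise σ 0.15 Cq plus replicate-day ΔCq offsets σ 0.3 |
| densitometry | loading ≈ 1000 AU, target = loading × fold, multiplicative lognormal noise at the replicate CV |
| flux | control centroid (459 pmol O₂/min, 30 mpH/min) scaled by Hill fold curves per axis, lognormal noise |

Effect curves are four-parameter Hill functions — the simplest monotone
saturating family; an optional negative second Hill term supports biphasic
responses (off by default).  One global seed expands into fixed-offset
child seeds per table and chemical, so any table regenerates independently
and identically.  The default dose ladder is half-decade spaced, 0–100 µM,
with three replicates.  Within-replicate variance components are rarely
published for these assays; the defaults above (replicate CV 5%, Cq σ 0.15,
batch ΔCq σ 0.3) are plausible bench values stated here as configuration,
not as estimates of any particular study.

The default eight-archetype panel pairs four GC-like fingerprints (MN
induction 2.5–4.5% max, G2 arrest, p53/p21 activation, nuclear-area
increase — plus one oxidant-like profile with area *decrease* and
glycolytic flux) against four NGC-like fingerprints (flat MN, moderate
expression changes, cell-area reduction, quiescent flux; one metal-like
profile keeps G2 arrest and mild p53 without MN, and one carbamate-like
profile never reaches 50% cytotoxicity).

**What passing tests do and do not show.**  The generator reproduces the
support, dispersion family and dose-shapes the analysis assumes — it cannot
certify behaviour on real data with non-Hill kinetics, correlated endpoint
noise, plate/edge effects, segmentation artifacts or heteroscedastic Cq
noise.  Parameter-recovery and separation results on synthetic panels are
internal-consistency evidence, not external validation.

## Problem sizes used in the test suite

Simulation-based tests use 2000 series for type-I calibration, 999
bootstrap resamples inside simulations (2000 in production defaults),
25–200 repeated runs for recovery checks, and 100 seeded studies for the
panel-separation check, with 900 imaged cells per condition in generated
morphology tables.  These sizes give Monte-Carlo error comfortably inside
the asserted tolerances.

## Known limitations

* The departure test is mildly anti-conservative (≈ 6–6.5% at nominal 5%)
  at n = 3; exact small-sample calibration is impossible for a
  nonparametric test at that replicate count.
* No benchmark-dose (BMD) modelling, no Bayesian dose-response, no
  multiplicity correction by default.
* ISC display-scale constants are user configuration; published composite
  scores from other implementations are reproducible only up to the
  (generally unpublished) scale grouping, so cross-study score values
  should be compared by rank, not magnitude.
* Classification of carcinogen class from an ISC cut-off is deliberately
  not built in; only a user-supplied threshold can be applied downstream.
* RICC/RCC cytotoxicity indices, FCS parsing, image segmentation and
  microarray normalisation are out of scope.
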