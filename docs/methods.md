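# Methods

## Particle size spectra

Diameters (mm) are binned into log10 size classes whose edges sit at
`10^(k·w)` for integer `k` and width `w = 0.1` by default. Anchoring edges
at integer multiples of `w` makes the binning data-independent and
reproducible; a diameter on an edge belongs to the bin it closes (bins are
half-open `(lower, upper]`, labelled by the upper edge). The spectrum
ordinate is `A_n = count / (upper − lower)` in mm⁻¹, so that a power-law
number density `f(d) ∝ d^−ξ` appears as a straight line of slope −ξ in
log-log coordinates regardless of bin layout.

**Exponent fit.** The fit uses all bins whose upper edge exceeds
`fit_min_mm` (default 3 mm; below that, surface trawls undersample small
fragments and the spectrum flattens), with the geometric bin midpoint as
abscissa. Two methods are provided:

* `method="poisson"` (default): Poisson regression of the bin **counts**
  on log diameter with a log-bin-width offset. This is the likelihood
  appropriate to binned counts; it uses empty bins, and it is unbiased
  where least squares on log-transformed occupied bins is not. With
  ξ = 3 on 0.3–30 mm, only ~1% of particles exceed 3 mm, so tail bins
  have expected counts below 1; conditioning on occupancy then inflates
  `log A_n` in exactly those bins and drags a log-log OLS slope toward
  shallower values (measured bias ≈ −0.33 at n = 5,000). The Poisson fit
  removes this bias (mean recovered ξ ≈ 2.96–3.0 at the same n) and
  coincides with OLS exactly on noiseless spectra.
* `method="ols"`: the classic unweighted least squares of `log10(A_n)` on
  `log10(midpoint)` over occupied bins, kept for comparability with the
  conventional presentation of size spectra. Prefer it only when all
  fitted bins are well populated.

`r_squared` is reported as the squared correlation between observed and
fitted `log10(A_n)` over occupied fitted bins for either method. Fits
require at least two occupied qualifying bins.

Concentration conversions are exact arithmetic: fragments/m³ =
count / volume filtered; fragments/km² = fragments/m³ × layer depth (m)
× 10⁶, with the neuston layer defaulting to the 0.15 m sampled by a
standard manta-trawl mouth.

## Bottle metabolism

Rates are two-point differences over the incubation — no time-course model
is fitted. With per-treatment means of replicate bottles and duration Δt
(default 24 h):

    NCP = (mean(light) − mean(t0)) · 24/Δt
    R   = (mean(t0) − mean(dark)) · 24/Δt
    GPP = NCP + R

GPP is stored as the derived sum, never independently, so the identity is
bit-exact through background subtraction and unit scaling. Standard errors
propagate within-treatment variances of the two means entering each rate;
the GPP standard error treats NCP and R as independent (conservative,
since they share the t0 mean). Negative rates are reported as-is.

Plastic-amended bottles are displacement-adjusted before rate computation:
total O₂ (µmol) = concentration × (bottle volume − particle volume), the
identity operation when no particle is present. Per-particle rates assume
one particle per amended bottle (the standard incubation design) and
subtract the mean unamended seawater bottle rate.

Chlorophyll: areal density = Chl mass / particle surface area (mg/m²);
sphere area π·d²; the seawater-equivalence volume is
`chl_areal × area / chl_water`, converted m³ → mL. The exact station
pairings behind any published equivalence range are not recoverable from
summary tables, so the package exposes the calculation and the tests check
order-of-magnitude envelopes over the observed Chl ranges.

Group tests: Kruskal–Wallis omnibus across size classes with a hand-rolled
Dunn post-hoc z-test (joint mid-ranks, tie-corrected variance,
Benjamini–Hochberg adjustment at 0.05) — no pre-installed package provides
Dunn's test. Two-group comparisons use Mann–Whitney (exact enumeration for
tie-free samples of ≤ 8 per group, tie-corrected normal approximation
otherwise; all-tied data returns p = 1 rather than an error) or one-way
ANOVA. Both are type-I calibrated in the test suite by null simulation.

## LCA taxonomic profiling

Reference curation comes first: hits to blacklisted (e.g. chimera-flagged)
accessions are removed, as are hits overlapping any masked contaminant
interval. Intervals are 1-based inclusive, matching tabular aligner
output; *any* overlap removes the hit, and reversed (minus-strand) subject
coordinates are normalized before the check.

Retention, per read: alignment length ≥ 100 bp, bit score ≥ 50, and bit
score ≥ (1 − 0.01) × best, where "best" is the maximum over
floor-qualifying hits and the boundary is inclusive. The rule is
order-invariant and idempotent, and always keeps the best qualifying hit.

The assignment is the longest common rank-prefix (domain → genus) of the
retained lineages. Disjoint prefixes yield an "unclassified root" read;
these are kept in totals under the total-reads denominator and dropped
under rank-assigned denominators. The top retained hit's percent identity
is carried per read so per-clade mean identities can be reported.

Abundance tables record their denominator explicitly — `rank_assigned`
(default), `domain`, or `total` — because different summaries legitimately
use different baselines. Proportions are rounded half-away-from-zero to a
configurable number of decimals (thousandths for eukaryote tables,
hundredths for bacterial ones in the intended workflow); rounding to
`k` decimals equalizes resolution across libraries like rarefying to
~10^k reads, deterministically. Half-away-from-zero is chosen over
banker's rounding so results are bit-reproducible and match everyday
expectation; the resolution is stored on the table.

Ordination: square-root transform, Bray–Curtis dissimilarity (scipy), and
non-metric MDS (scikit-learn) in 2 dimensions with a fixed seed, 8 random
restarts, and the normalized (Kruskal stress-1) stress reported. Identical
samples get distance 0; a pair of all-zero samples is defined as distance
0 rather than NaN.

Family richness counts clades with (rounded) proportion above a threshold
(default 1%); two-group comparisons use Welch's t-test with a 95% CI.
Per-clade group tests are two-sided Mann–Whitney on rounded proportions
with BH control, flagging at adjusted p < 0.005; clades constant across
all samples are assigned p = 1 and never flagged.

## KO functional comparison

Bacterial-origin screening requires *all* best-scoring hits of a read
(alignment ≥ 50 aa) to be bacterial — a single tied non-bacterial hit
excludes the read. KO assignment consults only the top-scoring hit: if it
lacks a KO annotation the read is unassigned even when lower hits are
annotated; an exact score tie between conflicting KOs breaks to the
lexicographically lowest KO id with a warning (deterministic, arbitrary).

Counts become per-sample proportions of KO-assigned reads, rounded to 5
decimals by default. Differential abundance is per-KO two-sided
Mann–Whitney (vectorized, tie-corrected normal approximation — rounded
proportions always carry ties, so the exact distribution is unavailable
anyway) with BH control across all tested KOs; KOs absent everywhere are
excluded. The fold-change estimator is `log2((mean_A + c)/(mean_B + c))`
with pseudocount `c` = half the smallest nonzero rounded proportion in the
table, applied symmetrically so the flags are antisymmetric under group
swap. Enrichment requires both adjusted p < 0.005 and |log2FC| > 2.

A negative-binomial GLM per feature is deliberately not implemented; the
rank-based path is the primary test, and `ko_diff_test(test=...)` accepts
an external per-feature test callable for users who want to plug one in.

## Synthetic data

The generators' defaults are the study conditions the rest of the package
is validated under:

* **Diameters** — bounded power law, ξ = 3 on 0.3–30 mm, n = 5,000, via
  inverse-CDF sampling (log-uniform closed form at ξ = 1). The analytic
  CDF ships alongside as the oracle.
* **Bottles** — NCP 10, R 5 µmol O₂ L⁻¹ day⁻¹ around a 210 µmol/L
  baseline (typical near-surface open-ocean O₂ saturation), 8 bottles per
  treatment, Gaussian noise sd 1 µmol/L, 24 h. Negative concentrations are
  clipped at 0 with a warning.
* **Hit tables** — each read hits its true subject at the best score;
  confounder subjects (the true lineage mutated at a chosen rank) are
  placed *by construction* half a window inside, or two windows outside,
  the 1% retention window, so the window boundary is exercised
  deterministically rather than by chance, and the truthful LCA rank is
  known per read (30%/30%/40% in/out/none by default).
* **KO tables** — 2,000 KOs across 12 vs 17 samples at ~216,000 reads per
  library (±10% depth jitter), log-normal baseline abundances,
  negative-binomial noise with dispersion α = 0.1 (variance µ + αµ²,
  Poisson in the α → 0 limit), and 10% of KOs planted at log2FC = 4 in the
  first group.

Each generator draws from its own stream split off the master seed, so
outputs are byte-identical per seed and adding a generator never perturbs
the others.

What the synthetic data does **not** emulate: real reference databases
(taxon richness, uneven lineage depth, annotation error), sequence-level
artifacts (chimeras, low-complexity masking — the pipeline consumes hit
tables downstream of alignment and QC), correlated noise across KOs,
compositional coupling between planted and background features, and
spatial/station structure in particles or bottles. Passing tests therefore
demonstrate the correctness and calibration of the computations under
their stated models, not robustness to every pathology of field data.

## Numerical choices and edge cases

* Diameters exactly on a bin edge join the bin they close; floating-point
  edge comparisons use a relative tolerance before `ceil`.
* `retain_hits` on an empty or fully-floored hit set returns empty; the
  read is reported as unclassified rather than raising.
* Rounding is half-away-from-zero everywhere a decimal resolution is
  applied.
* Mann–Whitney with all observations tied returns p = 1.
* NMDS distances of duplicate (including all-zero) samples are 0.
* The Poisson spectrum fit runs IRLS to tolerance 1e-12, making the
  noiseless fit exact to machine precision.

## Problem sizes

The validation suite simulates at n = 5,000 particles × 20 seeds for
exponent recovery, 100 seeds of 24-bottle incubations for rate recovery,
hundreds of reads per sample for LCA truth checks, and 2,000-KO tables
over 50 null seeds plus 10 planted-effect seeds for calibration and
sensitivity — sizes chosen to make sampling error small relative to the
tolerances being checked while keeping the full suite fast on a laptop.

## Known limitations

* The LCA operates on a fixed six-rank ladder (domain → genus); ragged
  lineages are supported but ranks are positional, not named per node.
* Per-particle rate normalization assumes one particle per amended bottle;
  surface-area normalization of rates must be done by the caller from the
  particle table.
* The bacterial read filter trusts the subject domain labels it is given.
* `enrichment_summary` percentages are integer-rounded for display only;
  use the underlying counts for arithmetic.
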