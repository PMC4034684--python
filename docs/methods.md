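# Methods

## Effect-size model

One observation is one study × element contrast: the relative change
`(E − A)/A` of a mean element concentration between ambient and elevated
CO₂, with its replicate count n. The analysis metric is the log response
ratio `x = ln(1 + (E − A)/A) = ln(E/A)`. The log scale treats a halving
and a doubling symmetrically; a raw percent scale is bounded below at
−100% but unbounded above and biases pooled means toward increases. All
pooling, interval construction and testing happen on the log scale;
percent changes are produced only at the reporting boundary via
`100·(eˣ − 1)`.

Records with `relative_change ≤ −1` are physically impossible
(a concentration cannot lose 100% or more) and are rejected at load
time with row-indexed diagnostics, as are records violating CO₂
ordering, replicate positivity, coordinate ranges, unknown element
symbols, or a paired-concentration cross-check
(`|relative_change − (E−A)/A| ≥ 1e−6`).

## Pooling and confidence intervals

The pooled mean is fixed-effect in spirit: no between-study variance
component is modelled, matching the flat structure of the data the
pipeline targets (most primary studies report no variance measure, so
inverse-variance weighting is off the table). Two weighting schemes are
always computable so callers can compare them:

- unweighted: arithmetic mean, `SE = sd/√m`;
- replicate-weighted: `Σnᵢxᵢ/Σnᵢ`, with the normalized
  reliability-weights SE: for `wᵢ = nᵢ/Σn`,
  `s²_w = Σwᵢ(xᵢ − x̄_w)² / (1 − Σwᵢ²)` and `SE = s_w·√(Σwᵢ²)`.
  The weighted SE construction is this package's documented choice; the
  two weighting routes agree closely on realistic data and exactly when
  all n are equal.

Intervals come from two routes:

- **t interval**: `x̄ ± t₍α/2,m−1₎·SE`, p-value from the two-sided
  one-sample t test of mean 0; requires m ≥ 2.
- **percentile bootstrap**: B = 10,000 resamples with replacement of
  the m log effects (B is configurable; below 100 a contract warning is
  emitted), CI = the α/2 and 1−α/2 empirical quantiles of the resampled
  means. The bootstrap p-value is the smallest two-sided level at which
  the percentile interval excludes zero, reported on the 1/B grid
  (`p = max(2·min(P*(x̄* ≤ 0), P*(x̄* ≥ 0)), 1/B)`). The percentile
  variant (rather than BCa) was chosen as the simplest consistent
  construction; the choice is isolated behind `ci_method`. A
  zero-variance slice collapses the interval to the point estimate and
  is flagged `degenerate`.

All resampling uses `numpy.random.Generator`; the same seed and inputs
give byte-identical summaries.

## Post-hoc power

Power is evaluated for a fixed absolute effect of 0.05 (a 5%
concentration change, taken on the effect-size scale rather than as
ln 0.95 ≈ −0.0513; the difference is under 3% relative) at α = 0.05.

**Analytic route.** Cohen's `d = effect/SD`; one-sample:
noncentrality `d√m`, df `m − 1`; two-sample equal groups: `d√(n/2)`,
df `2n − 2`. Two-sided power sums both rejection tails of the
noncentral t. Deep in the tails scipy's noncentral-t CDF can return
NaN; the shifted-normal CDF is substituted there, where it is exact to
double precision. At `d = 0` power equals α for every convention
(verified in tests). The two-sample two-sided convention is the
default, as the natural reading of replicated two-treatment CO₂
experiments; for d = 0.2 and 3–5 replicates per group it yields powers
0.054–0.059, under the 0.10 ceiling that defines the low-power regime.

**SD floor.** For slices with m < 20 mean observations the SD entering
d is `max(sample SD, 0.21)`, 0.21 being the dataset-wide SD of mineral
log effects. A small slice whose sample SD happens to be far below the
population value would otherwise overstate d and its power.

**Bootstrap route.** The non-parametric power mirrors the bootstrap
test actually used for inference: the observed effects are re-centred
to mean = 0.05 (when the floor applies, residuals are first rescaled so
their SD equals 0.21); each of B_outer Monte-Carlo replicates resamples
m values with replacement and rejects if the inner percentile-bootstrap
CI (B_inner resamples) excludes zero; power is the rejection fraction.
The re-centring construction is this package's concrete choice for a
procedure that is usually left unstated. Defaults B_outer = 500,
B_inner = 999 put the Monte-Carlo SE of a mid-range power near 0.02.
Zero-variance inputs short-circuit to power 1 (non-zero alternative) or
α, flagged `degenerate`. Reported slice power uses this bootstrap route
(one-sample convention, since a slice is a set of study-level effects);
it agrees with the noncentral-t answer within ~0.03 at m ≥ 100.

## Fragmentation and the power gate

Slicing dimensions: element, tissue (foliar/edible), plant group
(woody/herbaceous, wild/crop, C₃/C₄), experiment type (FACE vs
enclosures), crop name (cultivars mapped to a common-name registry,
e.g. every *Oryza sativa* cultivar → "rice"), country, latitude region,
and the "ionome" aggregate (every element except C and N; "mineral"
means element ∉ {C, H, O, N}). Conventions baked into slicing: C₄
records are excluded everywhere except an explicit C₄ slice;
geographic slices keep only FACE and OTC facilities (open-air designs
reflect local environment; closed chambers do not); crop/country/region
slices pool minerals only. The latitude boundary is 35° N/S, inclusive
on the tropical/subtropical side (the inclusive convention is fixed
here and unit-tested; the underlying convention is not stated more
precisely than "between 35 N and S").

The power gate partitions summaries at power > 0.40 (strict). It
affects headline reporting only: excluded summaries remain in the full
export, so no estimate is suppressed, and gating never feeds back into
estimation.

## Funnel diagnostics

The funnel plots each study × mineral log effect against its replicate
count for C₃ plants, with the unweighted grand mean as the reference
line (internally identical to `pooled_mean`; also reported
back-transformed). Because per-study variances are largely unavailable,
the x-axis is n rather than 1/SE. The original assessment of such
funnels is visual; the quantitative supplements here are labelled as
additions: a two-sided sign test on the above/below counts, and a
Kendall rank correlation between the standardized deviations
`(x − x̄)·√n` and `1/n`. Standardizing removes the funnel's own
spread-vs-n dependence, so a symmetric funnel gives τ ≈ 0 while
small-study effects (small-n results selectively missing on one side)
push τ away from zero. Both diagnostics need ≥ 10 points; below that
only counts are reported. The whole construction is invariant under
adding a constant to every effect.

## Stoichiometric calculus

If X rises x% while Y falls y% (both signed), X:Y changes by
`(x + y)/(100 − y)·100` %, identically
`100·((1 + x/100)/(1 − y/100) − 1)`. One signed formula serves
increases and decreases; the canonical orientation is numerator up,
denominator down. The TNC-dilution model: adding `a` g of
non-structural carbohydrates to 100 g dry mass with baseline TNC at T%
changes any unchanged component by `−a/(100+a)·100` %, TNC by
`a(100−T)/(T(100+a))·100` %, and every TNC:X ratio by exactly
`a/T·100` %. The model conserves mass (component grams times total mass
recover the gram ledger — property-tested) and is consistent with the
ratio formula (feeding the TNC and protein concentration changes
through it reproduces `a/T` exactly).

With the standard spoonful scenario (a = 5): grains/tubers at T = 65
give TNC +2.6%, TNC:protein +7.7%, protein/minerals −4.8%; foliar
tissue at T = 15 gives TNC +27%, TNC:protein +33%, minerals −4.8%.
Known discrepancy: the widely printed grains TNC:protein entry of 7
conflicts with the stated formulas, which give 5/65·100 = 7.69; this
package reports 7.7 and documents rather than matches the rounder
value. Report-table rounding elsewhere follows the printed granularity
(integers for foliar ratio entries, one decimal for concentrations).

The compensation helper inverts a dilution: a d% nutrient dilution
requires `100·(1/(1 − d/100) − 1)` % more intake (5% → 5.26%, since
1.0526 × 0.95 ≈ 1).

## Data-inclusion rules

For studies contributing multiple co-dependent datasets, per
study × species/cultivar × element group: (1) keep the lowest-ambient /
highest-elevated CO₂ arm; (2) foliar: drop arms with environmental
cofactors (ozone etc.), keeping the CO₂-only contrast — edible-tissue
cofactor arms are retained because edible data are scarce; (3) keep the
highest nutrient regime when no control is identifiable; (4) keep the
last time point; (5) keep the most mature foliage; (6) if three or more
separate datasets still remain for one species/cultivar, average them
unweighted into a single record, with the replicate count the rounded
mean (the averaging convention for n is this package's choice). Exactly
two surviving records are both kept. A group mixing annotated and
unannotated records for a needed field raises an unresolved-group error
naming the field. The rules are idempotent and the resolved dataset is
unique per study × element × tissue.

## Synthetic generator

The generator emulates the compiled dataset's statistical skeleton:
per study × element one log effect drawn from Normal(μₑ, σ) with
defaults μ = ln 0.92 for minerals (an ~8% decline), ln 0.85 for N,
ln 1.06 for C, 0 for Mn, and σ = 0.21 — the dataset-wide SD, used for
every element because per-element SDs are not separately established;
replicate counts uniform on 3–48 (48 being the largest count on
record); category mixes of roughly 60/40 foliar/edible, 25% FACE, 96/4
C₃/C₄, 60/40 crop/wild, 70/30 temperate/tropical; CO₂ pairs centred on
368 ppm ambient with elevated ~715 ppm for enclosures and ~560 ppm for
FACE (free-air enrichment is costlier, so its contrast is smaller).
Species/country metadata come from small realistic pools so every
generated dataset passes schema validation.

What the generator does **not** emulate: between-study heterogeneity
beyond the single σ (no hierarchical variance components — the target
analysis models none), inter-laboratory measurement bias structure,
correlation between elements within a study, unequal element coverage
across studies, or missing-data patterns. Passing recovery tests
therefore demonstrate that the pipeline is consistent and calibrated
under its own assumptions, not that real compiled data satisfy those
assumptions.

The recovery harness repeats generate → slice → summarize, reporting
per-element bias of the back-transformed mean, 95% CI coverage of the
truth, and power-gate behaviour next to the analytic power. At the
reference condition (true −8%, σ = 0.21, m = 140, 100 repetitions) mean
bias is well under 0.5 percentage points and bootstrap CI coverage sits
in [0.90, 0.99].

## Problem sizes and numerical choices

Default bootstrap B = 10,000 for analysis runs. The test suite and the
recovery experiment use reduced resampling (B = 400–2,000,
B_outer = 30–200) — sizes chosen so Monte-Carlo error stays an order of
magnitude below the tolerances being asserted while the suite stays
quick; tolerance bands in tests are 3-σ binomial or 3-MC-SE
constructions, not tuned margins. Quantiles are numpy's default linear
interpolation. Ties in the inclusion rules (e.g. identical CO₂ levels)
keep all tied records. Seeds: every stochastic entry point takes either
an integer seed or a `numpy.random.Generator`; derived seeds are drawn
below 2³¹.

## Known limitations

- Fixed-effect pooling only; no τ² estimation or random-effects model,
  by design fidelity to the flat replicate-weighted/unweighted analysis
  it implements.
- No inverse-variance weighting (primary-study variances mostly
  unreported).
- The bootstrap p-value resolution is 1/B; tiny p-values saturate at
  that floor.
- `validate_against_printed_counts` is meaningful only for the real
  compiled deposit (Dryad 10.5061/dryad.6356f); on synthetic data every
  line is flagged not-applicable. The optional fetch helper is never
  exercised by the test suite, which is fully download-free.
- The funnel diagnostics quantify asymmetry but implement no
  correction (no trim-and-fill, no fail-safe N).
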