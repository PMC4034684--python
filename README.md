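# ionomeshift

Meta-analysis toolkit for detecting small, systemic shifts in the plant
ionome — the mineral and trace-element composition of plant tissues —
under elevated atmospheric CO₂, for ecologists, agronomists and
nutrition researchers working with compiled CO₂-experiment data.

## The problem

Elevated CO₂ (eCO₂) stimulates carbohydrate synthesis in C₃ plants and
tends to dilute everything else: nitrogen, protein, and — the contested
part — minerals such as Fe, Zn, Ca and Mg. The per-experiment signal is
small (~5–10%) against noisy concentration data with 3–5 replicates, so
individual studies and under-powered meta-analytic slices routinely
return null or contradictory results. Detecting the shift is a
statistical-power problem, and this package implements the full
power-aware pipeline:

- **Effect sizes.** Each observation is the relative change
  `(E − A)/A` in a mean element concentration between ambient (`A`) and
  elevated (`E`) CO₂; it is analysed as the log response ratio
  `ln r`, `r = E/A = 1 + (E − A)/A`, which treats declines and increases
  symmetrically. Results are back-transformed to percent,
  `100·(e^x̄ − 1)`, only for reporting.
- **Pooling and intervals.** Unweighted and replicate-weighted means of
  the log effects, with both a parametric one-sample *t* interval and a
  percentile bootstrap (10,000 resamples by default, seeded).
- **Post-hoc power.** Analytic power via the noncentral *t*
  distribution (`ncp = d√m` one-sample, `d√(n/2)` two-sample,
  `d = effect/SD`), a conservative SD floor of 0.21 for slices with
  m < 20 mean observations, and a bootstrap Monte-Carlo power that
  mirrors the bootstrap CI test.
- **Power-gated fragmentation.** Slices by element, tissue, plant
  group, experiment type (FACE vs enclosure), crop, country and
  latitude band (35° N/S boundary); only slices with power > 0.40 for a
  5% effect are headline-reported, while all summaries stay in the full
  export.
- **Publication-bias diagnostics.** The funnel of effect sizes against
  replicate counts, its mean line, and quantitative supplements (sign
  test, Begg-style rank correlation of standardized deviations vs 1/n).
- **Stoichiometric calculus.** If X rises x% while Y falls y%, X:Y
  rises by `(x + y)/(100 − y)·100` % — exact ratio arithmetic for C:N,
  N:P, TNC:protein and the "spoonful of sugars" dilution model (adding
  `a` g of non-structural carbohydrates per 100 g dry mass dilutes every
  other component by `a/(100+a)` and raises every TNC:X ratio by `a/T`).
- **Synthetic data.** A seeded generator with the statistical structure
  the analysis assumes (per-element true log effects, SD 0.21,
  replicates 3–48, realistic category mixes), so the entire pipeline is
  testable end-to-end without any download, including parameter-recovery
  experiments.

## Worked example

```python
import math
from ionomeshift import (SyntheticConfig, generate, slice_effects, CategoryKey,
                         summarize_category, ratio_change, compensation_intake,
                         analytic_power, PowerSpec)

data = generate(SyntheticConfig(studies=120, seed=1))   # synthetic compilation
effs = slice_effects(data, CategoryKey("ionome"))       # all minerals, C3 only
s = summarize_category(effs, seed=1, label="ionome")
print(f"ionome: {s.mean_pct_change:.1f}% (95% CI {s.ci_low:.1f} to {s.ci_high:.1f}), "
      f"m={s.m}, n_total={s.n_total}, power={s.power:.2f}, p={s.p_value:.5f}")

zn = summarize_category(slice_effects(data, CategoryKey("element", "Zn")), seed=1)
print(f"Zn:     {zn.mean_pct_change:.1f}% (95% CI {zn.ci_low:.1f} to {zn.ci_high:.1f}), "
      f"m={zn.m}, power={zn.power:.2f}")

print(f"C:N shift for C +6%, N -15%: {ratio_change(x=6, y=15):.1f}%")
print(f"intake compensating a 5% dilution: {compensation_intake(5):.2f}%")
p = analytic_power(PowerSpec(effect=0.05, sd=0.25, sample_size=4, test="two_sample_t"))
print(f"power of a typical 4-replicate CO2 experiment for a 5% effect: {p.power:.3f}")
```

prints

```
ionome: -7.5% (95% CI -8.7 to -6.3), m=1062, n_total=28674, power=1.00, p=0.00010
Zn:     -9.9% (95% CI -13.5 to -6.0), m=118, power=0.67
C:N shift for C +6%, N -15%: 24.7%
intake compensating a 5% dilution: 5.26%
power of a typical 4-replicate CO2 experiment for a 5% effect: 0.057
```

The synthetic ionome (true mean −8%, SD 0.21 on the log scale) is
recovered as −7.5% with a tight bootstrap CI and saturated power; a
single element at m = 118 is noisier but still well-powered. The last
line is the heart of the power-failure story: a typical 4-replicate
experiment has under 6% probability of detecting a genuine 5% decline,
so single-study nulls say almost nothing.

The same pipeline runs from the shell — `ionomeshift simulate`,
`analyze`, `power`, `funnel`, `stoich`, `validate` — and
`ionomeshift analyze --input your.csv --by element --by tissue` writes
the full report bundle (category summaries, power surface, funnel points
and diagnostics, run log with seed and dataset checksum). Data compiled
from real experiments load through `read_dataset` (canonical CSV schema,
optional column mapping) with `apply_inclusion_rules` resolving
co-dependent arms (extreme CO₂ levels, cofactors, time series, leaf age,
≥3-dataset averaging) and `validate_against_printed_counts` checking a
loaded deposit against its published summary.

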