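# Methods

## Model and procedure

`pathdiffcorr` treats a two-condition expression study as a collection of
probe pairs, each observed as paired log2 intensities across the samples
of one condition. Co-expression is modelled by Pearson's product-moment
correlation r; condition-specific regulation by the difference
cor_dif = r_ref − r_test between the two conditions' correlations of the
same pair. Pairs are drawn from pathway structure (KEGG KGML relations),
not from the all-against-all pair space, which both restricts the
hypothesis space to biologically interpretable edges and keeps the
computation tractable.

The per-pair procedure in one condition:

1. Samples missing either value are removed pairwise; the remaining count
   is n_total. Below `min_samples` (default 10) the pair is *undefined* —
   a correlation on fewer points is too unstable to feed a 3·SD selection.
2. Ordinary least squares of the second probe (y) on the first (x), via
   the normal equations. The regression axis follows the ordered pair:
   x is the KGML entry1 gene (or the lexicographically smaller probe in
   all-pairs use). OLS residuals are axis-asymmetric, so swapping the pair
   can change the discard set; the final correlation itself is symmetric.
3. Squared residuals e², a single threshold mean(e²) + k·SD(e²) with
   k = `sd_multiplier` (default 3), strict exceedance discards a sample.
   One pass, no refit: the threshold the data implies is applied once.
4. A retention floor: never discard more than
   floor((1 − `retention_floor`)·n_total) samples (default floor 0.8,
   i.e. ≤ 20% discarded, largest residuals first, ties by sample order).
   With the default k = 3 and population SD this cap is in fact provably
   slack — by Cantelli's inequality at most n/(1+k²) = 10% of any sample
   can exceed a mean + 3·SD threshold — so it acts as a guarantee, and
   binds only when k is lowered.
5. Pearson's r on the kept samples; classification at ±`corr_threshold`
   (default 0.45), strict inequalities, so [−0.45, 0.45] is *unrelated*;
   a constant vector yields an undefined correlation and class.

Selection: cor_dif is computed for every pair defined in both conditions;
AVG and SD (population SD by default, sample SD behind
`population_sd=False`) are taken over that same eligible population, and a
pair is selected iff cor_dif lies strictly outside [AVG − 3·SD,
AVG + 3·SD]. Under a null in which no pair changes its correlation,
cor_dif is approximately normal and the rule selects ≈ 0.27% of pairs
(the two-sided 3σ tail) — the empirical check is part of the test suite
and the acceptance script. No multiple-testing correction is applied; the
3·SD rule is the method.

When several probe pairs map to one gene pair, the reported
representative is the probe pair with the largest |cor_dif| (conservative
and auditable); mean aggregation is available (`--aggregation mean`).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| corr_threshold | 0.45 | r | boundary between (co/reverse-)expressed and unrelated |
| sd_multiplier | 3 | SDs | both the residual-discard and the cor_dif selection width |
| retention_floor | 0.8 | fraction | at least 80% of samples enter the correlation |
| min_samples | 10 | samples | below this a correlation is reported undefined |
| population_sd | true | — | divide by n; the n−1 variant is flag-switchable |
| relation_types | PPrel, GErel | — | protein–protein and TF→target edges carry the co-expression hypotheses; ECrel/PCrel/maplink opt-in |
| workers / chunk_size | 1 / 10,000 | — | parallel execution; results independent of both |

## Synthetic data

The generator emulates the structure this method consumes, not microarray
physics. Planted pairs are bivariate normal with the requested per-
condition correlation — under normality the planted ρ is exactly the
population Pearson correlation, making recovery quantifiable through the
Fisher-transform standard error. Values are placed on a log2-intensity
scale (baseline 8.0 ± 1.0, typical of RMA summaries). Null probes are
independent. Gross outliers are additive offsets on one axis of a planted
pair (default 8 log2 units, a corrupted/saturated reading; the
outlier-robustness experiments use an offset of 100 marginal SDs so the
contamination is unambiguous), at a rate capped at 0.2 so the retention
floor can always absorb them. Default group sizes 160/89 mirror a
published breast-cancer relapse cohort's split.

What the generator does not emulate: probe-level noise models, intensity-
dependent variance, batch effects, correlated null structure, and
annotation ambiguity beyond the probe→gene multimap. Passing tests
therefore demonstrate the statistical machinery under its own model
assumptions, not performance on real arrays.

A companion KGML fixture writer emits a minimal pathway whose PPrel
relations are exactly the planted pairs, so the full KGML → gene pairs →
probe pairs → selection route is exercised end to end.

## Numerical choices

- OLS and Pearson are computed by the direct centered formulas in double
  precision; r is clamped to [−1, 1] against rounding. Agreement with
  scipy's implementations is asserted to 1e-12 in the tests.
- The discard cap floor((1 − retention_floor)·n) is evaluated with a 1e-9
  epsilon so binary representation of the fraction (e.g. 0.2·15) cannot
  shift the integer floor.
- Ties on squared residuals at the cap are broken by sample order (stable
  sort), making the discard set deterministic.
- Degenerate fits (constant x, or n < 3) skip filtering entirely and mark
  the correlation undefined rather than guessing.
- Report files render floats with `repr` (shortest round-trip), so
  staged and monolithic runs compare byte-for-byte and re-parsing is
  lossless; the pathway report formats cor_dif as a signed two-decimal
  value (e.g. `+0.37`).

## Parallel engine

The pair list is partitioned into contiguous chunks; each chunk is mapped
independently (no cross-chunk state), and chunk results are concatenated
in plan order — a map-only design with zero reduce steps. The correctness
contract, asserted in the tests, is bit-identical output for any
(workers, chunk_size). Chunk results are combined in memory; a failure in
any chunk surfaces with the chunk index and the failing pair key, and
partial results are discarded. Worker processes require the per-pair task
to be picklable.

## Design choices where the design was open

- **Outlier filtering per condition**, not on pooled samples: correlations
  are computed per condition, and a condition difference in means would
  otherwise masquerade as outliers.
- **Population SD** in both thresholds (flag-switchable): the thresholds
  describe the observed residual/delta population, not an inference about
  a larger one.
- **Strict inequalities** at every boundary (±0.45, discard threshold,
  AVG ± 3·SD): a value exactly at a boundary is not beyond it. This makes
  degenerate cases exact: perfectly collinear data (SD = 0) discards
  nothing, identical deltas select nothing.
- **Eligible population for AVG/SD** = all pathway-mapped pairs with a
  defined correlation in both conditions.
- **Probes without gene annotation** are dropped from pathway mapping
  (control probes have no gene) but remain in the matrix for direct use.
- An empty differential input yields empty reports rather than an error;
  a single defined pair errors, since an SD of one value is undefined.

## Known limitations

- The residual-based filter is single-pass: with contamination at
  moderate magnitude (around 8 marginal SDs) the outliers inflate their
  own discard threshold and a fraction escape; truly gross contamination
  is removed reliably. An iterative refit would reduce this but is
  deliberately out of scope.
- On clean uncorrelated pairs the filter trims the residual tail, which
  moves r more than it does for strongly correlated pairs (the residual
  there is the whole y variance); the induced shift stays below 0.1 and
  below 0.05 for |ρ| = 0.8 in ≥ 99% of replicates at n = 200.
- With n = 200 samples, the sampling SD of r at ρ = 0.8 is ≈ 0.028, so no
  estimator places r within ±0.05 of the truth much more than ~94% of the
  time; windows tighter than ±2 SE should not be expected to hold at high
  rates at this sample size.
- The 3·SD selection band is estimated from the analyzed pair set itself;
  with very few pairs (tens), planted signal inflates the band and
  sensitivity drops — the selection rule is meant for hundreds to
  thousands of mapped pairs.
- Directed pair order follows KGML entry1 → entry2; correlation is
  symmetric, so direction is interpretive (and fixes the regression
  axis), not statistical.

## Problem sizes used in the shipped experiments

End-to-end recovery: 10 rewired pairs (Δρ = 0.8) among 1,000 unchanged
pairs, 150 samples per condition. Null rate: 10,000 unchanged pairs at
the same sample size. Filter recovery: 500 replicates of a single pair at
n = 200 with 5% contamination. These sizes make all statistical
tolerances meaningful while keeping a full run in seconds on one CPU.
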