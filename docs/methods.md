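# Methods

## Model and procedure

`transqtl` targets a specific failure mode of QTL detection in
interspecific F2 populations: a causal marker whose phenotypic effect is
switched off, in part of the panel, by an unlinked *trans*-acting
suppressor. The method assumes a second panel — a wild diversity panel —
in which the causal signal is intact, and uses it to prioritize hybrid
samples before fitting tree-ensemble marker-ranking models.

The pipeline stages and their contracts:

1. **Independent marker filtering.** Pairwise Pearson correlation between
   dosage columns (pairwise-complete over non-missing entries); a graph
   with an edge wherever |r| strictly exceeds the threshold (default 0.7);
   one representative per connected component. A known causal marker is
   always its component's representative (so its rank stays measurable);
   otherwise the representative is a seeded uniform draw. Correlated
   markers split importance credit in tree ensembles, which is why
   filtering precedes ranking.
2. **Phenotype simulation.** y = β·g + ε with ε ~ N(0, σ²) i.i.d. and
   σ² = Var(β·g)(1−VE)/VE computed from the *realized* dosage variance, so
   the expected regression R² equals the target VE exactly. Suppression
   subtracts the genetic term β·g (times a suppression factor, default 1)
   in every sample whose suppressor dosage exceeds 0.
3. **Sample weighting.** Focus markers = top-|r| wild markers against the
   wild phenotype, restricted to wild/hybrid shared markers. Segregation
   filters keep both phenotypic tails at quantile q (two-tailed by
   default; single-tail modes exist for sensitivity analysis). Mean Gower
   or Jaccard distance from each hybrid sample to the filtered wild
   samples, over the focus markers only, maps to raw weight 1 − d̄ for
   filtered hybrid samples. Unfiltered hybrid samples are retained at the
   minimum filtered raw weight rather than dropped, so resampled training
   sets keep the full panel size; `exclude_unfiltered` implements the
   strict alternative.
4. **Ranking models.** Random forest (default 1000 trees, squared-error
   loss) scored by permutation-on-out-of-bag importance; gradient boosting
   (learning rate 0.3, squared-error loss, default 100 rounds, depth 6)
   scored by total gain; a single-marker OLS scan (slope t-test, two-sided)
   as the regression baseline. Importance scores become ranks (1 = best,
   ties averaged) and are averaged over repeated iterations: weighted mode
   redraws a probabilistic resample each iteration; unweighted mode refits
   with a fresh model seed on the full panel.
5. **Evaluation.** Detection rate per cumulative rank bin (fraction of
   replicates with causal avg-rank < edge; edges 2..6) and
   linear-interpolation quantiles (80%/90%) of the causal-rank
   distribution, per cell of the parameter grid (effect size × metric ×
   top-marker cutoff × wild/hybrid segregation quantiles × model).

## What the simulator emulates — and what it does not

The generator reproduces the structural features the method depends on:
panel shapes (defaults 143 wild / 140 hybrid samples), dosage coding
{0,1,2} counting the non-cultivar allele, blockwise LD in the wild panel
(Gaussian-copula haplotypes with a shared block factor, ρ = 0.8),
Mendelian F2 segregation from wild × homozygous-cultivar crosses (default
20 parent lines, per-adjacent-marker recombination 0.05 within blocks,
free recombination between blocks), partial marker overlap between panels,
and a wild MAF spectrum (uniform on (0.1, 0.5)) that makes the causal
MAF-ratio filter (wild/hybrid ≥ 1.5) satisfiable: the cross to a null
cultivar parent halves the alternate-allele frequency in the F2.

Half of the markers (configurable `alt_major_fraction`) carry the
non-cultivar allele as the wild panel's *major* allele, as expected for
markers fixed by interspecific divergence. These markers segregate broadly
in the F2 (carrier fractions up to ~0.75) and are the realistic candidates
for a trans-suppressor that masks a substantial share of the panel. The
scenario runner restricts the suppressor draw to markers with carrier
fraction ≥ 0.5 (`min_suppressed_fraction`): a suppressor carried by only a
few percent of samples does not produce the suppressed-signal regime the
method addresses. Under the 20-parent design, carrier fractions are
bounded near 0.75·p (p the wild allele frequency), so floors much above
0.5 are unattainable.

Not emulated: real GBS marker ascertainment and missingness patterns,
population structure within the wild panel, multi-QTL or dominance
architectures, genetic-map distances (LD is purely blockwise), and
selection-based line filtering. Passing tests therefore demonstrate the
method's behavior under a clean single-QTL trans-suppression scenario, not
performance on real GBS panels.

## Numerical and design choices

- **RF importance** is computed at forest level: permute a marker's column
  once (per iteration), recompute the out-of-bag aggregated prediction
  error, report the MSE increase. This matches the OOB-permutation
  definition and is cross-checked in the tests against a naive per-tree
  loop oracle. For speed, all permuted panels are pushed through a single
  batched `forest.apply` call and predictions are gathered from padded
  per-tree leaf tables.
- **RF `max_features`** defaults to 1/3 of markers, the regression
  convention of the reference random-forest ecosystem. Trees default to
  1000; the heavy scenario tests use 100 trees and 25 iterations as
  scaled-down problem sizes (stated in the test docstrings).
- **Gradient boosting** is deterministic given the data (no row/column
  subsampling), so unweighted GBM iterations coincide; the iteration loop
  is kept for interface uniformity and for the weighted mode, where each
  iteration's resample differs.
- **Edge rule** for marker filtering uses |r| (anti-correlated markers are
  equally redundant); a `signed` flag restricts edges to positive r. The
  threshold comparison is strict (> 0.7, not ≥).
- **Zero-variance markers** are dropped before graph construction with a
  warning (they carry no mappable signal and break Pearson correlation);
  in the regression scan they receive p = 1, ranking last.
- **Jaccard degenerate pairs** (both vectors all-zero over the focus
  markers) are undefined by the formula (0/0). The scalar operation
  raises; the vectorized pipeline treats such a pair as distance 0
  (identical vectors, the identity-of-indiscernibles limit) so one
  degenerate pair cannot abort a weighting run. The Jaccard numerator is
  restricted to markers with I_k = 1; counting matches at double-zero
  markers while excluding them from the denominator could otherwise push
  the distance negative.
- **Gower validity weight** δ marks a marker invalid for a pair when
  either dosage is missing or the pooled dosage range R_k is zero.
- **Noise generation** uses i.i.d. univariate Gaussian draws (equivalent
  to a multivariate normal with identity covariance). σ² is a
  deterministic function of the realized dosage variance, not itself
  random: this pins the expected VE at the target, which the calibration
  check (mean realized VE over 200 replicates within ±0.02 of target)
  verifies.
- **Wild phenotypes** are simulated from the same causal marker at the
  same effect size, without suppression — the method's premise is that
  the wild panel retains the intact signal that the weighting step
  correlates against.
- **Suppression semantics**: "suppressed" means the genetic term is fully
  removed (phenotype = noise) for carrier samples; a suppression factor in
  [0, 1] generalizes to partial attenuation.
- **Quantile definition** is linear interpolation throughout (trait
  segregation thresholds and causal-rank quantiles); fractional rank
  summaries require an interpolating rule, and this is numpy's default,
  stated here to fix it.
- **Seeding**: every stochastic stage takes an explicit seed; scenario
  replicates derive seeds as
  `SeedSequence([master_seed, replicate, stage_counter])`, so any single
  replicate can be re-run in isolation and weighted/unweighted contrasts
  are paired on identical data.
- **Tie handling**: tied importance scores receive their average rank, so
  every per-iteration rank vector sums to m(m+1)/2.

## Parameter grid defaults

Top-marker cutoffs {5, 10, 15, 20}; segregation quantiles
{5, 10, 15, 20, 25}% for both panels; metrics {gower, jaccard}; effect
sizes {0.4, 0.8}; models {rf, gbm} × {weighted, unweighted} plus
regression; 100 iterations per ranking and 100 replicates per cell by
default (percent-resolution rates), both configurable downward for desk
runs. Scenario panels default to the post-filter Bari-like scale
(143 wild / 140 hybrid × 125 independent markers): simulating at the
filtered scale with `ld_block_size=1` stands in for simulating a dense
correlated panel and then filtering it, which the filtering module covers
separately.

## Known limitations

- The weighted causal-rank distribution is heavier-tailed than the
  unweighted one: when the filtered wild reference set is atypical, the
  resample can bury the causal signal in that replicate even as the
  top-bin detection rate improves on average.
- With a single simulated QTL and independent markers, the single-marker
  regression scan is a near-optimal baseline; the weighting scheme's
  advantage is specific to the suppressed-signal regime.
- `select_causal_marker` and `select_suppressor_marker` use empirical
  frequencies, so eligibility is sample-size dependent at small panels.
- The VCF reader accepts bi-allelic GT fields only.
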