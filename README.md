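# transqtl

Interspecific sample prioritization for QTL detection with tree-based
marker-ranking models.

## The problem

Crossing a wild crop relative to an elite cultivar (an interspecific F2
population) is a standard way to recover trait variation that domestication
lost. But QTL signals in such hybrids are frequently masked by
*trans*-regulation: an unlinked suppressor locus switches off the causal
allele's phenotypic effect in the subset of hybrids that carry it. A
single-population association scan or importance ranking then sees a diluted
signal, while the same causal locus still segregates cleanly in a wild
diversity panel.

`transqtl` implements a probabilistic sample-prioritization scheme that
combines both panels. Hybrid samples whose genotype–phenotype pattern is
consistent with the trait-segregating wild samples are sampled with higher
probability when building the training sets of tree-ensemble models (random
forest with permutation-on-out-of-bag importance; gradient boosting with
total-gain importance). Markers are ranked by importance averaged over
repeated iterations, and detection is scored by how often the known causal
marker lands in the top rank bin ("rank < 2").

The weighting pipeline:

1. **Focus markers** — rank shared wild/hybrid markers by |Pearson r|
   between wild phenotype and dosage; keep the top *k* (k ∈ {5, 10, 15, 20}).
2. **Trait segregation filters** — keep phenotypic extremes in each panel at
   quantile q ∈ {5, 10, 15, 20, 25}%.
3. **Genotype distance** — for every hybrid sample, the mean Gower or
   Jaccard distance to the filtered wild samples over the focus markers:

   Gower: S<sub>ij</sub> = Σ<sub>k</sub> s<sub>ijk</sub> δ<sub>ijk</sub> / Σ<sub>k</sub> δ<sub>ijk</sub>, with
   s<sub>ijk</sub> = |x<sub>ik</sub> − x<sub>jk</sub>| / R<sub>k</sub>;
   Jaccard: J<sub>ij</sub> = 1 − Σ<sub>k</sub> I<sub>ijk</sub> / Σ<sub>k</sub> I<sub>k</sub>,
   over markers where at least one sample carries a non-zero dosage.

4. **Sampling probabilities** — filtered hybrid samples get weight
   1 − d̄<sub>i</sub>; the rest are kept at the minimum filtered weight;
   normalized, then used for with-replacement resampling of each training
   set.

Because the processed genotype matrices of the original chickpea panels are
not publicly deposited, the package ships a first-class simulator that
emulates their structure: a wild panel with blockwise LD and a configurable
MAF spectrum, F2 panels from wild × fixed-cultivar crosses with Mendelian
1:2:1 segregation, partial marker overlap between panels, higher wild than
hybrid MAF at candidate causal markers, additive phenotypes at a target
variance explained (VE ∈ {0.4, 0.8}), and dosage-conditional
trans-suppression.

## Worked example

Simulate Bari-like panels (143 wild, 140 F2 hybrids, 125 independent
markers), apply full trans-suppression at VE = 0.8, and compare weighted
vs unweighted gradient boosting over 20 replicates:

```python
import numpy as np
from transqtl.evaluation import GridConfig, run_scenario_grid
from transqtl.genotypes import SimPopConfig

grid = GridConfig(
    panel=SimPopConfig(n_wild=143, n_hybrid=140, n_markers=125),
    effect_sizes=(0.8,),
    metrics=("gower",),
    top_marker_cutoffs=(10,),
    wild_seg_quantiles=(0.10,),
    hybrid_seg_quantiles=(0.05,),
    models=("gbm", "gbm_weighted", "regression"),
    suppression=True,
    n_iterations=25,
)
results = run_scenario_grid(grid, n_replicates=20, master_seed=1)
for res in results:
    label = res.grid_cell["model_label"]
    print(f"{label:14s} rank<2 detection: {res.detection[2.0]:.2f}  "
          f"mean causal rank: {np.mean(res.causal_ranks):.2f}")
```

prints

```
gbm            rank<2 detection: 0.50  mean causal rank: 1.50
gbm_weighted   rank<2 detection: 0.75  mean causal rank: 3.61
regression     rank<2 detection: 0.80  mean causal rank: 1.55
```

With most hybrid samples suppressed, plain gradient boosting ranks the
causal marker on top in only half the replicates; borrowing the wild
panel's intact signal through probabilistic resampling lifts the top-bin
detection rate to 0.75. (The weighted mean rank is heavier-tailed — when
the wild reference set is misleading in a replicate the causal marker can
drop far — but the top-bin rate, the metric of interest, improves.) The
single-marker regression scan is a strong baseline here because the
simulated panels carry a single causal locus and independent markers.

Estimator-style classes (`HybridSampleWeighter`,
`RandomForestMarkerRanker`, `GradientBoostingMarkerRanker`,
`RegressionMarkerRanker`, `IndependentMarkerFilter`) expose the same
machinery with sklearn `fit`/`get_params` conventions, and a `transqtl`
CLI (`simulate-genotypes`, `simulate-phenotypes`, `filter-markers`,
`weight`, `rank`, `run-grid`) wraps the library for shell use; every
subcommand writes a JSON run manifest for reproducibility.

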