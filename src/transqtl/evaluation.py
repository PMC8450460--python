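"""Simulation-study machinery: replicate scenarios and detection rates.

A scenario fixes the panel shapes, the effect size (variance explained),
whether trans-suppression is applied, and a cell of the weighting
parameter grid.  For every replicate, fresh panels and phenotypes are
simulated, markers are filtered to independent representatives, each model
ranks the markers, and the causal marker's iteration-averaged rank is
recorded.  Detection rates are the fraction of replicates whose causal
rank falls below each rank-bin edge ("rank < 2" = ranked top marker).

Per-replicate seeds derive from the master seed with a counter scheme:
``SeedSequence([master_seed, replicate_index, stage_counter])``; stage
counters are fixed module constants, so any single replicate can be re-run
in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, SimPopConfig, simulate_f2_population, simulate_wild_population
from .marker_filter import IndependentMarkerFilter
from .models import GBMConfig, RFConfig, average_rank, regression_ranks
from .pheno_sim import (
    apply_trans_suppression,
    select_causal_marker,
    select_suppressor_marker,
    simulate_phenotype,
)
from .weighting import WeightingConfig, compute_sample_weights

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioResult",
    "GridConfig",
    "detection_rates",
    "cumulative_rank_quantiles",
    "simulate_replicate_data",
    "run_scenario_grid",
    "results_to_dataframe",
]

DEFAULT_BIN_EDGES = (2.0, 3.0, 4.0, 5.0, 6.0)

# stage counters for the per-replicate seed-splitting scheme
_STAGE_PANEL = 0
_STAGE_CAUSAL = 1
_STAGE_WILD_PHENO = 2
_STAGE_HYBRID_PHENO = 3
_STAGE_SUPPRESSOR = 4
_STAGE_FILTER = 5
_STAGE_MODEL = 6


def _stage_seed(master_seed: int, replicate: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(replicate), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def detection_rates(
    causal_ranks: Sequence[float], bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> dict[float, float]:
    """Fraction of replicates with causal avg_rank < edge, per bin edge."""
    ranks = np.asarray(list(causal_ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("empty causal rank list")
    if (ranks < 1).any():
        raise ValueError("ranks must be >= 1")
    return {float(e): float(np.mean(ranks < e)) for e in bin_edges}


def cumulative_rank_quantiles(
    causal_ranks: Sequence[float], probs: Sequence[float] = (0.8, 0.9)
) -> dict[float, float]:
    """Empirical quantiles of the causal-rank distribution.

    Uses the linear-interpolation quantile definition, which matches the
    fractional rank summaries the cumulative curves are read from.
    """
    ranks = np.asarray(list(causal_ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("empty causal rank list")
    probs = list(probs)
    if any(not (0.0 < p < 1.0) for p in probs):
        raise ValueError("quantile probabilities must be in (0, 1)")
    return {float(p): float(np.quantile(ranks, p, method="linear")) for p in probs}


@dataclass
class ScenarioResult:
    """Causal-rank outcomes for one grid cell."""

    grid_cell: dict
    causal_ranks: list[float]
    detection: dict[float, float]
    n_replicates: int
    n_failed: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.causal_ranks):
            raise ValueError("causal ranks must be >= 1")
        rates = [self.detection[e] for e in sorted(self.detection)]
        if any(not (0.0 <= x <= 1.0) for x in rates):
            raise ValueError("detection rates must lie in [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(rates, rates[1:])):
            raise ValueError("detection rates must be non-decreasing across bins")


@dataclass
class GridConfig:
    """Parameter grid plus fixed study conditions for a scenario sweep."""

    panel: SimPopConfig = field(default_factory=SimPopConfig)
    effect_sizes: tuple[float, ...] = (0.4, 0.8)
    metrics: tuple[str, ...] = ("gower", "jaccard")
    top_marker_cutoffs: tuple[int, ...] = (5, 10, 15, 20)
    wild_seg_quantiles: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)
    hybrid_seg_quantiles: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)
    models: tuple[str, ...] = ("rf", "rf_weighted", "gbm", "gbm_weighted", "regression")
    suppression: bool = True
    suppression_factor: float = 1.0
    min_suppressed_fraction: float = 0.5
    maf_ratio_threshold: float = 1.5
    corr_threshold: float = 0.7
    n_iterations: int = 100
    rf: RFConfig = field(default_factory=RFConfig)
    gbm: GBMConfig = field(default_factory=GBMConfig)
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def validate(self) -> None:
        self.panel.validate()
        known = {"rf", "rf_weighted", "gbm", "gbm_weighted", "regression"}
        bad = set(self.models) - known
        if bad:
            raise ValueError(f"unknown model labels: {sorted(bad)}")
        for v in self.effect_sizes:
            if not (0.0 < v <= 1.0):
                raise ValueError("effect sizes must be in (0, 1]")


@dataclass
class ReplicateData:
    """Everything one replicate's models consume."""

    wild: GenotypeMatrix
    wild_pheno: object
    hybrid: GenotypeMatrix
    hybrid_pheno: object
    causal: str
    suppressor: str | None


def simulate_replicate_data(
    grid: GridConfig, effect_size: float, replicate: int, master_seed: int
) -> ReplicateData:
    """Simulate one replicate: panels, causal/suppressor choice, phenotypes.

    The hybrid panel is reduced to independent representative markers
    (causal retained); the wild phenotype is simulated from the same causal
    marker at the same effect size and is never suppressed.
    """
    panel_cfg = SimPopConfig(
        **{
            **grid.panel.__dict__,
            "seed": _stage_seed(master_seed, replicate, _STAGE_PANEL),
        }
    )
    wild = simulate_wild_population(panel_cfg)
    hybrid = simulate_f2_population(wild, panel_cfg)
    causal = select_causal_marker(
        wild,
        hybrid,
        maf_ratio_threshold=grid.maf_ratio_threshold,
        seed=_stage_seed(master_seed, replicate, _STAGE_CAUSAL),
    )
    filt = IndependentMarkerFilter(
        threshold=grid.corr_threshold,
        random_state=_stage_seed(master_seed, replicate, _STAGE_FILTER),
    )
    hybrid_f = filt.fit_transform(hybrid, causal_ids=[causal])

    wild_pheno = simulate_phenotype(
        wild,
        causal,
        target_ve=effect_size,
        seed=_stage_seed(master_seed, replicate, _STAGE_WILD_PHENO),
    )
    hybrid_pheno = simulate_phenotype(
        hybrid_f,
        causal,
        target_ve=effect_size,
        seed=_stage_seed(master_seed, replicate, _STAGE_HYBRID_PHENO),
    )
    suppressor = None
    if grid.suppression:
        exclude = filt.partition_.component_of(causal)
        suppressor = select_suppressor_marker(
            hybrid_f,
            causal,
            exclude=exclude,
            min_suppressed_fraction=grid.min_suppressed_fraction,
            seed=_stage_seed(master_seed, replicate, _STAGE_SUPPRESSOR),
        )
        hybrid_pheno = apply_trans_suppression(
            hybrid_pheno, hybrid_f, suppressor, grid.suppression_factor
        )
    return ReplicateData(wild, wild_pheno, hybrid_f, hybrid_pheno, causal, suppressor)


def _causal_rank_for_model(
    data: ReplicateData,
    model_label: str,
    wcfg: WeightingConfig,
    grid: GridConfig,
    model_seed: int,
) -> float:
    if model_label == "regression":
        table = regression_ranks(data.hybrid, data.hybrid_pheno)
    else:
        weighted = model_label.endswith("_weighted")
        base = model_label.split("_")[0]
        weights = None
        if weighted:
            weights = compute_sample_weights(
                data.wild, data.wild_pheno, data.hybrid, data.hybrid_pheno, wcfg
            )
        cfg = grid.rf if base == "rf" else grid.gbm
        table = average_rank(
            data.hybrid,
            data.hybrid_pheno,
            model=base,
            cfg=cfg,
            weights=weights,
            n_iter=grid.n_iterations,
            seed=model_seed,
        )
    return table.rank_of(data.causal)


def run_scenario_grid(
    grid: GridConfig, n_replicates: int = 100, master_seed: int = 0
) -> list[ScenarioResult]:
    """Run the full parameter sweep and collect per-cell detection rates.

    Within a replicate, every grid cell and model sees the same simulated
    panels and phenotypes (matched seeds), so weighted/unweighted contrasts
    are paired.  Unweighted models do not depend on the weighting
    parameters and are computed once per (effect size, replicate).  A cell
    with more than 10% failed replicates is flagged.
    """
    grid.validate()
    cells = [
        {
            "effect_size": ve,
            "metric": met,
            "top_marker_cutoff": c,
            "wild_seg_quantile": wq,
            "hybrid_seg_quantile": hq,
            "model_label": lab,
        }
        for ve, met, c, wq, hq, lab in product(
            grid.effect_sizes,
            grid.metrics,
            grid.top_marker_cutoffs,
            grid.wild_seg_quantiles,
            grid.hybrid_seg_quantiles,
            grid.models,
        )
    ]
    ranks: dict[tuple, list[float]] = {tuple(sorted(c.items())): [] for c in cells}
    fails: dict[tuple, int] = {k: 0 for k in ranks}

    for ve in grid.effect_sizes:
        for rep in range(n_replicates):
            try:
                data = simulate_replicate_data(grid, ve, rep, master_seed)
            except Exception as exc:
                logger.warning("replicate %d (VE=%s) failed to simulate: %s", rep, ve, exc)
                for cell in cells:
                    if cell["effect_size"] == ve:
                        fails[tuple(sorted(cell.items()))] += 1
                continue
            model_seed = _stage_seed(master_seed, rep, _STAGE_MODEL)
            unweighted_cache: dict[str, float] = {}
            for cell in cells:
                if cell["effect_size"] != ve:
                    continue
                key = tuple(sorted(cell.items()))
                lab = cell["model_label"]
                wcfg = WeightingConfig(
                    top_marker_cutoff=cell["top_marker_cutoff"],
                    wild_seg_quantile=cell["wild_seg_quantile"],
                    hybrid_seg_quantile=cell["hybrid_seg_quantile"],
                    metric=cell["metric"],
                )
                try:
                    if lab in ("rf", "gbm", "regression"):
                        if lab not in unweighted_cache:
                            unweighted_cache[lab] = _causal_rank_for_model(
                                data, lab, wcfg, grid, model_seed
                            )
                        ranks[key].append(unweighted_cache[lab])
                    else:
                        ranks[key].append(
                            _causal_rank_for_model(data, lab, wcfg, grid, model_seed)
                        )
                except Exception as exc:
                    logger.warning("cell %s replicate %d failed: %s", cell, rep, exc)
                    fails[key] += 1

    results = []
    for cell in cells:
        key = tuple(sorted(cell.items()))
        cell_ranks = ranks[key]
        n_fail = fails[key]
        flagged = n_fail > 0.1 * n_replicates
        if flagged:
            warnings.warn(
                f"grid cell {cell} had {n_fail}/{n_replicates} failed replicates",
                UserWarning,
                stacklevel=2,
            )
        det = (
            detection_rates(cell_ranks, grid.bin_edges)
            if cell_ranks
            else {float(e): 0.0 for e in grid.bin_edges}
        )
        results.append(
            ScenarioResult(
                grid_cell=cell,
                causal_ranks=cell_ranks,
                detection=det,
                n_replicates=len(cell_ranks),
                n_failed=n_fail,
                flagged=flagged,
            )
        )
    return results


def results_to_dataframe(results: Iterable[ScenarioResult]):
    """Long-format table: one row per grid cell x rank-bin edge."""
    import pandas as pd

    rows = []
    for res in results:
        for edge, rate in sorted(res.detection.items()):
            rows.append(
                {
                    **res.grid_cell,
                    "bin_edge": edge,
                    "detection_rate": rate,
                    "n_replicates": res.n_replicates,
                    "n_failed": res.n_failed,
                    "flagged": res.flagged,
                }
            )
    return pd.DataFrame(rows)
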