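"""Probabilistic hybrid-sample prioritization from wild-panel similarity.

The weighting scheme rescues trans-suppressed QTL signal in a hybrid panel
by borrowing information from a wild panel in which the signal is intact:

1. rank shared markers by |correlation| between wild phenotype and dosage,
   keep the top few ("focus markers");
2. keep only trait-segregating samples (phenotypic extremes) in each panel,
   at separate wild and hybrid quantile cutoffs;
3. for every hybrid sample, average its genotype distance (Gower or
   Jaccard, over the focus markers) to the filtered wild samples;
4. convert mean distances to sampling probabilities (closer to the wild
   extremes = more likely to be drawn) and build resampled training sets
   for the tree-ensemble rankers.

Hybrid samples that fail the segregation filter are retained at the
minimum filtered weight by default, so training sets keep their size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, intersect_markers
from .pheno_sim import PhenotypeVector

__all__ = [
    "WeightingConfig",
    "DistanceContext",
    "SampleWeights",
    "top_wild_markers",
    "segregating_samples",
    "gower_distance",
    "jaccard_distance",
    "pairwise_distances",
    "mean_distance",
    "sampling_probabilities",
    "resample_training_set",
    "compute_sample_weights",
    "HybridSampleWeighter",
]

TOP_MARKER_GRID = (5, 10, 15, 20)
QUANTILE_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class WeightingConfig:
    """Swept parameters of the prioritization scheme."""

    top_marker_cutoff: int = 10
    wild_seg_quantile: float = 0.10
    hybrid_seg_quantile: float = 0.05
    metric: str = "gower"
    tail_mode: str = "both"
    exclude_unfiltered: bool = False

    def validate(self) -> None:
        if self.top_marker_cutoff < 1:
            raise ValueError("top_marker_cutoff must be >= 1")
        for name in ("wild_seg_quantile", "hybrid_seg_quantile"):
            q = getattr(self, name)
            if not (0.0 < q < 0.5):
                raise ValueError(f"{name} must be in (0, 0.5)")
        if self.metric not in ("gower", "jaccard"):
            raise ValueError("metric must be 'gower' or 'jaccard'")
        if self.tail_mode not in ("both", "upper", "lower"):
            raise ValueError("tail_mode must be 'both', 'upper' or 'lower'")


@dataclass
class DistanceContext:
    """Focus-marker subset plus per-marker dosage ranges for Gower terms.

    ``ranges[k]`` is the dosage range R_k of focus marker k over the pooled
    comparison set (wild references plus hybrid samples).  A marker is
    invalid for a pair (its Gower weight is 0) when either dosage is
    missing or R_k = 0.
    """

    marker_ids: list[str]
    ranges: np.ndarray

    def __post_init__(self) -> None:
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.ranges.shape != (len(self.marker_ids),):
            raise ValueError("one range per focus marker required")
        if (self.ranges < 0).any():
            raise ValueError("ranges must be non-negative")

    @classmethod
    def from_pooled(
        cls, marker_ids: Sequence[str], *matrices: GenotypeMatrix
    ) -> "DistanceContext":
        cols = [m.subset_markers(list(marker_ids)).dosage_float() for m in matrices]
        pooled = np.vstack(cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rng_ = np.nanmax(pooled, axis=0) - np.nanmin(pooled, axis=0)
        rng_ = np.where(np.isnan(rng_), 0.0, rng_)
        return cls(list(marker_ids), rng_)


@dataclass
class SampleWeights:
    """Per-hybrid-sample sampling probabilities."""

    sample_ids: list[str]
    probabilities: np.ndarray
    mean_distances: np.ndarray
    filtered_flag: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.mean_distances = np.asarray(self.mean_distances, dtype=float)
        self.filtered_flag = np.asarray(self.filtered_flag, dtype=bool)
        n = len(self.sample_ids)
        for name in ("probabilities", "mean_distances", "filtered_flag"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if (self.probabilities < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def top_wild_markers(
    wildG: GenotypeMatrix,
    wild_pheno: PhenotypeVector,
    cutoff: int,
    candidate_ids: Sequence[str] | None = None,
) -> list[str]:
    """Focus markers: largest |Pearson r| between wild trait and dosage.

    ``candidate_ids`` restricts the ranking (normally to the wild/hybrid
    shared markers).  Ties are broken by candidate order.
    """
    if candidate_ids is None:
        candidate_ids = wildG.marker_ids
    candidate_ids = list(candidate_ids)
    if cutoff > len(candidate_ids):
        raise ValueError(
            f"cutoff {cutoff} exceeds {len(candidate_ids)} candidate markers"
        )
    y = wild_pheno.values
    if np.std(y) == 0:
        raise ValueError("wild phenotype has zero variance")
    X = wildG.subset_markers(candidate_ids).dosage_float()
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = X - np.nanmean(X, axis=0)
        Xc = np.where(np.isnan(Xc), 0.0, Xc)
        num = Xc.T @ yc
        den = np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
        r = np.where(den > 0, num / den, 0.0)
    order = np.argsort(-np.abs(r), kind="stable")
    return [candidate_ids[i] for i in order[:cutoff]]


def segregating_samples(
    pheno: PhenotypeVector, q: float, tail_mode: str = "both"
) -> set[str]:
    """Samples whose trait value falls in the extreme quantile tail(s)."""
    if not (0.0 < q < 0.5):
        raise ValueError("segregation quantile must be in (0, 0.5)")
    v = pheno.values
    if np.std(v) == 0:
        raise ValueError("constant phenotype: no trait segregation")
    lo = np.quantile(v, q)
    hi = np.quantile(v, 1.0 - q)
    if tail_mode == "both":
        mask = (v <= lo) | (v >= hi)
    elif tail_mode == "lower":
        mask = v <= lo
    elif tail_mode == "upper":
        mask = v >= hi
    else:
        raise ValueError("tail_mode must be 'both', 'upper' or 'lower'")
    return {s for s, m in zip(pheno.sample_ids, mask) if m}


def _as_float(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x == MISSING, np.nan, x)


def gower_distance(xi: np.ndarray, xj: np.ndarray, ctx: DistanceContext) -> float:
    """Gower dissimilarity S_ij = sum_k s_ijk d_ijk / sum_k d_ijk.

    s_ijk = |x_ik - x_jk| / R_k; the weight d_ijk is 0 when marker k is
    invalid for the pair (missing dosage or zero range).
    """
    xi, xj = _as_float(xi), _as_float(xj)
    valid = ~np.isnan(xi) & ~np.isnan(xj) & (ctx.ranges > 0)
    if not valid.any():
        raise ValueError("no valid marker for Gower distance")
    s = np.abs(xi[valid] - xj[valid]) / ctx.ranges[valid]
    return float(s.sum() / valid.sum())


def jaccard_distance(xi: np.ndarray, xj: np.ndarray) -> float:
    """Jaccard dissimilarity on dosage vectors.

    Over markers where at least one sample has non-zero dosage (I_k = 1),
    J_ij = 1 - (# markers with identical dosage) / (# markers with I_k=1).
    Undefined (raises) when both vectors are all-zero.
    """
    xi, xj = _as_float(xi), _as_float(xj)
    valid = ~np.isnan(xi) & ~np.isnan(xj)
    active = valid & ((xi != 0) | (xj != 0))
    if not active.any():
        raise ValueError("Jaccard distance undefined: no marker with non-zero dosage")
    matches = (xi[active] == xj[active]).sum()
    return float(1.0 - matches / active.sum())


def pairwise_distances(
    A: np.ndarray, B: np.ndarray, ctx: DistanceContext, metric: str
) -> np.ndarray:
    """Distance matrix between row-vectors of A and of B over ctx markers.

    Vectorized equivalent of looping :func:`gower_distance` /
    :func:`jaccard_distance` over all pairs.  A Jaccard pair with no active
    marker (both vectors all-zero) is identical genotypically and gets
    distance 0 rather than raising, so one degenerate pair cannot abort a
    weighting run.
    """
    A, B = _as_float(np.atleast_2d(A)), _as_float(np.atleast_2d(B))
    diff = A[:, None, :] - B[None, :, :]
    if metric == "gower":
        valid = ~np.isnan(diff) & (ctx.ranges > 0)[None, None, :]
        if not valid.any(axis=2).all():
            raise ValueError("a pair has no valid marker for Gower distance")
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.abs(diff) / ctx.ranges[None, None, :]
        s = np.where(valid, s, 0.0)
        return s.sum(axis=2) / valid.sum(axis=2)
    if metric == "jaccard":
        valid = ~np.isnan(diff)
        active = valid & ((A[:, None, :] != 0) | (B[None, :, :] != 0))
        n_active = active.sum(axis=2)
        matches = (np.where(active, diff, np.nan) == 0).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - matches / n_active
        return np.where(n_active == 0, 0.0, d)
    raise ValueError("metric must be 'gower' or 'jaccard'")


def mean_distance(
    hybrid_sample: np.ndarray,
    wild_reference: np.ndarray,
    ctx: DistanceContext,
    metric: str = "gower",
) -> float:
    """Mean distance from one hybrid sample to every wild reference sample."""
    wild_reference = np.atleast_2d(wild_reference)
    if wild_reference.shape[0] == 0:
        raise ValueError("wild reference set is empty")
    d = pairwise_distances(np.atleast_2d(hybrid_sample), wild_reference, ctx, metric)
    return float(d.mean())


def sampling_probabilities(
    mean_distances: np.ndarray,
    filtered_flags: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    exclude_unfiltered: bool = False,
) -> SampleWeights:
    """Convert mean distances to per-sample sampling probabilities.

    Filtered (trait-segregating) samples get raw weight 1 - d_i, so closer
    to the wild extremes means more likely to be drawn.  Unfiltered samples
    get the minimum filtered raw weight (baseline inclusion), or 0 with
    ``exclude_unfiltered``.  Weights are normalized to sum to 1.
    """
    d = np.asarray(mean_distances, dtype=float)
    flags = np.asarray(filtered_flags, dtype=bool)
    if d.shape != flags.shape:
        raise ValueError("mean_distances and filtered_flags lengths differ")
    if (d[flags] < -1e-12).any() or (d[flags] > 1 + 1e-12).any():
        raise ValueError("mean distances must lie in [0, 1]")
    if not flags.any():
        raise ValueError("no sample passed the segregation filter")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(d.size)]
    raw = np.zeros_like(d)
    raw[flags] = 1.0 - d[flags]
    baseline = 0.0 if exclude_unfiltered else raw[flags].min()
    raw[~flags] = baseline
    total = raw.sum()
    if total <= 0:
        warnings.warn(
            "all raw weights are zero; falling back to uniform probabilities",
            UserWarning,
            stacklevel=2,
        )
        probs = np.full(d.size, 1.0 / d.size)
    else:
        probs = raw / total
    return SampleWeights(list(sample_ids), probs, d, flags)


def resample_training_set(
    hybridG: GenotypeMatrix,
    hybrid_pheno: PhenotypeVector,
    weights: SampleWeights,
    n_out: int | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Draw a probabilistic training set (with replacement).

    Genotype rows and phenotype entries stay paired; drawn sample ids get a
    ``.r<k>`` suffix so the resampled matrix keeps unique ids.  Default
    ``n_out`` is the full hybrid panel size.
    """
    if hybridG.sample_ids != hybrid_pheno.sample_ids:
        raise ValueError("genotype and phenotype samples do not match")
    if weights.sample_ids != hybridG.sample_ids:
        raise ValueError("weights do not match the hybrid samples")
    n = hybridG.n_samples
    if n_out is None:
        n_out = n
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_out, replace=True, p=weights.probabilities)
    new_ids = [f"{hybridG.sample_ids[i]}.r{k}" for k, i in enumerate(idx)]
    G2 = GenotypeMatrix(
        new_ids, list(hybridG.marker_ids), hybridG.dosage[idx, :], hybridG.population
    )
    P2 = PhenotypeVector(
        sample_ids=new_ids,
        values=hybrid_pheno.values[idx],
        causal_marker=hybrid_pheno.causal_marker,
        suppressor_marker=hybrid_pheno.suppressor_marker,
        target_ve=hybrid_pheno.target_ve,
        effect=hybrid_pheno.effect,
        suppressed_mask=hybrid_pheno.suppressed_mask[idx],
    )
    return G2, P2


from sklearn.base import BaseEstimator


class HybridSampleWeighter(BaseEstimator):
    """Estimator computing hybrid-sample sampling probabilities.

    Parameters mirror :class:`WeightingConfig`.  After :meth:`fit`, the
    fitted attributes expose the focus markers, the filtered wild reference
    samples and the resulting :class:`SampleWeights`.
    """

    def __init__(
        self,
        metric: str = "gower",
        top_marker_cutoff: int = 10,
        wild_seg_quantile: float = 0.10,
        hybrid_seg_quantile: float = 0.05,
        tail_mode: str = "both",
        exclude_unfiltered: bool = False,
    ):
        self.metric = metric
        self.top_marker_cutoff = top_marker_cutoff
        self.wild_seg_quantile = wild_seg_quantile
        self.hybrid_seg_quantile = hybrid_seg_quantile
        self.tail_mode = tail_mode
        self.exclude_unfiltered = exclude_unfiltered

    def _config(self) -> WeightingConfig:
        cfg = WeightingConfig(
            top_marker_cutoff=self.top_marker_cutoff,
            wild_seg_quantile=self.wild_seg_quantile,
            hybrid_seg_quantile=self.hybrid_seg_quantile,
            metric=self.metric,
            tail_mode=self.tail_mode,
            exclude_unfiltered=self.exclude_unfiltered,
        )
        cfg.validate()
        return cfg

    def fit(
        self,
        wildG: GenotypeMatrix,
        wild_pheno: PhenotypeVector,
        hybridG: GenotypeMatrix,
        hybrid_pheno: PhenotypeVector,
    ):
        cfg = self._config()
        shared = intersect_markers(wildG, hybridG)
        cutoff = min(cfg.top_marker_cutoff, len(shared))
        self.top_markers_ = top_wild_markers(wildG, wild_pheno, cutoff, shared)

        wild_keep = segregating_samples(wild_pheno, cfg.wild_seg_quantile, cfg.tail_mode)
        hyb_keep = segregating_samples(
            hybrid_pheno, cfg.hybrid_seg_quantile, cfg.tail_mode
        )
        self.wild_reference_ids_ = [s for s in wildG.sample_ids if s in wild_keep]

        wild_sub = wildG.subset_markers(self.top_markers_)
        hyb_sub = hybridG.subset_markers(self.top_markers_)
        wild_ref_rows = [wildG.sample_ids.index(s) for s in self.wild_reference_ids_]
        W = wild_sub.dosage[wild_ref_rows, :]
        H = hyb_sub.dosage
        self.context_ = DistanceContext.from_pooled(
            self.top_markers_, wild_sub.subset_samples(wild_ref_rows), hyb_sub
        )
        D = pairwise_distances(H, W, self.context_, cfg.metric)
        mean_d = D.mean(axis=1)
        flags = np.array([s in hyb_keep for s in hybridG.sample_ids])
        self.weights_ = sampling_probabilities(
            mean_d,
            flags,
            sample_ids=hybridG.sample_ids,
            exclude_unfiltered=cfg.exclude_unfiltered,
        )
        return self

    def resample(
        self,
        hybridG: GenotypeMatrix,
        hybrid_pheno: PhenotypeVector,
        n_out: int | None = None,
        seed: int | None = None,
    ) -> tuple[GenotypeMatrix, PhenotypeVector]:
        return resample_training_set(hybridG, hybrid_pheno, self.weights_, n_out, seed)


def compute_sample_weights(
    wildG: GenotypeMatrix,
    wild_pheno: PhenotypeVector,
    hybridG: GenotypeMatrix,
    hybrid_pheno: PhenotypeVector,
    cfg: WeightingConfig | None = None,
) -> SampleWeights:
    """Functional wrapper over :class:`HybridSampleWeighter`."""
    cfg = cfg or WeightingConfig()
    est = HybridSampleWeighter(
        metric=cfg.metric,
        top_marker_cutoff=cfg.top_marker_cutoff,
        wild_seg_quantile=cfg.wild_seg_quantile,
        hybrid_seg_quantile=cfg.hybrid_seg_quantile,
        tail_mode=cfg.tail_mode,
        exclude_unfiltered=cfg.exclude_unfiltered,
    )
    return est.fit(wildG, wild_pheno, hybridG, hybrid_pheno).weights_
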