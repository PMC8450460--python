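"""Additive phenotype simulation with trans-regulatory suppression.

A quantitative trait is simulated from one causal marker's allelic dosage:
``y = effect * g + noise``, with Gaussian noise scaled so that the causal
marker explains a chosen fraction of the phenotypic variance (the effect
size, VE).  Trans-downregulation is modelled by a second, unlinked
"suppressor" marker: in hybrid samples carrying at least one suppressor
allele, the genetic contribution is removed from the phenotype, leaving
noise.  This is the scenario in which a hybrid panel alone tends to lose
the association signal while a wild panel retains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, intersect_markers

__all__ = [
    "PhenotypeVector",
    "select_causal_marker",
    "select_suppressor_marker",
    "simulate_phenotype",
    "apply_trans_suppression",
    "realized_variance_explained",
]


@dataclass
class PhenotypeVector:
    """Per-sample trait values plus simulation provenance."""

    sample_ids: list[str]
    values: np.ndarray
    causal_marker: str | None = None
    suppressor_marker: str | None = None
    target_ve: float | None = None
    effect: float = 1.0
    suppressed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values length must match sample_ids")
        if self.suppressed_mask is None:
            self.suppressed_mask = np.zeros(len(self.sample_ids), dtype=bool)
        self.suppressed_mask = np.asarray(self.suppressed_mask, dtype=bool)
        if self.suppressed_mask.shape != self.values.shape:
            raise ValueError("suppressed_mask length must match values")
        if self.suppressor_marker is None and self.suppressed_mask.any():
            raise ValueError("suppressed_mask set without a suppressor marker")
        if self.target_ve is not None and not (0.0 < self.target_ve <= 1.0):
            raise ValueError("target_ve must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _marker_maf(G: GenotypeMatrix, ids: list[str]) -> np.ndarray:
    sub = G.subset_markers(ids)
    return sub.maf()


def select_causal_marker(
    wild: GenotypeMatrix,
    hybrid: GenotypeMatrix,
    maf_ratio_threshold: float = 1.5,
    seed: int | None = None,
) -> str:
    """Pick a causal marker from the wild/hybrid intersection.

    Eligible markers have wild-MAF / hybrid-MAF >= ``maf_ratio_threshold``
    (the wild panel must segregate more strongly at the causal locus) and a
    non-zero hybrid MAF; one eligible marker is drawn uniformly.
    """
    shared = intersect_markers(wild, hybrid)
    wild_maf = _marker_maf(wild, shared)
    hyb_maf = _marker_maf(hybrid, shared)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hyb_maf > 0, wild_maf / hyb_maf, np.nan)
    eligible = np.flatnonzero((hyb_maf > 0) & (ratio >= maf_ratio_threshold))
    if eligible.size == 0:
        best = np.nanmax(ratio) if np.isfinite(ratio).any() else float("nan")
        raise ValueError(
            f"no shared marker reaches MAF ratio {maf_ratio_threshold} "
            f"(best observed ratio: {best:.3f})"
        )
    rng = np.random.default_rng(seed)
    return shared[int(rng.choice(eligible))]


def select_suppressor_marker(
    hybrid: GenotypeMatrix,
    causal: str,
    exclude: Iterable[str] = (),
    min_suppressed_fraction: float = 0.0,
    seed: int | None = None,
) -> str:
    """Pick a trans-suppressor marker uniformly from the hybrid panel.

    The causal marker and any ids in ``exclude`` (typically the causal
    marker's correlation component) are ineligible.
    ``min_suppressed_fraction`` restricts the draw to markers for which at
    least that fraction of samples carry dosage > 0, i.e. to suppressors
    that actually mask the signal in a sizeable share of the panel.
    """
    banned = set(exclude) | {causal}
    frac_pos = np.mean(hybrid.dosage > 0, axis=0)
    candidates = [
        m
        for m, f in zip(hybrid.marker_ids, frac_pos)
        if m not in banned and f >= min_suppressed_fraction
    ]
    if not candidates:
        raise ValueError("no eligible suppressor marker")
    rng = np.random.default_rng(seed)
    return candidates[int(rng.integers(0, len(candidates)))]


def simulate_phenotype(
    G: GenotypeMatrix,
    causal: str,
    target_ve: float,
    effect: float = 1.0,
    seed: int | None = None,
) -> PhenotypeVector:
    """Simulate ``y = effect * dosage + N(0, sigma^2)`` at a target VE.

    The noise variance is set from the realized dosage variance:
    ``sigma^2 = Var(effect * g) * (1 - VE) / VE``, so the expected
    regression R^2 of y on g equals ``target_ve``.  ``target_ve = 1`` gives
    a noiseless phenotype.
    """
    if not (0.0 < target_ve <= 1.0):
        raise ValueError("target_ve must be in (0, 1]")
    g = G.marker_dosage(causal).astype(float)
    if (g == MISSING).any():
        raise ValueError("causal marker has missing dosages")
    g_var = float(np.var(g))
    if g_var == 0.0:
        raise ValueError(f"causal marker {causal!r} has zero dosage variance")
    sigma2 = (effect**2) * g_var * (1.0 - target_ve) / target_ve
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(sigma2), size=G.n_samples) if sigma2 > 0 else 0.0
    values = effect * g + noise
    return PhenotypeVector(
        sample_ids=G.sample_ids,
        values=values,
        causal_marker=causal,
        target_ve=target_ve,
        effect=effect,
    )


def apply_trans_suppression(
    pheno: PhenotypeVector,
    G: GenotypeMatrix,
    suppressor: str,
    suppression_factor: float = 1.0,
    seed: int | None = None,
) -> PhenotypeVector:
    """Suppress the genetic term in samples carrying the suppressor allele.

    For samples with suppressor dosage > 0, ``suppression_factor`` times
    the genetic contribution (``effect * causal_dosage``) is subtracted,
    so at the default factor of 1 only the noise term remains.  Other
    samples are untouched.  ``seed`` is accepted for interface symmetry;
    the operation itself is deterministic.
    """
    if not (0.0 <= suppression_factor <= 1.0):
        raise ValueError("suppression_factor must be in [0, 1]")
    if suppressor == pheno.causal_marker:
        raise ValueError("suppressor marker must differ from the causal marker")
    if pheno.causal_marker is None:
        raise ValueError("phenotype has no causal marker to suppress")
    if G.sample_ids != pheno.sample_ids:
        raise ValueError("genotype and phenotype samples do not match")
    sup = G.marker_dosage(suppressor)
    causal_g = G.marker_dosage(pheno.causal_marker).astype(float)
    mask = np.asarray(sup > 0)
    values = pheno.values.copy()
    values[mask] -= suppression_factor * pheno.effect * causal_g[mask]
    return replace(
        pheno,
        values=values,
        suppressor_marker=suppressor,
        suppressed_mask=mask,
    )


def realized_variance_explained(pheno: PhenotypeVector | np.ndarray, dosage: np.ndarray) -> float:
    """R^2 of a least-squares regression of trait values on dosage."""
    y = pheno.values if isinstance(pheno, PhenotypeVector) else np.asarray(pheno, float)
    g = np.asarray(dosage, dtype=float)
    if y.shape != g.shape:
        raise ValueError("phenotype and dosage lengths differ")
    if np.var(y) == 0 or np.var(g) == 0:
        raise ValueError("degenerate variance in phenotype or dosage")
    r = np.corrcoef(g, y)[0, 1]
    return float(r * r)
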