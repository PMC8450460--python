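"""Independent-marker selection via a correlation adjacency graph.

Tree-ensemble importance splits credit among correlated markers, so before
ranking, each panel is reduced to approximately independent markers: build
a graph whose nodes are markers, connect two markers when their pairwise
Pearson correlation exceeds a threshold (default 0.7, strict), and keep one
representative per connected component.  A known causal marker is kept as
its component's representative so its rank stays assessable; otherwise the
representative is drawn uniformly at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

__all__ = [
    "ComponentPartition",
    "pairwise_marker_correlation",
    "build_components",
    "select_representatives",
    "IndependentMarkerFilter",
]


@dataclass
class ComponentPartition:
    """Disjoint marker components plus one representative per component."""

    components: list[set[str]]
    representatives: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.representatives) != len(self.components):
            raise ValueError("one representative required per component")
        for rep, comp in zip(self.representatives, self.components):
            if rep not in comp:
                raise ValueError(f"representative {rep!r} not in its component")
        seen: set[str] = set()
        for comp in self.components:
            if seen & comp:
                raise ValueError("components are not disjoint")
            seen |= comp

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self, marker_id: str) -> set[str]:
        for comp in self.components:
            if marker_id in comp:
                return comp
        raise KeyError(marker_id)


def pairwise_marker_correlation(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between dosage columns.

    Zero-variance markers get correlation 0 to every other marker (with a
    warning); the diagonal is always 1.
    """
    X = G.dosage_float() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    m = X.shape[1]
    if np.isnan(X).any():
        import pandas as pd

        corr = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.atleast_2d(np.corrcoef(X, rowvar=False))
    zero_var = np.nanstd(X, axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance marker(s); correlations set to 0",
            UserWarning,
            stacklevel=2,
        )
    corr = np.where(np.isnan(corr), 0.0, corr)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def build_components(
    corr: np.ndarray,
    marker_ids: Sequence[str] | None = None,
    threshold: float = 0.7,
    signed: bool = False,
) -> ComponentPartition:
    """Connected components of the marker graph with edges where corr > threshold.

    The inequality is strict: a correlation exactly equal to the threshold
    does not create an edge.  By default the absolute correlation is used
    (anti-correlated markers are equally redundant); ``signed=True``
    restricts edges to positive correlations.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    m = corr.shape[0]
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    if len(marker_ids) != m:
        raise ValueError("marker_ids length must match matrix size")
    weight = corr if signed else np.abs(corr)
    g = nx.Graph()
    g.add_nodes_from(marker_ids)
    ii, jj = np.where(np.triu(weight, k=1) > threshold)
    g.add_edges_from((marker_ids[i], marker_ids[j]) for i, j in zip(ii, jj))
    order = {mid: k for k, mid in enumerate(marker_ids)}
    components = sorted(
        (set(c) for c in nx.connected_components(g)),
        key=lambda c: min(order[x] for x in c),
    )
    # placeholder representatives (first marker by input order); callers use
    # select_representatives for the causal-aware, seeded choice
    reps = [min(c, key=order.__getitem__) for c in components]
    return ComponentPartition(components, reps, threshold)


def select_representatives(
    partition: ComponentPartition,
    causal_ids: Iterable[str] = (),
    seed: int | None = None,
) -> list[str]:
    """One marker per component: the causal member if present, else random.

    Raises if a component contains more than one causal id (the scheme
    assumes at most one causal marker per component).
    """
    causal = set(causal_ids)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for comp in partition.components:
        hits = sorted(comp & causal)
        if len(hits) > 1:
            raise ValueError(
                f"component {sorted(comp)} contains {len(hits)} causal markers: {hits}"
            )
        if hits:
            out.append(hits[0])
        else:
            members = sorted(comp)
            out.append(members[int(rng.integers(0, len(members)))])
    return out


class IndependentMarkerFilter(BaseEstimator):
    """Transformer keeping one representative marker per correlation component.

    Parameters
    ----------
    threshold : correlation cutoff; markers with |r| (or r when
        ``signed=True``) strictly above it are connected.
    signed : use signed rather than absolute correlation for edges.
    random_state : seed for the random representative choice.

    Attributes
    ----------
    partition_ : ComponentPartition
    selected_markers_ : list of representative marker ids, causal-aware.
    """

    def __init__(self, threshold: float = 0.7, signed: bool = False, random_state: int | None = None):
        self.threshold = threshold
        self.signed = signed
        self.random_state = random_state

    def fit(self, G: GenotypeMatrix, causal_ids: Iterable[str] = ()):
        corr = pairwise_marker_correlation(G)
        zero_var = np.nanstd(G.dosage_float(), axis=0) == 0
        keep = [m for m, z in zip(G.marker_ids, zero_var) if not z]
        if len(keep) < len(G.marker_ids):
            idx = np.flatnonzero(~zero_var)
            corr = corr[np.ix_(idx, idx)]
        self.partition_ = build_components(
            corr, keep, threshold=self.threshold, signed=self.signed
        )
        self.partition_.representatives = select_representatives(
            self.partition_, causal_ids, seed=self.random_state
        )
        self.selected_markers_ = list(self.partition_.representatives)
        return self

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        order = {m: k for k, m in enumerate(G.marker_ids)}
        kept = sorted(self.selected_markers_, key=order.__getitem__)
        return G.subset_markers(kept)

    def fit_transform(self, G: GenotypeMatrix, causal_ids: Iterable[str] = ()) -> GenotypeMatrix:
        return self.fit(G, causal_ids).transform(G)
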