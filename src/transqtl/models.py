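"""Marker-ranking models: random forest, gradient boosting, regression.

Each ranker scores every marker's contribution to trait prediction and
converts scores to ranks (1 = most important, ties get their average
rank).  Ranks are averaged over repeated iterations: in *weighted* mode
each iteration fits on a fresh probabilistic resample of the hybrid panel
(see :mod:`transqtl.weighting`); in *unweighted* mode iterations differ
only in the model seed.

Random forest uses permutation importance on out-of-bag (OOB) samples: a
marker's score is the increase in OOB prediction error when its column is
permuted.  Gradient boosting uses total gain, the summed loss reduction of
all splits on the marker.  The regression baseline is the single-marker
additive linear model: one OLS fit per marker, ranked by the slope
t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .genotypes import GenotypeMatrix
from .pheno_sim import PhenotypeVector
from .weighting import SampleWeights, resample_training_set

__all__ = [
    "RFConfig",
    "GBMConfig",
    "RankTable",
    "fit_rf_importance",
    "fit_gbm_importance",
    "average_rank",
    "regression_ranks",
    "RandomForestMarkerRanker",
    "GradientBoostingMarkerRanker",
    "RegressionMarkerRanker",
]


@dataclass
class RFConfig:
    """Random-forest settings: 1000 trees, RMSE loss, OOB permutation importance.

    ``max_features`` follows the 1/3-of-predictors regression convention of
    the reference random-forest ecosystem.
    """

    n_trees: int = 1000
    max_features: float | str = 1.0 / 3.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class GBMConfig:
    """Gradient-boosting settings: squared-error loss, gain importance."""

    eta: float = 0.3
    n_rounds: int = 100
    max_depth: int = 6
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must be in (0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class RankTable:
    """Per-marker importance rank averaged over model iterations."""

    marker_ids: list[str]
    avg_rank: np.ndarray
    n_iterations: int
    model_label: str

    def __post_init__(self) -> None:
        self.avg_rank = np.asarray(self.avg_rank, dtype=float)
        m = len(self.marker_ids)
        if self.avg_rank.shape != (m,):
            raise ValueError("avg_rank length must match marker_ids")
        if ((self.avg_rank < 1) | (self.avg_rank > m)).any():
            raise ValueError("average ranks must lie in [1, n_markers]")

    def rank_of(self, marker_id: str) -> float:
        return float(self.avg_rank[self.marker_ids.index(marker_id)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "avg_rank": self.avg_rank,
                "model_label": self.model_label,
            }
        ).sort_values("avg_rank", ignore_index=True)


def _validate_training(X: np.ndarray, y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant; cannot train a ranking model")
    if X.shape[1] < 1:
        raise ValueError("at least one marker required")


def _forest_oob_predictions(forest, leaves, oob_mask, values, counts):
    """Aggregate per-sample predictions over the trees where it is OOB."""
    preds = values[np.arange(leaves.shape[1])[None, :], leaves]  # (n, T)
    num = (preds * oob_mask).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, num / np.maximum(counts, 1), num)


def fit_rf_importance(
    G: GenotypeMatrix | np.ndarray,
    pheno: PhenotypeVector | np.ndarray,
    cfg: RFConfig | None = None,
) -> np.ndarray:
    """Permutation-on-out-of-bag importance from a random forest.

    Fits ``n_trees`` regression trees, then for each marker permutes its
    column once and recomputes the forest's out-of-bag prediction error
    (MSE, i.e. squared RMSE); the importance is the error increase.
    Markers the forest never uses score ~0; larger is more important.
    """
    cfg = cfg or RFConfig()
    cfg.validate()
    X = G.dosage_float() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    y = pheno.values if isinstance(pheno, PhenotypeVector) else np.asarray(pheno, float)
    _validate_training(X, y)
    n, m = X.shape
    rng = np.random.default_rng(cfg.seed)
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        bootstrap=True,
        n_jobs=1,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    forest.fit(X, y)

    T = cfg.n_trees
    oob_mask = np.ones((n, T), dtype=bool)
    for t, inbag in enumerate(forest.estimators_samples_):
        oob_mask[inbag, t] = False
    counts = oob_mask.sum(axis=1)

    # pad per-tree leaf values into one (T, max_nodes) table so predictions
    # reduce to a leaf-id gather after a single batched forest.apply call
    max_nodes = max(e.tree_.node_count for e in forest.estimators_)
    values = np.zeros((T, max_nodes))
    for t, e in enumerate(forest.estimators_):
        values[t, : e.tree_.node_count] = e.tree_.value.ravel()

    Xf = np.asarray(X, dtype=np.float32)
    perm = rng.permutation(n)
    blocks = [Xf]
    for j in range(m):
        Xp = Xf.copy()
        Xp[:, j] = Xp[perm, j]
        blocks.append(Xp)
    leaves_all = forest.apply(np.vstack(blocks)).reshape(m + 1, n, T)

    def oob_mse(leaves) -> float:
        yhat = _forest_oob_predictions(forest, leaves, oob_mask, values, counts)
        ok = counts > 0
        return float(np.mean((y[ok] - yhat[ok]) ** 2))

    base = oob_mse(leaves_all[0])
    return np.array([oob_mse(leaves_all[j + 1]) - base for j in range(m)])


def fit_gbm_importance(
    G: GenotypeMatrix | np.ndarray,
    pheno: PhenotypeVector | np.ndarray,
    cfg: GBMConfig | None = None,
) -> np.ndarray:
    """Total-gain importance from a gradient-boosted tree ensemble.

    Squared-error loss, learning rate ``eta``; a marker's gain is the
    summed objective improvement over every split on it, 0 if never split
    on.
    """
    import xgboost as xgb

    cfg = cfg or GBMConfig()
    cfg.validate()
    X = G.dosage_float() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    y = pheno.values if isinstance(pheno, PhenotypeVector) else np.asarray(pheno, float)
    _validate_training(X, y)
    m = X.shape[1]
    feature_names = [f"f{j}" for j in range(m)]
    dtrain = xgb.DMatrix(X, label=y, feature_names=feature_names, nthread=1)
    params = {
        "eta": cfg.eta,
        "max_depth": cfg.max_depth,
        "objective": "reg:squarederror",
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(cfg.seed) % (2**31 - 1) if cfg.seed is not None else 0,
    }
    bst = xgb.train(params, dtrain, num_boost_round=cfg.n_rounds)
    gains = bst.get_score(importance_type="total_gain")
    return np.array([gains.get(name, 0.0) for name in feature_names])


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = largest score; ties get their average rank."""
    return stats.rankdata(-np.asarray(scores, float), method="average")


def _iteration_seed(base: int | None, i: int) -> int:
    ss = np.random.SeedSequence([0 if base is None else int(base), i])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def average_rank(
    G: GenotypeMatrix,
    pheno: PhenotypeVector,
    model: str = "rf",
    cfg: RFConfig | GBMConfig | None = None,
    weights: SampleWeights | None = None,
    n_iter: int = 100,
    seed: int | None = None,
) -> RankTable:
    """Importance ranks averaged over repeated model iterations.

    With ``weights``, every iteration first draws a fresh probabilistic
    resample of the training samples; without, each iteration refits on
    the full panel with a fresh model seed.
    """
    if model not in ("rf", "gbm"):
        raise ValueError("model must be 'rf' or 'gbm'")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    fit = fit_rf_importance if model == "rf" else fit_gbm_importance
    base_cfg = cfg or (RFConfig() if model == "rf" else GBMConfig())
    rank_sum = np.zeros(G.n_markers)
    for i in range(n_iter):
        it_seed = _iteration_seed(seed, i)
        if weights is not None:
            Gi, pi = resample_training_set(G, pheno, weights, seed=it_seed)
        else:
            Gi, pi = G, pheno
        it_cfg = replace(base_cfg, seed=it_seed)
        scores = fit(Gi, pi, it_cfg)
        rank_sum += _scores_to_ranks(scores)
    label = model + ("_weighted" if weights is not None else "")
    return RankTable(list(G.marker_ids), rank_sum / n_iter, n_iter, label)


def regression_ranks(G: GenotypeMatrix, pheno: PhenotypeVector) -> RankTable:
    """Single-marker additive linear-model baseline.

    For every marker, OLS of the phenotype on dosage; markers are ranked by
    the ascending two-sided t-test p-value of the slope.  Zero-variance
    markers get p = 1.  Equivalent to the additive association scan of
    standard GWAS tooling, without covariates.
    """
    n = G.n_samples
    if n < 3:
        raise ValueError("regression needs at least 3 samples")
    X = G.dosage_float()
    y = pheno.values
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    yc = y - y.mean()
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(Xc), 0.0, Xc)
    ssx = (Xc**2).sum(axis=0)
    ssy = float((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ssx > 0, (Xc.T @ yc) / np.sqrt(ssx * ssy), 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(ssx > 0, pvals, 1.0)
    ranks = stats.rankdata(pvals, method="average")
    return RankTable(list(G.marker_ids), ranks, 1, "regression")


class _BaseMarkerRanker(BaseEstimator):
    """Shared fit machinery for the sklearn-style ranking estimators."""

    def fit(
        self,
        G: GenotypeMatrix,
        pheno: PhenotypeVector,
        sample_weights: SampleWeights | None = None,
    ):
        table = self._rank(G, pheno, sample_weights)
        self.rank_table_ = table
        self.marker_ids_ = list(table.marker_ids)
        self.avg_rank_ = table.avg_rank
        self.ranking_ = [table.marker_ids[i] for i in np.argsort(table.avg_rank)]
        return self


class RandomForestMarkerRanker(_BaseMarkerRanker):
    """Random-forest marker ranking with OOB permutation importance."""

    def __init__(
        self,
        n_trees: int = 1000,
        max_features: float | str = 1.0 / 3.0,
        n_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.n_iter = n_iter
        self.random_state = random_state

    def _rank(self, G, pheno, sample_weights):
        cfg = RFConfig(n_trees=self.n_trees, max_features=self.max_features)
        return average_rank(
            G, pheno, "rf", cfg, sample_weights, self.n_iter, self.random_state
        )


class GradientBoostingMarkerRanker(_BaseMarkerRanker):
    """Gradient-boosting marker ranking with total-gain importance."""

    def __init__(
        self,
        eta: float = 0.3,
        n_rounds: int = 100,
        max_depth: int = 6,
        n_iter: int = 100,
        random_state: int | None = None,
    ):
        self.eta = eta
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.n_iter = n_iter
        self.random_state = random_state

    def _rank(self, G, pheno, sample_weights):
        cfg = GBMConfig(eta=self.eta, n_rounds=self.n_rounds, max_depth=self.max_depth)
        return average_rank(
            G, pheno, "gbm", cfg, sample_weights, self.n_iter, self.random_state
        )


class RegressionMarkerRanker(_BaseMarkerRanker):
    """Single-marker OLS baseline ranker (p-value order)."""

    def __init__(self):
        pass

    def _rank(self, G, pheno, sample_weights):
        if sample_weights is not None:
            raise ValueError("the regression baseline is not sample-weighted")
        return regression_ranks(G, pheno)
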