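"""Supervised arm: Monte-Carlo cross-validated random-forest relevance.

A random forest is trained repeatedly to map the block-diagonal subject x
(odor, property) rating matrix onto the olfactory diagnosis.  Each run draws
a fresh training subset (2/3 of the cohort) stratified so that both diagnoses
and all four odor sets keep their proportions, fits a forest (1000 trees,
mtry = round(0.5*sqrt(n_features)), at most seven leaf nodes per tree by
default), and records

* the per-feature mean decrease in Gini impurity,
* the per-feature -log(p) of a Wilcoxon-Mann-Whitney test between diagnoses
  computed on the same training subjects (within the feature's odor-set
  block, since only those subjects rated it), and
* the AUC-ROC on the held-out third.

Importance and -log(p) are averaged over runs into two odor x property
matrices.  Rank-transforming both and multiplying the ranks fuses them under
an AND semantic: a cell scores high only if it is important to the forest AND
shows a comparatively large statistical effect.  An ABC analysis of the rank
products selects the most relevant (set A) cells; repeating with inverted
ranks selects the least relevant ones.  Training on permuted diagnosis labels
provides the guessing-level negative control.

Out-of-block cells carry no rating; for the single-forest mode they are
encoded as a constant sentinel (0, outside the 1-5 grade scale), which makes
them useless as split variables.  A per-set-forests mode is available behind
``block_mode="per_set"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .abc_analysis import abc_partition
from .cohort import HYPOSMIC, NORMOSMIC
from .prepare import FeatureMatrix

__all__ = [
    "RunConfig",
    "RelevanceMatrices",
    "SelectionResult",
    "MonteCarloRelevance",
    "stratified_split",
    "run_relevance",
    "permuted_control",
    "rank_product_select",
    "mtry_from_features",
]

logger = logging.getLogger(__name__)

SENTINEL = 0.0  # out-of-block encoding, outside the 1..5 grade scale


def mtry_from_features(n_features: int) -> int:
    """Features tried per split: round(0.5 * sqrt(n_features)), at least 1."""
    return max(1, int(round(0.5 * np.sqrt(n_features))))


@dataclass(frozen=True)
class RunConfig:
    """Monte-Carlo cross-validation configuration.

    Defaults are the study's settings (1000 runs, 1000 trees, 2/3 training
    fraction, seven-node trees); tests and the acceptance runs scale
    ``n_runs``/``n_trees`` down for desk-scale runtime.
    """

    n_runs: int = 1000
    train_fraction: float = 2.0 / 3.0
    n_trees: int = 1000
    max_leaf_nodes: int = 7
    seed: int = 0
    block_mode: str = "sentinel"  # or "per_set"
    balanced: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1 or self.n_trees < 1:
            raise ValueError("n_runs and n_trees must be positive")
        if self.block_mode not in ("sentinel", "per_set"):
            raise ValueError("block_mode must be 'sentinel' or 'per_set'")


@dataclass
class RelevanceMatrices:
    """Run-averaged odor x property relevance: importance and -log(p)."""

    importance_mean: pd.DataFrame  # odor x property
    neglogp_mean: pd.DataFrame  # odor x property

    def __post_init__(self) -> None:
        if self.importance_mean.shape != self.neglogp_mean.shape:
            raise ValueError("relevance matrices must share their shape")

    @property
    def rank_product(self) -> pd.DataFrame:
        """Elementwise product of the ascending rank transforms (AND fusion)."""
        return _rank_matrix(self.importance_mean) * _rank_matrix(self.neglogp_mean)


def _rank_matrix(m: pd.DataFrame, invert: bool = False) -> pd.DataFrame:
    vals = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("relevance matrices must be finite")
    flat = -vals.ravel() if invert else vals.ravel()
    ranks = stats.rankdata(flat, method="average").reshape(vals.shape)
    return pd.DataFrame(ranks, index=m.index, columns=m.columns)


def stratified_split(
    y: pd.Series,
    odor_sets: pd.Series,
    fraction: float,
    rng: np.random.Generator,
    balanced: bool = False,
) -> tuple[list, list]:
    """Split subjects into train/test preserving diagnosis x odor-set strata.

    With ``balanced=False`` each stratum contributes ``round(fraction * size)``
    subjects (clamped so that both train and test keep at least one) to the
    training set — proportional representation.  With ``balanced=True`` every
    stratum contributes the same number, ``round(fraction * smallest stratum)``,
    so that no odor set or diagnosis dominates training merely by being larger;
    the test set is always the complement.  Returns (train_ids, test_ids).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1); both splits must be non-empty")
    train: list = []
    test: list = []
    strata = pd.DataFrame({"y": y, "s": odor_sets})
    groups = list(strata.groupby(["y", "s"], sort=True))
    sizes = [len(block) for _, block in groups]
    if min(sizes) < 2:
        raise ValueError("every diagnosis x odor-set stratum needs at least 2 subjects")
    n_balanced = int(np.clip(round(fraction * min(sizes)), 1, min(sizes) - 1))
    for _, block in groups:
        ids = np.asarray(block.index)
        n = len(ids)
        n_train = n_balanced if balanced else int(np.clip(round(fraction * n), 1, n - 1))
        picked = rng.choice(n, size=n_train, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[picked] = True
        train.extend(ids[mask])
        test.extend(ids[~mask])
    return train, test


class MonteCarloRelevance(BaseEstimator):
    """Monte-Carlo cross-validated random-forest relevance estimator.

    Parameters mirror :class:`RunConfig`.  ``permute=True`` shuffles the
    diagnosis labels of each training subset before fitting (negative
    control); importance/-log(p) matrices are then not meaningful and only
    the AUC summary should be used.

    Fitted attributes: ``importance_mean_`` and ``neglogp_mean_`` (odor x
    property DataFrames), ``relevance_`` (:class:`RelevanceMatrices`),
    ``auc_runs_``, ``auc_median_``, ``auc_ci95_``, ``mtry_``.
    """

    def __init__(
        self,
        n_runs: int = 1000,
        train_fraction: float = 2.0 / 3.0,
        n_trees: int = 1000,
        max_leaf_nodes: int = 7,
        block_mode: str = "sentinel",
        balanced: bool = False,
        permute: bool = False,
        random_state: int | None = 0,
    ):
        self.n_runs = n_runs
        self.train_fraction = train_fraction
        self.n_trees = n_trees
        self.max_leaf_nodes = max_leaf_nodes
        self.block_mode = block_mode
        self.balanced = balanced
        self.permute = permute
        self.random_state = random_state

    # -- internals -------------------------------------------------------------

    def _wilcoxon_neglogp(self, X: pd.DataFrame, y: pd.Series) -> np.ndarray:
        """Two-sided WMW -log(p) per feature, within each odor-set block."""
        out = np.full(X.shape[1], np.nan)
        col_sets = X.columns.get_level_values("odor_set")
        for s in col_sets.unique():
            cols = np.nonzero(col_sets == s)[0]
            block = X.iloc[:, cols]
            in_set = block.notna().any(axis=1)
            sub = block[in_set]
            labels = y[in_set]
            a = sub[labels == NORMOSMIC].to_numpy(dtype=float)
            b = sub[labels == HYPOSMIC].to_numpy(dtype=float)
            if a.shape[0] == 0 or b.shape[0] == 0:
                out[cols] = 0.0  # p = 1: no contrast available
                continue
            both = np.vstack([a, b])
            degenerate = np.ptp(both, axis=0) == 0.0
            with np.errstate(all="ignore"):
                res = stats.mannwhitneyu(a, b, axis=0, method="asymptotic")
                p = np.asarray(res.pvalue, dtype=float)
            p[degenerate] = 1.0
            p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
            out[cols] = -np.log(p)
        return out

    def _fit_predict_one(
        self, Xs: pd.DataFrame, y: pd.Series, sets: pd.Series, seed: np.random.SeedSequence
    ) -> tuple[np.ndarray, np.ndarray, float]:
        rng = np.random.default_rng(seed)
        train_ids, test_ids = stratified_split(
            y, sets, self.train_fraction, rng, balanced=self.balanced
        )
        y_train = y.loc[train_ids]
        if self.permute:
            y_train = pd.Series(
                rng.permutation(y_train.to_numpy()), index=y_train.index
            )
        sk_seed = int(rng.integers(0, 2**31 - 1))
        importances = np.zeros(Xs.shape[1])
        test_scores = np.zeros(len(test_ids))
        col_sets = Xs.columns.get_level_values("odor_set")
        if self.block_mode == "sentinel":
            X_train = Xs.loc[train_ids].fillna(SENTINEL)
            forest = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=self.mtry_,
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=sk_seed,
                n_jobs=1,
            )
            forest.fit(X_train.to_numpy(dtype=float), y_train.to_numpy())
            importances = forest.feature_importances_
            X_test = Xs.loc[test_ids].fillna(SENTINEL)
            pos = list(forest.classes_).index(HYPOSMIC)
            test_scores = forest.predict_proba(X_test.to_numpy(dtype=float))[:, pos]
        else:  # per-set forests: one forest per odor-set block
            test_scores = np.zeros(len(test_ids))
            test_index = pd.Index(test_ids)
            for s in col_sets.unique():
                cols = col_sets == s
                tr = [i for i in train_ids if sets.loc[i] == s]
                te = [i for i in test_ids if sets.loc[i] == s]
                block_mtry = mtry_from_features(int(cols.sum()))
                forest = RandomForestClassifier(
                    n_estimators=self.n_trees,
                    max_features=block_mtry,
                    max_leaf_nodes=self.max_leaf_nodes,
                    random_state=sk_seed,
                    n_jobs=1,
                )
                forest.fit(
                    Xs.loc[tr, cols].to_numpy(dtype=float), y_train.loc[tr].to_numpy()
                )
                importances[np.nonzero(cols)[0]] = forest.feature_importances_
                pos = list(forest.classes_).index(HYPOSMIC)
                scores = forest.predict_proba(Xs.loc[te, cols].to_numpy(dtype=float))[:, pos]
                test_scores[test_index.get_indexer(te)] = scores
        # Wilcoxon on the *actual* training labels (control permutes only training)
        neglogp = self._wilcoxon_neglogp(Xs.loc[train_ids], y.loc[train_ids])
        y_test = (y.loc[test_ids] == HYPOSMIC).astype(int).to_numpy()
        auc = float(roc_auc_score(y_test, test_scores))
        return importances, neglogp, auc

    # -- sklearn surface -------------------------------------------------------

    def fit(self, X, y=None, odor_sets: pd.Series | None = None):
        """Run the Monte-Carlo loop.

        ``X`` may be a :class:`FeatureMatrix` (then ``y``/``odor_sets`` are
        taken from it) or a DataFrame with the (set, odor, property) column
        MultiIndex plus explicit ``y`` and ``odor_sets`` series.
        """
        if isinstance(X, FeatureMatrix):
            odor_sets = X.odor_sets
            y = X.y
            X = X.X
        if y is None or odor_sets is None:
            raise ValueError("y and odor_sets are required unless X is a FeatureMatrix")
        self.mtry_ = mtry_from_features(X.shape[1])
        master = np.random.SeedSequence(self.random_state)
        run_seeds = master.spawn(self.n_runs)
        imp_sum = np.zeros(X.shape[1])
        nlp_sum = np.zeros(X.shape[1])
        aucs = []
        for seed in run_seeds:
            imp, nlp, auc = self._fit_predict_one(X, y, odor_sets, seed)
            imp_sum += imp
            nlp_sum += nlp
            aucs.append(auc)
        self.auc_runs_ = np.asarray(aucs)
        self.auc_median_ = float(np.median(self.auc_runs_))
        self.auc_ci95_ = (
            float(np.percentile(self.auc_runs_, 2.5)),
            float(np.percentile(self.auc_runs_, 97.5)),
        )
        imp_mean = imp_sum / self.n_runs
        nlp_mean = nlp_sum / self.n_runs
        self.importance_mean_ = _to_odor_property(imp_mean, X.columns)
        self.neglogp_mean_ = _to_odor_property(nlp_mean, X.columns)
        self.relevance_ = RelevanceMatrices(self.importance_mean_, self.neglogp_mean_)
        return self

    def score(self, X=None, y=None) -> float:
        return self.auc_median_


def _to_odor_property(values: np.ndarray, columns: pd.MultiIndex) -> pd.DataFrame:
    """Reshape a flat per-feature vector into the odor x property matrix."""
    s = pd.Series(values, index=columns)
    table = s.unstack("property")
    # keep design order: odors by (set, first appearance), canonical properties
    odor_order = []
    for st, od, _ in columns:
        if od not in odor_order:
            odor_order.append(od)
    prop_order = []
    for _, _, p in columns:
        if p not in prop_order:
            prop_order.append(p)
    table = table.droplevel("odor_set").reindex(index=odor_order, columns=prop_order)
    return table


def run_relevance(
    matrix: FeatureMatrix, cfg: RunConfig
) -> tuple[RelevanceMatrices, np.ndarray]:
    """Monte-Carlo relevance run; returns matrices and the per-run AUC list."""
    est = MonteCarloRelevance(
        n_runs=cfg.n_runs,
        train_fraction=cfg.train_fraction,
        n_trees=cfg.n_trees,
        max_leaf_nodes=cfg.max_leaf_nodes,
        block_mode=cfg.block_mode,
        balanced=cfg.balanced,
        random_state=cfg.seed,
    ).fit(matrix)
    run_relevance.last_estimator_ = est  # for callers needing AUC summaries
    return est.relevance_, est.auc_runs_


def permuted_control(matrix: FeatureMatrix, cfg: RunConfig) -> float:
    """Median held-out AUC with training labels permuted each run."""
    est = MonteCarloRelevance(
        n_runs=cfg.n_runs,
        train_fraction=cfg.train_fraction,
        n_trees=cfg.n_trees,
        max_leaf_nodes=cfg.max_leaf_nodes,
        block_mode=cfg.block_mode,
        balanced=cfg.balanced,
        permute=True,
        random_state=cfg.seed,
    ).fit(matrix)
    return est.auc_median_


@dataclass
class SelectionResult:
    """ABC set-A cells of the rank products, in both ranking directions.

    ``most_relevant``/``least_relevant`` are (odor, property) cell lists;
    tallies count how often an odor or property occurs in each list.  Cells
    selected by both directions are dropped from both (and logged).
    """

    most_relevant: list[tuple[str, str]]
    least_relevant: list[tuple[str, str]]
    most_relevant_odors: list[str]
    least_relevant_odors: list[str]
    odor_tally_most: Counter = field(default_factory=Counter)
    odor_tally_least: Counter = field(default_factory=Counter)
    property_tally_most: Counter = field(default_factory=Counter)
    property_tally_least: Counter = field(default_factory=Counter)
    auc_median: float | None = None
    auc_ci95: tuple[float, float] | None = None
    auc_permuted_median: float | None = None


def _abc_set_a_cells(product: pd.DataFrame) -> list[tuple[str, str]]:
    flat = product.stack()
    res = abc_partition(flat.to_numpy())
    return [tuple(flat.index[i]) for i in res.set_a]


def rank_product_select(
    rel: RelevanceMatrices,
    auc_median: float | None = None,
    auc_ci95: tuple[float, float] | None = None,
    auc_permuted_median: float | None = None,
) -> SelectionResult:
    """Select the most and least diagnosis-relevant (odor, property) cells.

    Ascending ranks (largest value -> largest rank, ties averaged) of the two
    relevance matrices are multiplied; the ABC set A of the products gives the
    most relevant cells.  Inverting both rankings and repeating gives the
    least relevant cells.  Any cell claimed by both directions is removed
    from both.
    """
    product_most = _rank_matrix(rel.importance_mean) * _rank_matrix(rel.neglogp_mean)
    product_least = _rank_matrix(rel.importance_mean, invert=True) * _rank_matrix(
        rel.neglogp_mean, invert=True
    )
    most = _abc_set_a_cells(product_most)
    least = _abc_set_a_cells(product_least)
    overlap = set(most) & set(least)
    if overlap:
        logger.info("cells selected in both directions dropped: %s", sorted(overlap))
        most = [c for c in most if c not in overlap]
        least = [c for c in least if c not in overlap]
    odor_order = list(rel.importance_mean.index)
    most_odors = [o for o in odor_order if any(c[0] == o for c in most)]
    least_odors = [o for o in odor_order if any(c[0] == o for c in least)]
    return SelectionResult(
        most_relevant=most,
        least_relevant=least,
        most_relevant_odors=most_odors,
        least_relevant_odors=least_odors,
        odor_tally_most=Counter(c[0] for c in most),
        odor_tally_least=Counter(c[0] for c in least),
        property_tally_most=Counter(c[1] for c in most),
        property_tally_least=Counter(c[1] for c in least),
        auc_median=auc_median,
        auc_ci95=auc_ci95,
        auc_permuted_median=auc_permuted_median,
    )
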