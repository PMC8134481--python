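"""End-to-end two-arm pipeline on a (synthetic) rating cohort.

Chains simulation, completeness filtering, kNN imputation, the unsupervised
PCA arm, the supervised Monte-Carlo forest arm, and the consensus
intersection into one deterministic run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortDesign, EffectSpec, RatingsCohort, simulate_cohort
from .consensus import ConsensusResult, exclusive_sets, intersect_arms
from .prepare import (
    FeatureMatrix,
    MeanProfileMatrix,
    build_feature_matrix,
    build_mean_profiles,
    filter_complete,
    impute_knn,
)
from .supervised import (
    MonteCarloRelevance,
    RelevanceMatrices,
    RunConfig,
    SelectionResult,
    rank_product_select,
)
from .unsupervised import (
    PairedDistanceTable,
    ProjectionResult,
    categorize_odors,
    paired_distances,
    project_profiles,
)

__all__ = ["PipelineResult", "prepare_cohort", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the two-arm analysis produces on one cohort."""

    cohort: RatingsCohort
    excluded_subjects: list[str]
    features: FeatureMatrix
    profiles: MeanProfileMatrix
    projection: ProjectionResult
    distances: PairedDistanceTable
    unsupervised_categories: dict[str, list[str]]
    relevance: RelevanceMatrices
    selection: SelectionResult
    consensus: ConsensusResult
    auc_runs: np.ndarray


def prepare_cohort(cohort: RatingsCohort, k: int = 3) -> tuple[RatingsCohort, list[str]]:
    """Completeness filter then within-set kNN imputation."""
    filtered, excluded = filter_complete(cohort)
    return impute_knn(filtered, k=k), excluded


def run_pipeline(
    design: CohortDesign,
    effect: EffectSpec | None = None,
    cfg: RunConfig | None = None,
    with_permuted_control: bool = False,
) -> PipelineResult:
    """Simulate a cohort and run both analysis arms plus their consensus."""
    cfg = cfg if cfg is not None else RunConfig(seed=design.seed)
    cohort = simulate_cohort(design, effect)
    imputed, excluded = prepare_cohort(cohort)

    features = build_feature_matrix(imputed)
    profiles = build_mean_profiles(imputed)

    projection = project_profiles(profiles)
    distances = paired_distances(projection)
    categories = categorize_odors(distances)

    est = MonteCarloRelevance(
        n_runs=cfg.n_runs,
        train_fraction=cfg.train_fraction,
        n_trees=cfg.n_trees,
        max_leaf_nodes=cfg.max_leaf_nodes,
        block_mode=cfg.block_mode,
        balanced=cfg.balanced,
        random_state=cfg.seed,
    ).fit(features)
    permuted_median = None
    if with_permuted_control:
        perm = MonteCarloRelevance(
            n_runs=cfg.n_runs,
            train_fraction=cfg.train_fraction,
            n_trees=cfg.n_trees,
            max_leaf_nodes=cfg.max_leaf_nodes,
            block_mode=cfg.block_mode,
            balanced=cfg.balanced,
            permute=True,
            random_state=cfg.seed,
        ).fit(features)
        permuted_median = perm.auc_median_
    selection = rank_product_select(
        est.relevance_,
        auc_median=est.auc_median_,
        auc_ci95=est.auc_ci95_,
        auc_permuted_median=permuted_median,
    )

    excl_d, excl_n = exclusive_sets(selection)
    consensus = intersect_arms(
        excl_d,
        excl_n,
        categories,
        odor_universe=[o for (_, o) in imputed.odor_order()],
    )
    return PipelineResult(
        cohort=cohort,
        excluded_subjects=excluded,
        features=features,
        profiles=profiles,
        projection=projection,
        distances=distances,
        unsupervised_categories=categories,
        relevance=est.relevance_,
        selection=selection,
        consensus=consensus,
        auc_runs=est.auc_runs_,
    )
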