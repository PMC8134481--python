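"""Analysis matrices from a ratings cohort.

Turns the long-form cohort into the two matrices the analysis arms consume:

* the subject-level feature matrix — subjects x (odor set, odor, property),
  block-diagonal because each subject rated only the odors of their own set
  (146 x 280 for the default design), repetitions collapsed by mean;
* the diagnosis-stratified mean-profile matrix — one row per
  (odor, diagnosis) pair, one column per property (80 x 7 by default).

Before either matrix is built, subjects who completed fewer than two thirds
of their required ratings are excluded and remaining gaps are filled by
k-nearest-neighbor imputation (k = 3) within the subject's own odor set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .cohort import CohortError, RatingsCohort, HYPOSMIC, NORMOSMIC

__all__ = [
    "FeatureMatrix",
    "MeanProfileMatrix",
    "filter_complete",
    "impute_knn",
    "build_feature_matrix",
    "build_mean_profiles",
    "feature_matrix_to_csv",
    "csv_to_feature_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Subjects x (odor_set, odor_id, property) mean ratings.

    ``X`` has a three-level column MultiIndex ordered (set, odor, property);
    cells outside a subject's own odor-set block are NaN — structurally
    absent, not zero.  ``y`` holds the diagnosis per subject.
    """

    X: pd.DataFrame
    y: pd.Series

    @property
    def odor_sets(self) -> pd.Series:
        """Odor set of each subject, derived from the filled block."""
        sets = self.X.columns.get_level_values(0)
        filled = self.X.notna()
        out = {}
        for s in sets.unique():
            block = filled.loc[:, sets == s]
            for sid in block.index[block.any(axis=1)]:
                out[sid] = int(s)
        return pd.Series(out, name="odor_set").reindex(self.X.index)


@dataclass
class MeanProfileMatrix:
    """(odor, diagnosis) x property mean grades; 80 x 7 by default."""

    values: pd.DataFrame  # MultiIndex rows (odor_id, diagnosis), property columns
    odor_sets: dict[str, int]  # odor -> set, for bookkeeping


def filter_complete(
    cohort: RatingsCohort, min_fraction: float = 2.0 / 3.0
) -> tuple[RatingsCohort, list[str]]:
    """Keep subjects whose non-missing rating fraction is >= ``min_fraction``.

    Returns the filtered cohort and the list of excluded subject ids.
    """
    if not 0 < min_fraction <= 1:
        raise CohortError("min_fraction must be in (0, 1]")
    if len(cohort.frame) == 0:
        logger.warning("filter_complete called on an empty cohort")
        return cohort.copy(), []
    frac = cohort.completeness()
    excluded = sorted(frac.index[frac < min_fraction])
    if excluded:
        logger.info("excluding %d incomplete subjects: %s", len(excluded), excluded)
    kept = cohort.frame[~cohort.frame["subject_id"].isin(excluded)].reset_index(drop=True)
    return RatingsCohort(kept, cohort.rating_scale), excluded


def impute_knn(cohort: RatingsCohort, k: int = 3) -> RatingsCohort:
    """Fill missing grades by kNN within each odor set.

    Subjects are rows, (odor, property, repetition) cells are columns; the
    neighbor metric is Euclidean distance over mutually observed cells scaled
    by the overlap size, and the imputed value is the distance-weighted mean
    of the k nearest neighbors.  When no neighbor shares an observed cell the
    imputer falls back to the column mean.  Observed values are never altered.
    """
    if k < 1:
        raise CohortError("k must be >= 1")
    frame = cohort.frame
    if len(frame) == 0:
        return cohort.copy()
    pieces = []
    for s, block in frame.groupby("odor_set", sort=True):
        wide = block.pivot_table(
            index="subject_id",
            columns=["odor_id", "property", "repetition"],
            values="grade",
            dropna=False,
        )
        if wide.isna().any().any():
            if len(wide) < k + 1:
                raise CohortError(
                    f"odor set {s} has {len(wide)} subjects; need at least {k + 1} for kNN"
                )
            imputer = KNNImputer(n_neighbors=k, weights="distance")
            lo, hi = cohort.rating_scale
            # weighted means stay within the scale mathematically; clip float error
            filled = pd.DataFrame(
                np.clip(imputer.fit_transform(wide.to_numpy()), lo, hi),
                index=wide.index,
                columns=wide.columns,
            )
        else:
            filled = wide
        long = filled.stack(["odor_id", "property", "repetition"], future_stack=True)
        long.name = "grade"
        pieces.append(long.reset_index().assign(odor_set=int(s)))
    merged = pd.concat(pieces, ignore_index=True)
    meta = frame.drop_duplicates("subject_id")[["subject_id", "diagnosis"]]
    out = merged.merge(meta, on="subject_id", how="left")
    # restore the original record order and column layout
    key_cols = ["subject_id", "odor_id", "property", "repetition"]
    original = frame[key_cols].copy()
    original["_order"] = np.arange(len(original))
    out = out.merge(original, on=key_cols, how="left").sort_values("_order")
    out = out.drop(columns="_order").reset_index(drop=True)
    out = out[list(frame.columns)]
    return RatingsCohort(out, cohort.rating_scale)


def build_feature_matrix(cohort: RatingsCohort) -> FeatureMatrix:
    """Collapse repetitions by mean into the block-diagonal feature matrix.

    Column order is deterministic: odor set ascending, odors in design order
    within each set, properties in canonical order.
    """
    frame = cohort.frame
    if frame["grade"].isna().any():
        raise CohortError("cohort must be imputed before building the feature matrix")
    odor_to_set = dict(
        frame[["odor_id", "odor_set"]].drop_duplicates().itertuples(index=False)
    )
    subj_sets = frame.drop_duplicates("subject_id").set_index("subject_id")["odor_set"]
    bad = frame[frame["odor_set"] != frame["odor_id"].map(odor_to_set)]
    if len(bad):
        raise CohortError("subjects rated odors outside their own odor set")

    cell_means = (
        frame.groupby(["subject_id", "odor_set", "odor_id", "property"], sort=False)["grade"]
        .mean()
        .reset_index()
    )
    wide = cell_means.pivot_table(
        index="subject_id",
        columns=["odor_set", "odor_id", "property"],
        values="grade",
        dropna=False,
    )
    props = cohort.property_order()
    cols = pd.MultiIndex.from_tuples(
        [(s, o, p) for (s, o) in cohort.odor_order() for p in props],
        names=["odor_set", "odor_id", "property"],
    )
    wide = wide.reindex(columns=cols)
    subj_order = list(pd.unique(frame["subject_id"]))
    wide = wide.reindex(index=subj_order)
    diag = frame.drop_duplicates("subject_id").set_index("subject_id")["diagnosis"]
    return FeatureMatrix(X=wide, y=diag.reindex(wide.index))


def build_mean_profiles(cohort: RatingsCohort) -> MeanProfileMatrix:
    """Average grades per (odor, diagnosis) over subjects and repetitions."""
    frame = cohort.frame
    if frame["grade"].isna().any():
        raise CohortError("cohort must be imputed before building mean profiles")
    sets = frame["odor_set"].unique()
    for s in sets:
        diags = set(frame.loc[frame["odor_set"] == s, "diagnosis"].unique())
        if not {NORMOSMIC, HYPOSMIC} <= diags:
            raise CohortError(
                f"odor set {s} lacks one diagnosis group ({sorted(diags)}); "
                "mean profiles need both"
            )
    merged = frame[["odor_id", "property", "diagnosis", "grade"]]
    table = merged.pivot_table(
        index=["odor_id", "diagnosis"], columns="property", values="grade", aggfunc="mean"
    )
    props = cohort.property_order()
    table = table.reindex(columns=props)
    odor_order = [o for (_, o) in cohort.odor_order()]
    rows = pd.MultiIndex.from_tuples(
        [(o, d) for o in odor_order for d in (NORMOSMIC, HYPOSMIC)],
        names=["odor_id", "diagnosis"],
    )
    table = table.reindex(index=rows)
    odor_to_set = {
        o: int(s)
        for o, s in frame[["odor_id", "odor_set"]].drop_duplicates().itertuples(index=False)
    }
    return MeanProfileMatrix(values=table, odor_sets=odor_to_set)


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Wide CSV: one row per subject, diagnosis first, then set|odor|property columns."""
    flat = fm.X.copy()
    flat.columns = [f"{s}|{o}|{p}" for s, o, p in fm.X.columns]
    flat.insert(0, "diagnosis", fm.y)
    flat.to_csv(path, index_label="subject_id")


def csv_to_feature_matrix(path: str | Path) -> FeatureMatrix:
    flat = pd.read_csv(path, index_col="subject_id")
    y = flat.pop("diagnosis")
    tuples = []
    for c in flat.columns:
        s, o, p = c.split("|")
        tuples.append((int(s), o, p))
    flat.columns = pd.MultiIndex.from_tuples(tuples, names=["odor_set", "odor_id", "property"])
    return FeatureMatrix(X=flat, y=y)
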