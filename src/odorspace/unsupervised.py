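"""Unsupervised arm: PCA of diagnosis-stratified mean odor profiles.

The 80 x 7 matrix of mean ratings (40 odors x 2 olfactory diagnoses, 7
perceptual properties) is projected by principal component analysis on
centered, unscaled data.  Each odor contributes two points — its mean profile
as rated by normosmic and by hyposmic subjects — and the Euclidean distance
between the paired projections on the retained component plane measures how
differently the two groups perceive that odor.  An ABC analysis of these
distances then categorizes odors into distinctive (set A, largest
displacements), intermediate (B) and non-distinctive (C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .abc_analysis import abc_partition
from .prepare import MeanProfileMatrix

__all__ = [
    "ProfilePCA",
    "ProjectionResult",
    "PairedDistanceTable",
    "project_profiles",
    "paired_distances",
    "categorize_odors",
]


@dataclass
class ProjectionResult:
    """PCA of mean profiles: scores, loadings, variance and contributions.

    ``scores`` covers the retained components only; ``loadings``,
    ``explained_variance_fraction`` and ``contributions`` cover the full
    decomposition so the variance fractions sum to one.
    """

    scores: pd.DataFrame  # (odor, diagnosis) x retained components
    loadings: pd.DataFrame  # property x all components
    explained_variance_fraction: pd.Series
    contributions: pd.DataFrame  # property x components, percent (sums to 100)
    n_components: int


class ProfilePCA(TransformerMixin, BaseEstimator):
    """Centered, unscaled PCA with a deterministic sign convention.

    The full decomposition is always computed; ``n_components`` only selects
    how many coordinates :meth:`transform` returns.  Each component's sign is
    fixed so that its largest-magnitude loading is positive, making score
    tables reproducible across BLAS backends.

    Attributes (after ``fit``): ``loadings_`` (property x component),
    ``explained_variance_ratio_`` (sums to 1), ``contributions_``
    (squared-loading share per component, in percent), ``mean_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        n_feat = X.shape[1]
        if not 1 <= self.n_components <= n_feat:
            raise ValueError(f"n_components must be in [1, {n_feat}]")
        variances = X.var(axis=0, ddof=1)
        if np.allclose(variances, 0.0):
            degenerate = list(X.columns[variances <= 0])
            raise ValueError(f"matrix has no variance; degenerate columns: {degenerate}")
        self._pca = PCA(n_components=min(X.shape[0] - 1, n_feat))
        self._pca.fit(X.to_numpy(dtype=float))
        comps = self._pca.components_.copy()  # (k, p) unit rows
        signs = np.ones(comps.shape[0])
        for i, row in enumerate(comps):
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                signs[i] = -1.0
        comps *= signs[:, None]
        self._signs = signs
        comp_names = [f"PC{i + 1}" for i in range(comps.shape[0])]
        self.feature_names_in_ = np.asarray(X.columns)
        self.loadings_ = pd.DataFrame(comps.T, index=X.columns, columns=comp_names)
        self.explained_variance_ratio_ = pd.Series(
            self._pca.explained_variance_ratio_, index=comp_names
        )
        contrib = self.loadings_**2
        self.contributions_ = 100.0 * contrib / contrib.sum(axis=0)
        self.mean_ = self._pca.mean_
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        scores = self._pca.transform(X.to_numpy(dtype=float)) * self._signs
        cols = list(self.loadings_.columns[: self.n_components])
        return pd.DataFrame(scores[:, : self.n_components], index=X.index, columns=cols)


def project_profiles(profiles: MeanProfileMatrix, n_components: int = 2) -> ProjectionResult:
    """Project the mean-profile matrix onto its principal components."""
    table = profiles.values
    est = ProfilePCA(n_components=n_components).fit(table)
    return ProjectionResult(
        scores=est.transform(table),
        loadings=est.loadings_,
        explained_variance_fraction=est.explained_variance_ratio_,
        contributions=est.contributions_,
        n_components=n_components,
    )


@dataclass
class PairedDistanceTable:
    """Per-odor Euclidean distance between its two diagnosis projections."""

    distances: pd.Series  # index: odor_id
    retained_components: int


def paired_distances(proj: ProjectionResult) -> PairedDistanceTable:
    """Displacement of each odor between its normosmic and hyposmic points.

    Distances are taken on the retained component plane.  Raises if any odor
    does not have exactly two score rows.
    """
    scores = proj.scores
    counts = scores.groupby(level="odor_id", sort=False).size()
    unpaired = counts[counts != 2]
    if len(unpaired):
        raise ValueError(f"odors without exactly two diagnosis rows: {list(unpaired.index)}")
    out = {}
    for odor, block in scores.groupby(level="odor_id", sort=False):
        a, b = block.to_numpy(dtype=float)
        out[odor] = float(np.linalg.norm(a - b))
    return PairedDistanceTable(
        distances=pd.Series(out, name="distance"), retained_components=proj.n_components
    )


def categorize_odors(dist: PairedDistanceTable) -> dict[str, list[str]]:
    """ABC-categorize odors by their paired displacement.

    Set A (largest distances) -> ``distinctive``, B -> ``intermediate``,
    C -> ``nondistinctive``.  Exact zero distances (coinciding projections)
    are jittered to machine epsilon so the partition stays defined.
    """
    d = dist.distances.astype(float).copy()
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    zero = d == 0.0
    if zero.any():
        scale = d.max() if d.max() > 0 else 1.0
        d[zero] = np.finfo(float).eps * scale
    res = abc_partition(d.to_numpy())
    odors = list(d.index)
    return {
        "distinctive": [odors[i] for i in res.set_a],
        "intermediate": [odors[i] for i in res.set_b],
        "nondistinctive": [odors[i] for i in res.set_c],
    }
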