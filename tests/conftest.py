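import numpy as np
import pandas as pd
import pytest

import odorspace as od


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (146 subjects) with the default planted effect."""
    return od.simulate_cohort(od.CohortDesign(seed=1))


@pytest.fixture(scope="session")
def default_imputed(default_cohort):
    imputed, _ = od.prepare_cohort(default_cohort)
    return imputed


@pytest.fixture(scope="session")
def default_features(default_imputed):
    return od.build_feature_matrix(default_imputed)


@pytest.fixture(scope="session")
def default_profiles(default_imputed):
    return od.build_mean_profiles(default_imputed)


@pytest.fixture
def small_design():
    """Reduced design for fast end-to-end runs."""
    return od.CohortDesign(
        n_sets=2,
        odors_per_set=4,
        set_sizes=(14, 14),
        hyposmic_per_set=(6, 6),
        missing_rate=0.05,
        seed=5,
    )


def abc_oracle(values):
    """Brute-force geometric ABC oracle, independent of the implementation.

    Enumerates every curve point, computes distances to (0, 1) and segment
    slopes directly, and assigns items to A/B/C by the same published
    geometry: A|B at the point closest to (0, 1), B|C at the break-even
    point (last segment with slope >= 1), B empty if break-even comes first.
    """
    values = list(map(float, values))
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    total = sum(values)
    points = []
    cum = 0.0
    for rank, idx in enumerate(order, start=1):
        cum += values[idx]
        points.append((rank / n, cum / total))
    dists = [(e - 0.0) ** 2 + (yl - 1.0) ** 2 for e, yl in points]
    dmin = min(dists)
    best_ab = next(rank for rank, d in enumerate(dists, start=1) if d <= dmin + 1e-12)
    bc = 0
    prev_y = 0.0
    for rank, (e, yl) in enumerate(points, start=1):
        slope = (yl - prev_y) * n  # segment rise over 1/n run
        if slope >= 1.0 - 1e-9:
            bc = rank
        prev_y = yl
    bc = max(bc, best_ab)
    return (
        set(order[:best_ab]),
        set(order[best_ab:bc]),
        set(order[bc:]),
    )
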