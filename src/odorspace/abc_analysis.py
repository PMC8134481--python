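"""Computed ABC analysis.

Partitions a set of positive values into three ordered disjoint subsets:
"A" (the few most important items), "B", and "C" (the trivial many), from the
geometry of the cumulative (effort, yield) curve.  With the values sorted
descending, point i of the curve is (i/n, cumsum_i / total).  The A|B limit is
the curve point closest (Euclidean) to the ideal point (0, 1); the B|C limit
is the break-even point — the last point whose segment slope is still >= 1,
i.e. the last item whose value is at least the mean.  If the break-even point
precedes the A|B limit, set B is empty.

The construction is purely discrete: no smoothing or interpolation of the
curve, so the partition is reproducible without a bandwidth choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ABCResult", "abc_partition"]

_SLOPE_TOL = 1e-12  # floats: values exactly at the mean must count as slope >= 1


@dataclass(frozen=True)
class ABCResult:
    """Partition of positive values into ordered disjoint index sets A, B, C.

    ``curve`` contains n+1 points from (0, 0) to (1, 1); ``ab_limit`` and
    ``bc_limit`` are indices into the curve (item i ends at curve point i).
    Index lists refer to positions in the input sequence, ordered by
    descending value (ties: ascending original index).
    """

    set_a: tuple[int, ...]
    set_b: tuple[int, ...]
    set_c: tuple[int, ...]
    curve: np.ndarray
    ab_limit: int
    bc_limit: int

    @property
    def labels(self) -> dict[int, str]:
        out = {i: "A" for i in self.set_a}
        out.update({i: "B" for i in self.set_b})
        out.update({i: "C" for i in self.set_c})
        return out


def abc_partition(values) -> ABCResult:
    """Partition positive ``values`` into ABC sets; see the module docstring.

    Raises ``ValueError`` on empty input or any non-positive value.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    n = v.size
    if n == 0:
        raise ValueError("ABC analysis needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("ABC analysis requires finite values")
    if np.any(v <= 0):
        raise ValueError("ABC analysis requires strictly positive values")

    # descending by value, stable in original index
    order = np.lexsort((np.arange(n), -v))
    sorted_v = v[order]
    total = sorted_v.sum()

    effort = np.arange(1, n + 1) / n
    yield_frac = np.cumsum(sorted_v) / total
    curve = np.column_stack(
        (np.concatenate(([0.0], effort)), np.concatenate(([0.0], yield_frac)))
    )

    # A|B limit: curve point (excluding the origin) closest to the ideal (0, 1);
    # first index on ties, with a float tolerance so exact geometric ties
    # (e.g. all-equal values) do not depend on cumsum rounding
    d2 = effort**2 + (1.0 - yield_frac) ** 2
    ab = int(np.nonzero(d2 <= d2.min() + 1e-12)[0][0]) + 1

    # B|C limit: last item whose segment slope >= 1  <=>  value >= mean
    slopes = sorted_v * n / total
    at_least_mean = np.nonzero(slopes >= 1.0 - _SLOPE_TOL)[0]
    bc = int(at_least_mean[-1]) + 1 if at_least_mean.size else 0
    bc = max(bc, ab)  # break-even before the A|B limit -> B empty

    return ABCResult(
        set_a=tuple(int(i) for i in order[:ab]),
        set_b=tuple(int(i) for i in order[ab:bc]),
        set_c=tuple(int(i) for i in order[bc:]),
        curve=curve,
        ab_limit=ab,
        bc_limit=bc,
    )
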