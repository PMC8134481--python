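"""Fusion of the two analysis arms by set intersection.

The supervised arm yields odors whose property ratings discriminate (or fail
to discriminate) the olfactory diagnoses; odors claimed by both directions
are dropped, leaving two *exclusive* odor sets.  Intersecting these with the
unsupervised arm's distinctive / non-distinctive categories gives the final
consensus sets, together with the fraction of supervised-exclusive odors the
unsupervised arm confirms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .supervised import SelectionResult

__all__ = ["ConsensusResult", "exclusive_sets", "intersect_arms"]


@dataclass
class ConsensusResult:
    """Final consensus odor sets and per-direction overlap fractions."""

    distinctive_final: list[str]
    nondistinctive_final: list[str]
    supervised_exclusive_distinctive: list[str]
    supervised_exclusive_nondistinctive: list[str]
    overlap_fraction_distinctive: float | None
    overlap_fraction_nondistinctive: float | None


def exclusive_sets(sel: SelectionResult) -> tuple[list[str], list[str]]:
    """Odors appearing only in the most- (resp. least-) relevant selection."""
    most = set(sel.most_relevant_odors)
    least = set(sel.least_relevant_odors)
    excl_d = [o for o in sel.most_relevant_odors if o not in least]
    excl_n = [o for o in sel.least_relevant_odors if o not in most]
    return excl_d, excl_n


def intersect_arms(
    exclusive_distinctive: list[str],
    exclusive_nondistinctive: list[str],
    unsup_categories: dict[str, list[str]],
    odor_universe: list[str] | None = None,
) -> ConsensusResult:
    """Intersect supervised-exclusive sets with the unsupervised categories.

    Overlap fractions use the supervised-exclusive set as denominator and are
    ``None`` when that set is empty.  If ``odor_universe`` is given, both
    arms must speak about the same odors.
    """
    unsup_all = set().union(*unsup_categories.values()) if unsup_categories else set()
    if odor_universe is not None:
        universe = set(odor_universe)
        if unsup_all != universe:
            raise ValueError("unsupervised categories do not cover the odor universe")
        stray = (set(exclusive_distinctive) | set(exclusive_nondistinctive)) - universe
        if stray:
            raise ValueError(f"supervised odors outside the odor universe: {sorted(stray)}")
    else:
        stray = (set(exclusive_distinctive) | set(exclusive_nondistinctive)) - unsup_all
        if stray:
            raise ValueError(f"odor-universe mismatch between the arms: {sorted(stray)}")

    unsup_d = set(unsup_categories.get("distinctive", []))
    unsup_n = set(unsup_categories.get("nondistinctive", []))
    final_d = [o for o in exclusive_distinctive if o in unsup_d]
    final_n = [o for o in exclusive_nondistinctive if o in unsup_n]
    frac_d = len(final_d) / len(exclusive_distinctive) if exclusive_distinctive else None
    frac_n = (
        len(final_n) / len(exclusive_nondistinctive) if exclusive_nondistinctive else None
    )
    return ConsensusResult(
        distinctive_final=final_d,
        nondistinctive_final=final_n,
        supervised_exclusive_distinctive=list(exclusive_distinctive),
        supervised_exclusive_nondistinctive=list(exclusive_nondistinctive),
        overlap_fraction_distinctive=frac_d,
        overlap_fraction_nondistinctive=frac_n,
    )
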