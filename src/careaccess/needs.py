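"""WHODAS 2.0 scoring and needs stratification.

The WHO Disability Assessment Schedule 2.0 (36-item form) rates activities
and participation over the previous 30 days in six domains — cognition,
mobility, self-care, getting along, life activities, participation — each
item scored 0 (no difficulty) to 4 (extreme difficulty).  With the four
employment/study items dropped (as in disability-registry cohorts containing
mostly retired respondents), 32 items remain.  "Simple" scoring rescales the
item sums so each domain and the overall summary lie on 0-100, higher
meaning more disabled.

A cohort is split into a *general demand* group and a *high level of need*
group by conjunctive domain cutoffs: a case is high-need when cognition
> 77.5, mobility > 78.5, self-care > 55 and summary > 66.5 (all strict).
These cutoffs come from a validated screen for institutionalization risk in
dementia; cases above all of them need daily support.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .data_io import CaseRecord, DomainScores

__all__ = [
    "DomainScores",
    "NeedsCutoffs",
    "NeedsGroup",
    "DEFAULT_DOMAIN_MAP",
    "whodas_simple_scores",
    "stratify_case",
    "stratify_cohort",
]


class NeedsGroup(str, Enum):
    GENERAL_DEMAND = "general_demand"
    HIGH_LEVEL_OF_NEED = "high_level_of_need"


@dataclass(frozen=True)
class NeedsCutoffs:
    """Strict lower cutoffs defining the high-level-of-need group.

    ``combine="all"`` (the default) requires every cutoff to be exceeded;
    ``combine="any"`` is available for sensitivity analysis.
    """

    d1_cut: float = 77.5
    d2_cut: float = 78.5
    d3_cut: float = 55.0
    summary_cut: float = 66.5
    combine: str = "all"

    def __post_init__(self) -> None:
        for name in ("d1_cut", "d2_cut", "d3_cut", "summary_cut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.combine not in ("all", "any"):
            raise ValueError("combine must be 'all' or 'any'")


# 32-item form: domain -> item count (6+5+4+5+4+8); life activities keeps only
# its four household items once the work/study items are removed.
DEFAULT_DOMAIN_MAP: dict[str, tuple[int, ...]] = {
    "d1_cognition": tuple(range(1, 7)),
    "d2_mobility": tuple(range(7, 12)),
    "d3_selfcare": tuple(range(12, 16)),
    "d4_getting_along": tuple(range(16, 21)),
    "d5_life_activities": tuple(range(21, 25)),
    "d6_participation": tuple(range(25, 33)),
}


def whodas_simple_scores(
    items: Sequence[int],
    domain_map: Mapping[str, Sequence[int]] = DEFAULT_DOMAIN_MAP,
) -> DomainScores:
    """Simple (sum-and-rescale) scoring of the 32 item responses.

    Each domain score is ``100 * sum(items in domain) / (4 * n_items)``; the
    summary score rescales the total over all 32 items.
    """
    if len(items) != 32:
        raise ValueError(f"expected 32 item responses, got {len(items)}")
    if any(r not in (0, 1, 2, 3, 4) for r in items):
        bad = [r for r in items if r not in (0, 1, 2, 3, 4)]
        raise ValueError(f"item responses outside 0-4: {bad}")
    covered = sorted(i for ids in domain_map.values() for i in ids)
    if covered != list(range(1, 33)):
        raise ValueError("domain_map must cover items 1..32 exactly once")

    def domain_score(ids: Sequence[int]) -> float:
        return 100.0 * sum(items[i - 1] for i in ids) / (4.0 * len(ids))

    scores = {name: domain_score(ids) for name, ids in domain_map.items()}
    summary = 100.0 * sum(items) / (4.0 * 32)
    return DomainScores(summary=summary, **scores)


def stratify_case(scores: DomainScores, cutoffs: NeedsCutoffs = NeedsCutoffs()) -> NeedsGroup:
    """Assign one case to general-demand or high-level-of-need.

    All comparisons are strict: a score exactly at a cutoff does not qualify.
    """
    checks = (
        scores.d1_cognition > cutoffs.d1_cut,
        scores.d2_mobility > cutoffs.d2_cut,
        scores.d3_selfcare > cutoffs.d3_cut,
        scores.summary > cutoffs.summary_cut,
    )
    hit = all(checks) if cutoffs.combine == "all" else any(checks)
    return NeedsGroup.HIGH_LEVEL_OF_NEED if hit else NeedsGroup.GENERAL_DEMAND


def case_scores(case: CaseRecord) -> DomainScores:
    """Domain scores for a case, computed from items when not supplied."""
    if case.scores is not None:
        return case.scores
    if case.items is not None:
        return whodas_simple_scores(case.items)
    raise ValueError(f"case {case.case_id}: neither scores nor items present")


def stratify_cohort(
    cases: Iterable[CaseRecord],
    cutoffs: NeedsCutoffs = NeedsCutoffs(),
) -> tuple[dict[NeedsGroup, list[CaseRecord]], dict[NeedsGroup, int]]:
    """Partition a cohort into the two needs groups.

    Returns per-group case lists and counts; the partition is exhaustive and
    disjoint, so the counts always sum to the cohort size.
    """
    groups: dict[NeedsGroup, list[CaseRecord]] = {
        NeedsGroup.GENERAL_DEMAND: [],
        NeedsGroup.HIGH_LEVEL_OF_NEED: [],
    }
    for case in cases:
        groups[stratify_case(case_scores(case), cutoffs)].append(case)
    counts = {g: len(members) for g, members in groups.items()}
    return groups, counts
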