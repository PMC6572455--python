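"""PWD/TLD indicator extraction, area classification and priority ranking.

Two accessibility indicators are read off the joinpoint fit of an area's
nearest-distance frequency curve:

* **PWD** (profit willing distance): the first significant breakpoint where
  the slope turns from positive to negative — the distance band within which
  providers willingly supply services (the curve peaks there).
* **TLD** (tolerance limited distance): the first significant breakpoint
  where the slope turns from negative to positive — the distance beyond
  which users bear a renewed travel burden to reach far providers.

Either indicator may be absent; areas are classified four ways (both /
only-PWD / only-TLD / neither) and ranked for resource-allocation priority:
only-TLD areas first (users still seek services but no willing-supply band
exists; larger TLD = larger burden = more urgent), then areas with both
indicators by descending TLD, then only-PWD, then neither.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .joinpoint import JoinpointFit

__all__ = [
    "AreaCategory",
    "Zone",
    "AreaResult",
    "extract_pwd_tld",
    "classify_area",
    "service_density",
    "classify_zone",
    "rank_priorities",
    "summarize",
]


class AreaCategory(str, Enum):
    BOTH = "both"
    ONLY_PWD = "only_pwd"
    ONLY_TLD = "only_tld"
    NEITHER = "neither"


class Zone(str, Enum):
    SUPPLY = "supply"  # provider locations themselves
    PROFITABLE = "profitable"  # within the PWD
    TOLERABLE = "tolerable"  # between PWD and TLD
    BEYOND_TOLERANCE = "beyond_tolerance"  # past the TLD


@dataclass(frozen=True)
class AreaResult:
    """Indicator values and bookkeeping for one area and needs group."""

    area_code: str
    group: str  # all | general_demand | high_level_of_need
    pwd: float | None
    tld: float | None
    category: AreaCategory
    n_cases: int
    n_providers: int
    density_ratio: float | None = None
    priority_rank: int | None = None

    def __post_init__(self) -> None:
        if classify_area(self.pwd, self.tld) is not self.category:
            raise ValueError("category inconsistent with pwd/tld presence")
        if self.pwd is not None and self.tld is not None and not self.tld > self.pwd:
            raise ValueError(f"{self.area_code}: tld {self.tld} must exceed pwd {self.pwd}")


def _round_to_bin(value: float, bin_width: float) -> float:
    """Round a breakpoint (a bin midpoint) to the nearest bin-width multiple."""
    return math.floor(value / bin_width + 0.5) * bin_width


def extract_pwd_tld(
    fit: JoinpointFit,
    significant: Sequence[bool] | None = None,
    bin_width: float | None = None,
) -> tuple[float | None, float | None]:
    """PWD and TLD from a fitted curve.

    PWD is the smallest significant breakpoint whose slope changes + to -,
    TLD the smallest with a - to + change; either may be absent.  With
    ``bin_width`` given, values are reported rounded to the nearest multiple
    of the bin width (the resolution the curve was measured at).
    """
    if significant is None:
        significant = fit.significant_breakpoints()
    if len(significant) != fit.k:
        raise ValueError("one significance flag per breakpoint required")
    pwd = tld = None
    for bp, sig, before, after in zip(
        fit.breakpoints, significant, fit.slopes, fit.slopes[1:]
    ):
        if not sig:
            continue
        if pwd is None and before > 0 and after < 0:
            pwd = bp
            tld = None  # a tolerance bound must lie beyond the supply peak
        if tld is None and before < 0 and after > 0:
            tld = bp
    if bin_width:
        pwd = None if pwd is None else _round_to_bin(pwd, bin_width)
        tld = None if tld is None else _round_to_bin(tld, bin_width)
    return pwd, tld


def classify_area(pwd: float | None, tld: float | None) -> AreaCategory:
    """Four-way classification by indicator presence."""
    if pwd is not None and tld is not None:
        return AreaCategory.BOTH
    if pwd is not None:
        return AreaCategory.ONLY_PWD
    if tld is not None:
        return AreaCategory.ONLY_TLD
    return AreaCategory.NEITHER


def service_density(n_cases: int, n_providers: int) -> float | None:
    """Cases per provider, rounded to 2 decimals; None when no providers."""
    if n_cases < 0 or n_providers < 0:
        raise ValueError("counts must be non-negative")
    if n_providers == 0:
        return None
    return round(n_cases / n_providers, 2)


def classify_zone(distance: float, pwd: float | None, tld: float | None) -> Zone | None:
    """Zone of one user location relative to an area's indicators.

    Bounds are inclusive: ``distance == pwd`` is still profitable and
    ``distance == tld`` still tolerable.  In an only-PWD area a distance
    beyond the PWD has no defined zone (no tolerance bound exists) and None
    is returned.  An area with neither indicator cannot be zoned at all.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if pwd is None and tld is None:
        raise ValueError("area has neither PWD nor TLD; no zones are defined")
    if pwd is not None and distance <= pwd:
        return Zone.PROFITABLE
    if tld is not None:
        return Zone.TOLERABLE if distance <= tld else Zone.BEYOND_TOLERANCE
    return None  # only-PWD area, beyond the PWD: undefined, flagged to caller


def rank_priorities(results: Iterable[AreaResult]) -> list[AreaResult]:
    """Order areas by allocation priority and assign ranks.

    Tier order: only-TLD (descending TLD), then both (descending TLD), then
    only-PWD, then neither; ties broken by higher density ratio, then area
    code.  Returns a ranked copy; the output is a permutation of the input.
    """
    results = list(results)
    codes = [r.area_code for r in results]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate area codes in ranking input")
    tier = {
        AreaCategory.ONLY_TLD: 0,
        AreaCategory.BOTH: 1,
        AreaCategory.ONLY_PWD: 2,
        AreaCategory.NEITHER: 3,
    }

    def key(r: AreaResult):
        return (
            tier[r.category],
            -(r.tld if r.tld is not None else -math.inf),
            -(r.density_ratio if r.density_ratio is not None else -math.inf),
            r.area_code,
        )

    ordered = sorted(results, key=key)
    return [replace(r, priority_rank=i + 1) for i, r in enumerate(ordered)]


def summarize(results: Iterable[AreaResult]) -> dict[str, int]:
    """Category counts over a complete result set for one group."""
    counts = Counter(r.category.value for r in results)
    return {cat.value: counts.get(cat.value, 0) for cat in AreaCategory}
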