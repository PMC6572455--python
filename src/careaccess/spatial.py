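"""Within-area nearest-provider matching and distance-frequency curves.

Each case is matched to the nearest provider *in the same administrative
area* (accessibility planning is per administrative unit; a provider across
the boundary does not count toward an area's supply, though the restriction
can be relaxed for sensitivity analysis).  Nearest distances are then binned
at a fixed width — 50 m by default — into a frequency curve whose shape
carries the accessibility signal: a rise while supply is dense, a fall past
the distance providers willingly serve, and a renewed rise where users must
reach far-away providers.

Distances are planar Euclidean for projected metre coordinates and haversine
(great-circle, metres) for lon/lat input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .data_io import CaseRecord, CoordSystem, ProviderRecord

Metric = Literal["euclidean", "haversine"]

EARTH_RADIUS_M = 6_371_000.0

DEFAULT_BIN_WIDTH = 50.0


class NoSupplyError(ValueError):
    """Raised when a case's area has no provider (distinct from distance 0)."""


@dataclass(frozen=True)
class NearestMatch:
    case_id: str
    provider_id: str
    distance: float  # metres
    area_code: str

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class DistanceCurve:
    """Binned frequency of nearest case-to-provider distances.

    Bins are half-open ``[k*w, (k+1)*w)`` anchored at zero; ``counts[k]`` is
    the number of matches whose distance falls in bin ``k``.  Trailing empty
    bins are truncated at construction.
    """

    area_code: str
    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    group: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be >= 0")

    @property
    def n_matches(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints (25, 75, 125, ... for a 50 m width)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def is_empty(self) -> bool:
        return self.n_bins == 0 or self.counts.sum() == 0


def _coords(records: Sequence) -> np.ndarray:
    return np.array([[r.x, r.y] for r in records], dtype=float)


def haversine_m(xy1: np.ndarray, xy2: np.ndarray) -> np.ndarray:
    """Great-circle distance in metres between (lon, lat) degree arrays.

    Broadcasts over leading dimensions; inputs have shape (..., 2).
    """
    lon1, lat1 = np.radians(xy1[..., 0]), np.radians(xy1[..., 1])
    lon2, lat2 = np.radians(xy2[..., 0]), np.radians(xy2[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _distance_matrix(case_xy: np.ndarray, prov_xy: np.ndarray, metric: Metric) -> np.ndarray:
    if metric == "euclidean":
        diff = case_xy[:, None, :] - prov_xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "haversine":
        return haversine_m(case_xy[:, None, :], prov_xy[None, :, :])
    raise ValueError(f"unknown metric {metric!r}")


def nearest_provider_distance(
    case: CaseRecord,
    providers: Sequence[ProviderRecord],
    metric: Metric = "euclidean",
) -> NearestMatch:
    """Nearest provider to one case; ties broken by smallest provider_id."""
    if not providers:
        raise NoSupplyError(f"no providers available for case {case.case_id}")
    order = sorted(range(len(providers)), key=lambda i: providers[i].provider_id)
    prov_xy = _coords([providers[i] for i in order])
    d = _distance_matrix(np.array([[case.x, case.y]]), prov_xy, metric)[0]
    j = int(np.argmin(d))  # argmin returns the first minimum -> smallest id wins ties
    best = providers[order[j]]
    return NearestMatch(
        case_id=case.case_id,
        provider_id=best.provider_id,
        distance=float(d[j]),
        area_code=case.area_code,
    )


def _nearest_in_area(
    cases: Sequence[CaseRecord],
    providers: Sequence[ProviderRecord],
    metric: Metric,
) -> list[NearestMatch]:
    order = sorted(range(len(providers)), key=lambda i: providers[i].provider_id)
    providers = [providers[i] for i in order]
    case_xy = _coords(cases)
    prov_xy = _coords(providers)
    if metric == "euclidean" and len(providers) > 32:
        # KD-tree accelerates large areas; equivalent to the exhaustive scan
        # up to the identity of exactly tied providers
        tree = cKDTree(prov_xy)
        dmin, js = tree.query(case_xy)
        return [
            NearestMatch(case.case_id, providers[int(j)].provider_id, float(d), case.area_code)
            for case, j, d in zip(cases, js, dmin)
        ]
    D = _distance_matrix(case_xy, prov_xy, metric)
    js = np.argmin(D, axis=1)
    return [
        NearestMatch(case.case_id, providers[int(j)].provider_id, float(D[i, j]), case.area_code)
        for i, (case, j) in enumerate(zip(cases, js))
    ]


def nearest_distances_by_area(
    cases: Iterable[CaseRecord],
    providers: Iterable[ProviderRecord],
    metric: Metric = "euclidean",
    allow_cross_area: bool = False,
) -> tuple[list[NearestMatch], list[CaseRecord]]:
    """Match every case to its nearest same-area provider.

    Returns the matches plus the list of cases living in provider-less areas
    (those areas get no distance curve and will be classified as lacking both
    indicators).  With ``allow_cross_area=True`` all providers are candidates
    regardless of area (sensitivity analysis only).
    """
    cases = list(cases)
    providers = list(providers)
    by_area: dict[str, list[ProviderRecord]] = {}
    for p in providers:
        by_area.setdefault(p.area_code, []).append(p)

    matches: list[NearestMatch] = []
    unserved: list[CaseRecord] = []
    case_groups: dict[str, list[CaseRecord]] = {}
    for c in cases:
        case_groups.setdefault(c.area_code, []).append(c)
    for area, area_cases in case_groups.items():
        pool = providers if allow_cross_area else by_area.get(area, [])
        if not pool:
            unserved.extend(area_cases)
            continue
        matches.extend(_nearest_in_area(area_cases, pool, metric))
    return matches, unserved


def build_distance_curve(
    matches: Sequence[NearestMatch],
    bin_width: float = DEFAULT_BIN_WIDTH,
    area_code: str | None = None,
    group: str = "all",
) -> DistanceCurve:
    """Bin nearest distances into a frequency curve.

    An empty match list yields an empty curve (no joinpoints detectable, so
    the area reports neither indicator).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if area_code is None:
        areas = {m.area_code for m in matches}
        if len(areas) > 1:
            raise ValueError(f"matches span several areas: {sorted(areas)}")
        area_code = areas.pop() if areas else ""
    if not matches:
        return DistanceCurve(area_code=area_code, counts=np.zeros(0), bin_width=bin_width, group=group)
    d = np.array([m.distance for m in matches], dtype=float)
    idx = np.floor(d / bin_width).astype(int)  # half-open bins: d == k*w -> bin k
    counts = np.bincount(idx, minlength=int(idx.max()) + 1).astype(float)
    return DistanceCurve(area_code=area_code, counts=counts, bin_width=bin_width, group=group)


def matches_to_rows(matches: Iterable[NearestMatch]) -> list[dict]:
    return [
        {
            "case_id": m.case_id,
            "provider_id": m.provider_id,
            "area_code": m.area_code,
            "distance_m": m.distance,
        }
        for m in matches
    ]


def curve_to_rows(curve: DistanceCurve) -> list[dict]:
    edges = curve.bin_edges
    return [
        {
            "area_code": curve.area_code,
            "group": curve.group,
            "bin_lo": float(edges[k]),
            "bin_hi": float(edges[k + 1]),
            "count": float(curve.counts[k]),
        }
        for k in range(curve.n_bins)
    ]
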