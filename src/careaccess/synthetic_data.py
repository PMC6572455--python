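"""Seeded generators for synthetic registries with known ground truth.

The real inputs to this analysis — a national disability registry with case
coordinates and WHODAS 2.0 scores, and a provider roster — are not publicly
available.  These generators emit inputs with the same schemas and the
statistical structure the method assumes, so every pipeline stage can be
exercised against known ground truth:

* area point patterns whose nearest-distance frequency curve follows a
  prescribed piecewise-linear shape (known breakpoints, e.g. rise-fall-rise);
* WHODAS cohorts drawn from a two-component truncated-normal mixture whose
  components sit strictly above / below the needs cutoffs, so the intended
  high-need fraction is recovered exactly by stratification.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import CaseRecord, DomainScores, ProviderRecord
from .needs import NeedsCutoffs
from .spatial import DistanceCurve

__all__ = ["AreaSpec", "gen_frequency_curve", "gen_area_points", "gen_whodas_cohort", "gen_registry"]


@dataclass(frozen=True)
class AreaSpec:
    """Recipe for one synthetic administrative area."""

    area_code: str
    n_providers: int
    n_cases: int
    extent: float = 50_000.0  # square bounding box side, metres
    provider_layout: str = "uniform"  # uniform | clustered
    cluster_k: int = 3
    cluster_spread: float = 2_000.0
    breakpoints: tuple[float, ...] = (300.0, 1500.0)
    slopes: tuple[float, ...] = (0.4, -0.12, 0.05)
    intercept: float = 40.0
    n_bins: int = 40
    bin_width: float = 50.0
    noise_sd: float = 0.0
    p_high: float = 0.32

    def __post_init__(self) -> None:
        if self.n_providers < 0 or self.n_cases < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.p_high <= 1.0):
            raise ValueError("p_high must be in [0, 1]")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")


def _piecewise_values(
    x: np.ndarray,
    breakpoints: Sequence[float],
    slopes: Sequence[float],
    intercept: float,
) -> np.ndarray:
    if len(slopes) != len(breakpoints) + 1:
        raise ValueError("need one more slope than breakpoints")
    y = intercept + slopes[0] * x
    s_prev = slopes[0]
    for tau, s in zip(breakpoints, slopes[1:]):
        y = y + (s - s_prev) * np.maximum(0.0, x - tau)
        s_prev = s
    return y


def gen_frequency_curve(
    breakpoints: Sequence[float],
    slopes: Sequence[float],
    intercept: float,
    n_bins: int,
    bin_width: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    area_code: str = "SYN",
    group: str = "all",
) -> DistanceCurve:
    """Distance curve = piecewise-linear values at bin midpoints + noise.

    Gaussian noise is added per bin, then counts are floored at zero and
    rounded to integers.  The noiseless curve must be non-negative.
    """
    x = (np.arange(n_bins) + 0.5) * bin_width
    y = _piecewise_values(x, breakpoints, slopes, intercept)
    if (y < 0).any():
        raise ValueError("piecewise specification produces negative expected counts")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_bins)
    counts = np.round(np.maximum(y, 0.0))
    return DistanceCurve(area_code=area_code, counts=counts, bin_width=bin_width, group=group)


def _provider_points(spec: AreaSpec, rng: np.random.Generator) -> np.ndarray:
    """Provider coordinates with pairwise separation >= 2x the curve extent.

    The separation guarantees that a case placed at distance d from its
    anchor provider (d < extent of the target curve) has that provider as
    its true nearest neighbour, so the sampled distances survive the
    nearest-match step unchanged.
    """
    if spec.n_providers == 0:
        return np.zeros((0, 2))
    max_d = spec.n_bins * spec.bin_width
    min_sep = 2.0 * max_d + 1.0
    pts: list[np.ndarray] = []
    side = max(spec.extent, min_sep * (np.ceil(np.sqrt(spec.n_providers)) + 1))
    if spec.provider_layout == "clustered":
        centers = rng.uniform(0, side, size=(spec.cluster_k, 2))
        raw = centers[rng.integers(0, spec.cluster_k, spec.n_providers)] + rng.normal(
            0, spec.cluster_spread, size=(spec.n_providers, 2)
        )
    else:
        raw = rng.uniform(0, side, size=(spec.n_providers, 2))
    # thin to the separation constraint, resampling rejected points on a grid
    for p in raw:
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    i = 0
    while len(pts) < spec.n_providers:  # deterministic grid fallback
        gx, gy = divmod(i, 10_000)
        cand = np.array([side + (gx + 1) * min_sep, gy * min_sep])
        if all(np.hypot(*(cand - q)) >= min_sep for q in pts):
            pts.append(cand)
        i += 1
    return np.array(pts)


def _sample_distances(spec: AreaSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw nearest distances from the binned target density (inverse sampling)."""
    x = (np.arange(spec.n_bins) + 0.5) * spec.bin_width
    weights = _piecewise_values(x, spec.breakpoints, spec.slopes, spec.intercept)
    if (weights < 0).any():
        raise ValueError("piecewise specification produces negative expected counts")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero target curve cannot place cases")
    bins = rng.choice(spec.n_bins, size=n, p=weights / total)
    return (bins + rng.uniform(0.0, 1.0, size=n)) * spec.bin_width


def gen_area_points(spec: AreaSpec, seed: int | None = None) -> tuple[list[ProviderRecord], list[CaseRecord]]:
    """Generate provider and case points for one area.

    Each case is placed at a sampled distance and uniform bearing from a
    randomly chosen provider; provider separation guarantees the anchor is
    the nearest provider, so the empirical nearest-distance curve matches
    the target up to multinomial sampling error.  Cases carry WHODAS scores
    from :func:`gen_whodas_cohort` with the spec's high-need probability.
    """
    rng = np.random.default_rng(seed)
    prov_xy = _provider_points(spec, rng)
    providers = [
        ProviderRecord(
            provider_id=f"{spec.area_code}-P{i:04d}",
            area_code=spec.area_code,
            x=float(p[0]),
            y=float(p[1]),
            service_type="daycare",
        )
        for i, p in enumerate(prov_xy)
    ]
    if spec.n_cases == 0:
        return providers, []
    if not providers:
        raise ValueError("cannot place cases in an area without providers")
    d = _sample_distances(spec, spec.n_cases, rng)
    theta = rng.uniform(0.0, 2 * np.pi, size=spec.n_cases)
    anchors = prov_xy[rng.integers(0, len(providers), spec.n_cases)]
    xy = anchors + np.column_stack([d * np.cos(theta), d * np.sin(theta)])
    profiles = _cohort_profiles(spec.n_cases, spec.p_high, rng)
    cases = [
        CaseRecord(
            case_id=f"{spec.area_code}-C{i:05d}",
            area_code=spec.area_code,
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            age=prof["age"],
            sex=prof["sex"],
            severity=prof["severity"],
            residence="community",
            scores=prof["scores"],
        )
        for i, prof in enumerate(profiles)
    ]
    return providers, cases


# Two-component truncated-normal mixture for domain scores; the high-need
# component is truncated strictly above every needs cutoff and the general
# component strictly below the cognition cutoff, so labels are recovered
# exactly by stratification.  Moments echo a community dementia cohort:
# high-need domains cluster in the 90s, general demand in the 40s-70s.
_HIGH_PARAMS = {  # (mean, sd, lower, upper)
    "d1_cognition": (95.35, 7.02, 77.5, 100.0),
    "d2_mobility": (94.45, 10.41, 78.5, 100.0),
    "d3_selfcare": (95.11, 7.15, 55.0, 100.0),
    "d4_getting_along": (94.35, 11.02, 0.0, 100.0),
    "d5_life_activities": (99.37, 5.28, 0.0, 100.0),
    "d6_participation": (70.74, 22.36, 0.0, 100.0),
    "summary": (89.43, 7.58, 66.5, 100.0),
}
_GENERAL_PARAMS = {
    "d1_cognition": (61.17, 23.89, 0.0, 77.5),
    "d2_mobility": (44.64, 31.62, 0.0, 100.0),
    "d3_selfcare": (40.05, 29.16, 0.0, 100.0),
    "d4_getting_along": (59.21, 28.86, 0.0, 100.0),
    "d5_life_activities": (75.37, 29.45, 0.0, 100.0),
    "d6_participation": (43.33, 22.33, 0.0, 100.0),
    "summary": (54.56, 19.60, 0.0, 100.0),
}
_EPS = 1e-6  # keeps truncated draws strictly off the cutoff boundary


def _truncnorm_draw(params: tuple[float, float, float, float], n: int, rng) -> np.ndarray:
    mean, sd, lo, hi = params
    a, b = (lo + _EPS - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _cohort_profiles(n: int, p_high: float, rng: np.random.Generator) -> list[dict]:
    is_high = rng.uniform(size=n) < p_high
    fields = list(_HIGH_PARAMS)
    draws = {}
    for name in fields:
        vals = np.empty(n)
        n_hi = int(is_high.sum())
        if n_hi:
            vals[is_high] = _truncnorm_draw(_HIGH_PARAMS[name], n_hi, rng)
        if n - n_hi:
            vals[~is_high] = _truncnorm_draw(_GENERAL_PARAMS[name], n - n_hi, rng)
        draws[name] = np.clip(vals, 0.0, 100.0)
    ages = np.clip(rng.normal(78.2, 9.8, size=n), 18.0, 110.0)
    sexes = np.where(rng.uniform(size=n) < 0.63, "female", "male")
    severities = rng.choice(
        ["mild", "moderate", "severe", "extremely_serious"],
        size=n,
        p=[0.281, 0.373, 0.076, 0.270],
    )
    return [
        {
            "age": float(ages[i]),
            "sex": str(sexes[i]),
            "severity": str(severities[i]),
            "scores": DomainScores(**{k: float(draws[k][i]) for k in fields}),
            "is_high": bool(is_high[i]),
        }
        for i in range(n)
    ]


def gen_whodas_cohort(
    n: int,
    p_high: float,
    seed: int | None = None,
    area_code: str = "SYN",
) -> list[CaseRecord]:
    """Synthetic community cohort with a stated high-need mixing fraction.

    Every generated case stratifies to its mixture component under the
    default cutoffs, so the empirical high-need fraction is binomial(n,
    p_high).  Coordinates are placed at the origin; combine with
    :func:`gen_area_points` when geography matters.
    """
    rng = np.random.default_rng(seed)
    profiles = _cohort_profiles(n, p_high, rng)
    return [
        CaseRecord(
            case_id=f"{area_code}-C{i:05d}",
            area_code=area_code,
            x=0.0,
            y=0.0,
            age=prof["age"],
            sex=prof["sex"],
            severity=prof["severity"],
            residence="community",
            scores=prof["scores"],
        )
        for i, prof in enumerate(profiles)
    ]


def gen_registry(
    specs: Sequence[AreaSpec], seed: int = 0
) -> tuple[list[ProviderRecord], list[CaseRecord]]:
    """Multi-area registry: concatenated per-area point sets, one sub-seed each."""
    providers: list[ProviderRecord] = []
    cases: list[CaseRecord] = []
    ss = np.random.SeedSequence(seed)
    for spec, child in zip(specs, ss.spawn(len(specs))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        if spec.n_providers == 0:
            if spec.n_cases:
                # provider-less area: scatter cases uniformly; they stay unserved
                rng = np.random.default_rng(sub_seed)
                profiles = _cohort_profiles(spec.n_cases, spec.p_high, rng)
                xy = rng.uniform(0, spec.extent, size=(spec.n_cases, 2))
                cases.extend(
                    CaseRecord(
                        case_id=f"{spec.area_code}-C{i:05d}",
                        area_code=spec.area_code,
                        x=float(xy[i, 0]),
                        y=float(xy[i, 1]),
                        age=p["age"],
                        sex=p["sex"],
                        severity=p["severity"],
                        residence="community",
                        scores=p["scores"],
                    )
                    for i, p in enumerate(profiles)
                )
            continue
        p, c = gen_area_points(spec, seed=sub_seed)
        providers.extend(p)
        cases.extend(c)
    return providers, cases
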