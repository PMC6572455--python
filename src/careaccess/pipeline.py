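"""End-to-end orchestration: points in, ranked area indicators out.

Stage order: read -> residence filter / coordinate dedupe -> needs
stratification -> within-area nearest matching -> 50 m curves per area and
stratum (all cases, general demand, high level of need) -> joinpoint fits ->
PWD/TLD extraction -> classification, service density, category summary ->
priority ranking.  Every run writes a manifest (config, seed, library
versions) next to its outputs so a rerun reproduces the tables byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_io, indicators, joinpoint, needs, spatial
from .data_io import CaseRecord, FilterReport, ProviderRecord
from .indicators import AreaResult
from .joinpoint import JoinpointFit
from .needs import NeedsCutoffs, NeedsGroup
from .spatial import DistanceCurve, NearestMatch

logger = logging.getLogger("careaccess")

GROUPS = ("all", "general_demand", "high_level_of_need")


@dataclass
class PipelineConfig:
    cases_path: str | None = None
    providers_path: str | None = None
    coord_system: str = "projected_m"
    metric: str = "euclidean"
    bin_width: float = 50.0
    cutoffs: NeedsCutoffs = field(default_factory=NeedsCutoffs)
    k_max: int = joinpoint.DEFAULT_K_MAX
    method: str = "permutation"
    alpha: float = joinpoint.DEFAULT_ALPHA
    n_perm: int = joinpoint.DEFAULT_N_PERM
    seed: int = 0
    min_curve_bins: int = 2 * joinpoint.DEFAULT_MIN_SEG
    out_dir: str | None = None
    rank_group: str = "all"


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_reports: dict[str, FilterReport]
    group_counts: dict[str, int]
    matches: list[NearestMatch]
    unserved: list[CaseRecord]
    curves: dict[tuple[str, str], DistanceCurve]  # (area, group) -> curve
    fits: dict[tuple[str, str], JoinpointFit]
    results: dict[str, list[AreaResult]]  # group -> per-area results
    summaries: dict[str, dict[str, int]]
    ranking: list[AreaResult]
    anomalies: list[str] = field(default_factory=list)


def _sub_seed(seed: int, area: str, group: str) -> int:
    """Stable per-(area, group) seed below 2**31."""
    tag = zlib.crc32(f"{area}|{group}".encode())
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def _area_indicators(
    curve: DistanceCurve, cfg: PipelineConfig, seed: int
) -> tuple[JoinpointFit | None, float | None, float | None, str]:
    """Fit one curve and extract (fit, pwd, tld, note)."""
    if curve.is_empty() or curve.n_bins < cfg.min_curve_bins:
        return None, None, None, "curve too sparse for joinpoint detection"
    fit = joinpoint.select_model(
        curve,
        k_max=cfg.k_max,
        method=cfg.method,  # type: ignore[arg-type]
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=seed,
    )
    if fit.k == 0:
        return fit, None, None, fit.note
    pwd, tld = indicators.extract_pwd_tld(
        fit, fit.significant_breakpoints(cfg.alpha), bin_width=curve.bin_width
    )
    return fit, pwd, tld, fit.note


def run_pipeline(
    config: PipelineConfig,
    cases: Sequence[CaseRecord] | None = None,
    providers: Sequence[ProviderRecord] | None = None,
) -> PipelineResult:
    """Execute all stages; inputs come from paths in the config unless the
    record lists are passed directly (e.g. straight from the generators)."""
    cfg = config
    if cases is None:
        if cfg.cases_path is None:
            raise ValueError("no case input: set cases_path or pass records")
        cases = list(data_io.read_cases(cfg.cases_path, cfg.coord_system))  # type: ignore[arg-type]
    if providers is None:
        if cfg.providers_path is None:
            raise ValueError("no provider input: set providers_path or pass records")
        providers = list(data_io.read_providers(cfg.providers_path, cfg.coord_system))  # type: ignore[arg-type]

    community, case_report = data_io.filter_community(cases)
    unique_providers, provider_report = data_io.dedupe_providers(providers)
    logger.info("filter residence: %d -> %d", case_report.n_input, case_report.n_retained)
    logger.info("dedupe providers: %d -> %d", provider_report.n_input, provider_report.n_retained)

    groups, counts = needs.stratify_cohort(community, cfg.cutoffs)
    group_members: dict[str, set[str]] = {
        "all": {c.case_id for c in community},
        "general_demand": {c.case_id for c in groups[NeedsGroup.GENERAL_DEMAND]},
        "high_level_of_need": {c.case_id for c in groups[NeedsGroup.HIGH_LEVEL_OF_NEED]},
    }
    logger.info(
        "stratify: %d general, %d high",
        counts[NeedsGroup.GENERAL_DEMAND],
        counts[NeedsGroup.HIGH_LEVEL_OF_NEED],
    )

    matches, unserved = spatial.nearest_distances_by_area(
        community, unique_providers, metric=cfg.metric  # type: ignore[arg-type]
    )
    logger.info("nearest match: %d matched, %d in provider-less areas", len(matches), len(unserved))

    areas = sorted({c.area_code for c in community} | {p.area_code for p in unique_providers})
    providers_per_area = {a: 0 for a in areas}
    for p in unique_providers:
        providers_per_area[p.area_code] = providers_per_area.get(p.area_code, 0) + 1
    cases_per_area_group = {
        (a, g): sum(1 for c in community if c.area_code == a and c.case_id in group_members[g])
        for a in areas
        for g in GROUPS
    }

    curves: dict[tuple[str, str], DistanceCurve] = {}
    fits: dict[tuple[str, str], JoinpointFit] = {}
    results: dict[str, list[AreaResult]] = {g: [] for g in GROUPS}
    anomalies: list[str] = []
    for area in areas:
        area_matches = [m for m in matches if m.area_code == area]
        for group in GROUPS:
            member_ids = group_members[group]
            sub = [m for m in area_matches if m.case_id in member_ids]
            curve = spatial.build_distance_curve(
                sub, bin_width=cfg.bin_width, area_code=area, group=group
            )
            curves[(area, group)] = curve
            fit, pwd, tld, note = _area_indicators(curve, cfg, _sub_seed(cfg.seed, area, group))
            if fit is not None:
                fits[(area, group)] = fit
            if note:
                anomalies.append(f"{area}/{group}: {note}")
            n_cases = cases_per_area_group[(area, group)]
            n_prov = providers_per_area.get(area, 0)
            results[group].append(
                AreaResult(
                    area_code=area,
                    group=group,
                    pwd=pwd,
                    tld=tld,
                    category=indicators.classify_area(pwd, tld),
                    n_cases=n_cases,
                    n_providers=n_prov,
                    density_ratio=indicators.service_density(n_cases, n_prov),
                )
            )

    summaries = {g: indicators.summarize(results[g]) for g in GROUPS}
    ranking = indicators.rank_priorities(results[cfg.rank_group])

    out = PipelineResult(
        config=cfg,
        filter_reports={"cases": case_report, "providers": provider_report},
        group_counts={
            "all": len(community),
            "general_demand": counts[NeedsGroup.GENERAL_DEMAND],
            "high_level_of_need": counts[NeedsGroup.HIGH_LEVEL_OF_NEED],
        },
        matches=matches,
        unserved=unserved,
        curves=curves,
        fits=fits,
        results=results,
        summaries=summaries,
        ranking=ranking,
        anomalies=anomalies,
    )
    if cfg.out_dir is not None:
        write_bundle(out, Path(cfg.out_dir))
    return out


def results_frame(results: Sequence[AreaResult]) -> pd.DataFrame:
    rows = [
        {
            "area_code": r.area_code,
            "group": r.group,
            "n_providers": r.n_providers,
            "n_cases": r.n_cases,
            "pwd_m": r.pwd,
            "tld_m": r.tld,
            "category": r.category.value,
            "density_ratio": r.density_ratio,
            "priority_rank": r.priority_rank,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def write_bundle(result: PipelineResult, out_dir: Path) -> None:
    """Persist matches, curves, fits, per-group results, summary and ranking."""
    out_dir = Path(out_dir)
    for sub in ("matches", "curves", "fits", "results"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    data_io.write_results(spatial.matches_to_rows(result.matches), out_dir / "matches" / "matches.csv")
    curve_rows = [row for c in result.curves.values() for row in spatial.curve_to_rows(c)]
    data_io.write_results(pd.DataFrame(curve_rows), out_dir / "curves" / "curves.csv")
    fits_payload = {
        f"{area}|{group}": joinpoint.fit_to_dict(fit, seed=result.config.seed)
        for (area, group), fit in result.fits.items()
    }
    (out_dir / "fits" / "fits.json").write_text(json.dumps(fits_payload, indent=2) + "\n")
    for group, res in result.results.items():
        data_io.write_results(results_frame(res), out_dir / "results" / f"areas_{group}.csv")
    data_io.write_results(results_frame(result.ranking), out_dir / "results" / "ranking.csv")
    (out_dir / "results" / "summary.json").write_text(
        json.dumps(result.summaries, indent=2) + "\n"
    )
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(result.config).items() if k != "cutoffs"},
            "cutoffs": dataclasses.asdict(result.config.cutoffs),
        },
        "seed": result.config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "anomalies": result.anomalies,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def area_results_from_table(df: pd.DataFrame, group: str = "all") -> list[AreaResult]:
    """Build AreaResults from an area-level indicator table.

    Expects the schema of :func:`careaccess.published.area_table`: one row
    per area with count columns and ``pwd_<group>``/``tld_<group>`` values in
    metres (NaN = indicator absent).  This is the entry point for
    re-analysing published area-level results without case-level data.
    """
    suffix = {"all": "all", "general_demand": "general", "high_level_of_need": "high"}[group]
    count_col = {"all": "n_cases", "general_demand": "n_general", "high_level_of_need": "n_high"}[group]
    out = []
    for row in df.itertuples(index=False):
        pwd = getattr(row, f"pwd_{suffix}")
        tld = getattr(row, f"tld_{suffix}")
        pwd = None if pd.isna(pwd) else float(pwd)
        tld = None if pd.isna(tld) else float(tld)
        n_cases = int(getattr(row, count_col))
        n_prov = int(row.n_providers)
        out.append(
            AreaResult(
                area_code=str(row.area),
                group=group,
                pwd=pwd,
                tld=tld,
                category=indicators.classify_area(pwd, tld),
                n_cases=n_cases,
                n_providers=n_prov,
                density_ratio=indicators.service_density(n_cases, n_prov),
            )
        )
    return out
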