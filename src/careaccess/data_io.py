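"""Reading, filtering and writing of case and provider point tables.

Cases are service users (here: community-dwelling adults with dementia) with
an administrative-area code, planar or geographic coordinates, demographics
and optional WHODAS 2.0 functioning scores.  Providers are care-service sites
with an area code and coordinates.

Two record filters mirror the sample-selection flow of a national disability
registry analysis:

* :func:`filter_community` drops cases residing in institutions — only
  community dwellers travel to providers, so only they enter the distance
  analysis.
* :func:`dedupe_providers` keeps one provider per exact coordinate pair;
  listings that geocode to the same point (e.g. several services registered
  at one address) would otherwise inflate apparent supply.

Every filter returns a :class:`FilterReport` whose counts always reconcile
(``n_input == n_excluded + n_retained``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd

CoordSystem = Literal["projected_m", "lonlat"]

SEX_VALUES = {"male", "female"}
SEVERITY_VALUES = {"mild", "moderate", "severe", "extremely_serious"}
RESIDENCE_VALUES = {"community", "institution"}

#: Item columns accepted as an alternative to pre-computed domain scores.
ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, 33))
SCORE_COLUMNS = ("d1", "d2", "d3", "d4", "d5", "d6", "summary")

CASE_REQUIRED = ("case_id", "area_code", "x", "y", "age", "sex", "severity", "residence")
PROVIDER_REQUIRED = ("provider_id", "area_code", "x", "y")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class DomainScores:
    """WHODAS 2.0 domain and summary scores, each on a 0-100 scale.

    Higher scores indicate more severe disability.
    """

    d1_cognition: float
    d2_mobility: float
    d3_selfcare: float
    d4_getting_along: float
    d5_life_activities: float
    d6_participation: float
    summary: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{f.name}={v} outside [0, 100]")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.d1_cognition,
            self.d2_mobility,
            self.d3_selfcare,
            self.d4_getting_along,
            self.d5_life_activities,
            self.d6_participation,
            self.summary,
        )


@dataclass(frozen=True)
class CaseRecord:
    """One service user with location, demographics and functioning scores.

    Exactly one of ``scores``/``items`` may be absent, not both.
    """

    case_id: str
    area_code: str
    x: float
    y: float
    age: float
    sex: str
    severity: str
    residence: str
    scores: DomainScores | None = None
    items: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"case {self.case_id}: non-finite coordinates")
        if self.age < 18:
            raise ValueError(f"case {self.case_id}: age {self.age} < 18 (adult cohort)")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"case {self.case_id}: sex {self.sex!r}")
        if self.severity not in SEVERITY_VALUES:
            raise ValueError(f"case {self.case_id}: severity {self.severity!r}")
        if self.residence not in RESIDENCE_VALUES:
            raise ValueError(f"case {self.case_id}: residence {self.residence!r}")
        if self.scores is None and self.items is None:
            raise ValueError(f"case {self.case_id}: neither scores nor items present")
        if self.items is not None:
            if len(self.items) != 32:
                raise ValueError(f"case {self.case_id}: expected 32 items, got {len(self.items)}")
            if any(r not in (0, 1, 2, 3, 4) for r in self.items):
                raise ValueError(f"case {self.case_id}: item response outside 0-4")


@dataclass(frozen=True)
class ProviderRecord:
    """One care provider site with area code and coordinates."""

    provider_id: str
    area_code: str
    x: float
    y: float
    service_type: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"provider {self.provider_id}: non-finite coordinates")
        if not self.area_code:
            raise ValueError(f"provider {self.provider_id}: empty area_code")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one record filter; counts always reconcile."""

    n_input: int
    n_excluded: int
    n_retained: int
    rule: str

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise ValueError("filter report does not reconcile")


@dataclass
class RowError:
    row: int  # 1-based data-row number (header not counted)
    message: str


@dataclass
class RecordTable:
    """A parsed table: valid records plus row-level parse errors."""

    records: list
    coord_system: CoordSystem
    row_errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _load_point_frame(path: str | Path) -> pd.DataFrame:
    """Load a CSV table or a GeoJSON Point FeatureCollection as a DataFrame."""
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        payload = json.loads(path.read_text())
        rows = []
        for feat in payload.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"{path}: only Point features are supported")
            props = dict(feat.get("properties") or {})
            props["x"], props["y"] = geom["coordinates"][:2]
            rows.append(props)
        return pd.DataFrame(rows)
    return pd.read_csv(path, dtype={"case_id": str, "provider_id": str, "area_code": str})


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _row_scores(row: pd.Series) -> DomainScores | None:
    if not all(c in row.index for c in SCORE_COLUMNS):
        return None
    vals = [row[c] for c in SCORE_COLUMNS]
    if any(pd.isna(v) for v in vals):
        return None
    return DomainScores(*(float(v) for v in vals))


def _row_items(row: pd.Series) -> tuple[int, ...] | None:
    if not all(c in row.index for c in ITEM_COLUMNS):
        return None
    vals = [row[c] for c in ITEM_COLUMNS]
    if any(pd.isna(v) for v in vals):
        return None
    return tuple(int(v) for v in vals)


def read_cases(path: str | Path, coord_system: CoordSystem = "projected_m") -> RecordTable:
    """Read a case table (CSV or GeoJSON points).

    Rows that fail to parse are collected as :class:`RowError` entries rather
    than aborting the load; a missing required column raises
    :class:`SchemaError` naming the column.
    """
    df = _load_point_frame(path)
    _require_columns(df, CASE_REQUIRED, path)
    records: list[CaseRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = pd.Series(row._asdict())
        try:
            records.append(
                CaseRecord(
                    case_id=str(row["case_id"]),
                    area_code=str(row["area_code"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    severity=str(row["severity"]),
                    residence=str(row["residence"]),
                    scores=_row_scores(row),
                    items=_row_items(row),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return RecordTable(records=records, coord_system=coord_system, row_errors=errors)


def read_providers(path: str | Path, coord_system: CoordSystem = "projected_m") -> RecordTable:
    """Read a provider table (CSV or GeoJSON points)."""
    df = _load_point_frame(path)
    _require_columns(df, PROVIDER_REQUIRED, path)
    records: list[ProviderRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = pd.Series(row._asdict())
        try:
            records.append(
                ProviderRecord(
                    provider_id=str(row["provider_id"]),
                    area_code=str(row["area_code"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    service_type="" if pd.isna(row.get("service_type", "")) else str(row.get("service_type", "")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return RecordTable(records=records, coord_system=coord_system, row_errors=errors)


def filter_community(cases: Iterable[CaseRecord]) -> tuple[list[CaseRecord], FilterReport]:
    """Keep only community-dwelling cases; institutional residents are excluded."""
    cases = list(cases)
    kept = [c for c in cases if c.residence == "community"]
    report = FilterReport(
        n_input=len(cases),
        n_excluded=len(cases) - len(kept),
        n_retained=len(kept),
        rule="residence == community",
    )
    return kept, report


def dedupe_providers(providers: Iterable[ProviderRecord]) -> tuple[list[ProviderRecord], FilterReport]:
    """Keep the first provider per exact (x, y) coordinate pair.

    Coordinate equality is exact equality of the parsed floats — sites sharing
    an address geocode to bit-identical coordinates, which is the duplication
    this filter removes.
    """
    providers = list(providers)
    seen: set[tuple[float, float]] = set()
    kept: list[ProviderRecord] = []
    for p in providers:
        key = (p.x, p.y)
        if key not in seen:
            seen.add(key)
            kept.append(p)
    report = FilterReport(
        n_input=len(providers),
        n_excluded=len(providers) - len(kept),
        n_retained=len(kept),
        rule="first record per unique (x, y)",
    )
    return kept, report


def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for r in results:
        rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
    return pd.DataFrame(rows)


def write_results(results, path: str | Path, format: Literal["csv", "json"] = "csv") -> None:
    """Persist a result table (DataFrame or list of dataclasses/dicts).

    The written file round-trips: reading it back yields an equal table.
    """
    if results is None:
        raise ValueError("results must not be None")
    df = _to_frame(results)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=float) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: Literal["csv", "json"] = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    return pd.DataFrame(json.loads(path.read_text()))
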