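import textwrap

import pandas as pd
import pytest

from careaccess import data_io
from conftest import LOW_SCORES, make_case, make_provider

CASES_CSV = textwrap.dedent(
    """\
    case_id,area_code,x,y,age,sex,severity,residence,d1,d2,d3,d4,d5,d6,summary
    c1,A,0.0,0.0,80,female,moderate,community,80,85,60,50,70,40,70
    c2,A,10.0,5.0,75,male,mild,community,10,10,10,10,10,10,10
    c3,B,3.0,4.0,90,female,severe,institution,90,90,90,90,90,90,90
    """
)


def test_read_cases_parses_all_valid_rows(tmp_path):
    p = tmp_path / "cases.csv"
    p.write_text(CASES_CSV)
    table = data_io.read_cases(p)
    assert len(table) == 3
    assert table.row_errors == []
    assert table.coord_system == "projected_m"
    assert table[0].case_id == "c1"
    assert table[2].residence == "institution"
    assert table[0].scores.d1_cognition == 80.0


def test_missing_required_column_names_the_column(tmp_path):
    p = tmp_path / "cases.csv"
    p.write_text(CASES_CSV.replace("area_code", "area"))
    with pytest.raises(data_io.SchemaError, match="area_code"):
        data_io.read_cases(p)


def test_unparseable_coordinate_collected_as_row_error(tmp_path):
    p = tmp_path / "cases.csv"
    p.write_text(CASES_CSV.replace("c2,A,10.0", "c2,A,NA"))
    table = data_io.read_cases(p)
    assert len(table) == 2
    assert len(table.row_errors) == 1
    assert table.row_errors[0].row == 2


def test_read_geojson_points(tmp_path):
    import json

    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [121.5, 25.0]},
            "properties": {"provider_id": "p1", "area_code": "A", "service_type": "daycare"},
        }
    ]
    p = tmp_path / "prov.geojson"
    p.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    table = data_io.read_providers(p, coord_system="lonlat")
    assert len(table) == 1
    assert table[0].x == 121.5 and table[0].y == 25.0


@pytest.mark.parametrize(
    "n_total,n_inst",
    [(11_967, 2_263), (50, 0), (50, 50)],
    ids=["registry-scale", "all-community", "all-institution"],
)
def test_filter_community_counts_reconcile(n_total, n_inst):
    cases = [
        make_case(
            case_id=f"c{i}",
            residence="institution" if i < n_inst else "community",
            scores=LOW_SCORES,
        )
        for i in range(n_total)
    ]
    kept, report = data_io.filter_community(cases)
    assert report.n_input == n_total
    assert report.n_excluded == n_inst
    assert report.n_retained == len(kept) == n_total - n_inst
    assert all(c.residence == "community" for c in kept)


def test_filter_community_is_idempotent():
    cases = [make_case(case_id=f"c{i}", residence=r) for i, r in enumerate(["community", "institution"] * 5)]
    once, _ = data_io.filter_community(cases)
    twice, rep = data_io.filter_community(once)
    assert twice == once and rep.n_excluded == 0


def test_dedupe_keeps_first_record_per_coordinate():
    provs = [
        make_provider("A", x=0.0, y=0.0),
        make_provider("B", x=0.0, y=0.0),
        make_provider("C", x=1.0, y=1.0),
    ]
    kept, report = data_io.dedupe_providers(provs)
    assert [p.provider_id for p in kept] == ["A", "C"]
    assert (report.n_input, report.n_excluded, report.n_retained) == (3, 1, 2)


def test_dedupe_matches_pairwise_oracle(rng):
    # oracle: a provider survives iff no earlier provider has equal coordinates
    coords = rng.integers(0, 5, size=(40, 2)).astype(float)
    provs = [make_provider(f"p{i:02d}", x=c[0], y=c[1]) for i, c in enumerate(coords)]
    kept, report = data_io.dedupe_providers(provs)
    survivors = [
        p
        for i, p in enumerate(provs)
        if not any((q.x, q.y) == (p.x, p.y) for q in provs[:i])
    ]
    assert kept == survivors
    assert report.n_excluded == len(provs) - len(survivors)


def test_dedupe_is_idempotent_and_identity_on_unique(rng):
    provs = [make_provider(f"p{i}", x=float(i), y=0.0) for i in range(10)]
    kept, report = data_io.dedupe_providers(provs)
    assert kept == provs and report.n_excluded == 0
    again, rep2 = data_io.dedupe_providers(kept)
    assert again == kept and rep2.n_excluded == 0


def test_filter_report_must_reconcile():
    with pytest.raises(ValueError):
        data_io.FilterReport(n_input=5, n_excluded=1, n_retained=3, rule="r")


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_write_results_round_trip(tmp_path, fmt):
    rows = [
        {"area_code": "A", "pwd_m": 300.0, "category": "both"},
        {"area_code": "B", "pwd_m": 150.0, "category": "only_pwd"},
    ]
    path = tmp_path / f"out.{fmt}"
    data_io.write_results(rows, path, format=fmt)
    back = data_io.read_results(path, format=fmt)
    pd.testing.assert_frame_equal(back, pd.DataFrame(rows))


def test_write_empty_table_gives_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    data_io.write_results(pd.DataFrame(columns=["a", "b"]), path)
    assert path.read_text().strip() == "a,b"
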