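import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from careaccess import spatial
from careaccess.spatial import NearestMatch, NoSupplyError, build_distance_curve
from conftest import make_case, make_provider


def brute_nearest(case, providers, metric="euclidean"):
    """Independent exhaustive scan with explicit id tie-break."""
    best = None
    for p in providers:
        if metric == "euclidean":
            d = np.hypot(case.x - p.x, case.y - p.y)
        else:
            d = float(spatial.haversine_m(np.array([case.x, case.y]), np.array([p.x, p.y])))
        key = (d, p.provider_id)
        if best is None or key < best[0]:
            best = (key, p)
    return best[1], best[0][0]


def test_single_provider_is_matched():
    case = make_case(x=3.0, y=4.0)
    prov = make_provider(x=0.0, y=0.0)
    m = spatial.nearest_provider_distance(case, [prov])
    assert m.provider_id == "p1" and m.distance == pytest.approx(5.0)


def test_collocated_provider_gives_zero_distance_and_id_tiebreak():
    case = make_case(x=1.0, y=1.0)
    provs = [make_provider("b", x=1.0, y=1.0), make_provider("a", x=1.0, y=1.0)]
    m = spatial.nearest_provider_distance(case, provs)
    assert m.distance == 0.0
    assert m.provider_id == "a"


def test_empty_provider_list_is_a_distinct_signal():
    with pytest.raises(NoSupplyError):
        spatial.nearest_provider_distance(make_case(), [])


@pytest.mark.parametrize("metric", ["euclidean", "haversine"])
def test_nearest_matches_bruteforce_scan(rng, metric):
    scale = 0.1 if metric == "haversine" else 1000.0
    cases = [
        make_case(case_id=f"c{i}", x=float(rng.uniform(0, scale)), y=float(rng.uniform(0, scale)))
        for i in range(50)
    ]
    provs = [
        make_provider(f"p{i:02d}", x=float(rng.uniform(0, scale)), y=float(rng.uniform(0, scale)))
        for i in range(20)
    ]
    for case in cases:
        m = spatial.nearest_provider_distance(case, provs, metric=metric)
        oracle_p, oracle_d = brute_nearest(case, provs, metric)
        assert m.provider_id == oracle_p.provider_id
        assert m.distance == pytest.approx(oracle_d)


def test_by_area_equals_per_area_bruteforce(rng):
    cases, provs = [], []
    for a in ("A", "B", "C"):
        for i in range(30):
            cases.append(
                make_case(case_id=f"{a}c{i}", area=a, x=float(rng.uniform(0, 500)), y=float(rng.uniform(0, 500)))
            )
        for i in range(40):  # >32 providers exercises the KD-tree path
            provs.append(
                make_provider(f"{a}p{i:02d}", area=a, x=float(rng.uniform(0, 500)), y=float(rng.uniform(0, 500)))
            )
    matches, unserved = spatial.nearest_distances_by_area(cases, provs)
    assert unserved == [] and len(matches) == len(cases)
    by_id = {m.case_id: m for m in matches}
    for case in cases:
        pool = [p for p in provs if p.area_code == case.area_code]
        _, oracle_d = brute_nearest(case, pool)
        assert by_id[case.case_id].distance == pytest.approx(oracle_d)
        assert by_id[case.case_id].area_code == case.area_code


def test_provider_less_area_cases_reported_separately():
    cases = [make_case(case_id="c1", area="A"), make_case(case_id="c2", area="B")]
    provs = [make_provider(area="A")]
    matches, unserved = spatial.nearest_distances_by_area(cases, provs)
    assert [m.case_id for m in matches] == ["c1"]
    assert [c.case_id for c in unserved] == ["c2"]


def test_cross_area_matching_can_be_enabled():
    cases = [make_case(case_id="c2", area="B", x=1.0)]
    provs = [make_provider(area="A", x=0.0)]
    matches, unserved = spatial.nearest_distances_by_area(cases, provs, allow_cross_area=True)
    assert len(matches) == 1 and unserved == []


def _matches(distances):
    return [NearestMatch(f"c{i}", "p", float(d), "A") for i, d in enumerate(distances)]


def test_binning_half_open_convention():
    curve = build_distance_curve(_matches([10, 60, 70, 120]), bin_width=50)
    assert curve.counts.tolist() == [1, 2, 1]
    # boundary value falls into the upper bin
    curve = build_distance_curve(_matches([50.0]), bin_width=50)
    assert curve.counts.tolist() == [0, 1]


def test_empty_match_list_gives_empty_curve():
    curve = build_distance_curve([], area_code="A")
    assert curve.is_empty() and curve.n_bins == 0


def test_uniform_distances_fill_bins_within_multinomial_ci(rng):
    d = rng.uniform(0, 500, size=1000)
    curve = build_distance_curve(_matches(d), bin_width=50)
    lo, hi = stats.binom.interval(0.99, 1000, 0.1)
    assert curve.n_bins == 10
    assert all(lo <= c <= hi for c in curve.counts)


@given(
    distances=st.lists(st.floats(0, 5_000, allow_nan=False), min_size=1, max_size=200),
    bin_width=st.sampled_from([10.0, 50.0, 125.0]),
)
@settings(max_examples=50, deadline=None)
def test_curve_mass_conservation(distances, bin_width):
    curve = build_distance_curve(_matches(distances), bin_width=bin_width)
    assert curve.counts.sum() == len(distances)
    assert curve.counts[-1] > 0  # trailing zero bins truncated


def test_haversine_symmetry_identity_and_scale():
    a = np.array([121.5, 25.0])
    b = np.array([121.6, 25.1])
    assert spatial.haversine_m(a, a) == 0.0
    assert spatial.haversine_m(a, b) == pytest.approx(spatial.haversine_m(b, a))
    # one degree of latitude is ~111 km
    c = np.array([121.5, 26.0])
    assert spatial.haversine_m(a, c) == pytest.approx(111_195, rel=1e-3)
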