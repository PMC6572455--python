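import pytest

from careaccess import indicators, published
from careaccess.indicators import AreaCategory, AreaResult, Zone
from careaccess.joinpoint import JoinpointFit
from careaccess.pipeline import area_results_from_table


def fit_with(slopes, breakpoints, p_values=None):
    k = len(breakpoints)
    return JoinpointFit(
        k=k,
        breakpoints=tuple(breakpoints),
        intercept=0.0,
        slopes=tuple(slopes),
        rss=0.0,
        n_points=40,
        p_values=tuple(p_values if p_values is not None else [0.01] * k),
    )


class TestExtract:
    def test_peak_then_trough_gives_both(self):
        fit = fit_with([2, -1, 0.5], [300, 1500])
        assert indicators.extract_pwd_tld(fit) == (300, 1500)

    def test_all_rising_gives_neither(self):
        fit = fit_with([1, 2, 3], [300, 1500])
        assert indicators.extract_pwd_tld(fit) == (None, None)

    def test_peak_only_gives_pwd(self):
        fit = fit_with([1, -1], [650])
        assert indicators.extract_pwd_tld(fit) == (650, None)

    def test_insignificant_breakpoints_are_ignored(self):
        fit = fit_with([2, -1, 0.5], [300, 1500], p_values=[0.01, 0.4])
        assert indicators.extract_pwd_tld(fit) == (300, None)

    def test_trough_before_peak_is_not_a_tolerance_bound(self):
        # falling-rising-falling-rising: the trough preceding the supply peak
        # does not qualify as a TLD; the one after it does
        fit = fit_with([-1, 1, -1, 1], [200, 600, 1400])
        assert indicators.extract_pwd_tld(fit) == (600, 1400)

    def test_reported_values_round_to_bin_multiples(self):
        fit = fit_with([2, -1, 0.5], [325, 1475])
        assert indicators.extract_pwd_tld(fit, bin_width=50) == (350, 1500)


@pytest.mark.parametrize(
    "pwd,tld,expected",
    [
        (650, 1200, AreaCategory.BOTH),
        (150, None, AreaCategory.ONLY_PWD),
        (None, 6250, AreaCategory.ONLY_TLD),
        (None, None, AreaCategory.NEITHER),
    ],
)
def test_classify_area(pwd, tld, expected):
    assert indicators.classify_area(pwd, tld) is expected


@pytest.mark.parametrize(
    "cases,providers,expected",
    [(1564, 162, 9.65), (7, 7, 1.0), (3, 6, 0.5)],
)
def test_service_density(cases, providers, expected):
    assert indicators.service_density(cases, providers) == expected


def test_service_density_edge_cases():
    assert indicators.service_density(5, 0) is None
    with pytest.raises(ValueError):
        indicators.service_density(-1, 2)


@pytest.mark.parametrize(
    "d,expected",
    [
        (100, Zone.PROFITABLE),
        (650, Zone.PROFITABLE),  # inclusive upper bound
        (1200, Zone.TOLERABLE),
        (5000, Zone.BEYOND_TOLERANCE),
    ],
)
def test_zone_classification_with_both_bounds(d, expected):
    assert indicators.classify_zone(d, pwd=650, tld=1200) is expected


def test_zone_classification_with_single_bounds():
    assert indicators.classify_zone(800, pwd=None, tld=1200) is Zone.TOLERABLE
    assert indicators.classify_zone(3000, pwd=None, tld=1200) is Zone.BEYOND_TOLERANCE
    assert indicators.classify_zone(100, pwd=650, tld=None) is Zone.PROFITABLE
    # only-PWD area beyond the PWD: undefined, flagged as None
    assert indicators.classify_zone(800, pwd=650, tld=None) is None
    with pytest.raises(ValueError):
        indicators.classify_zone(100, pwd=None, tld=None)


def area(code, pwd, tld, density=1.0):
    return AreaResult(
        area_code=code,
        group="all",
        pwd=pwd,
        tld=tld,
        category=indicators.classify_area(pwd, tld),
        n_cases=10,
        n_providers=10,
        density_ratio=density,
    )


def test_priority_ranking_tiers_and_tld_order():
    results = [
        area("Changhua", 150, 4750),
        area("Taipei", 650, 1200),
        area("Hsinchu City", 150, None),
        area("Penghu", None, None),
        area("Yunlin", None, 6250),
        area("Taitung", None, 1300),
    ]
    ranked = indicators.rank_priorities(results)
    assert [r.area_code for r in ranked] == [
        "Yunlin",
        "Taitung",
        "Changhua",
        "Taipei",
        "Hsinchu City",
        "Penghu",
    ]
    assert [r.priority_rank for r in ranked] == [1, 2, 3, 4, 5, 6]


def test_ranking_is_a_permutation_with_tiebreaks():
    results = [area(c, None, None, density=d) for c, d in [("B", 2.0), ("A", 2.0), ("C", 9.0)]]
    ranked = indicators.rank_priorities(results)
    assert sorted(r.area_code for r in ranked) == ["A", "B", "C"]
    assert [r.area_code for r in ranked] == ["C", "A", "B"]  # density desc, then code


def test_single_area_gets_rank_one():
    ranked = indicators.rank_priorities([area("X", 100, 500)])
    assert ranked[0].priority_rank == 1


def test_duplicate_area_codes_rejected():
    with pytest.raises(ValueError):
        indicators.rank_priorities([area("X", None, None), area("X", 100, 500)])


def test_tld_must_exceed_pwd_when_both_present():
    with pytest.raises(ValueError):
        area("X", 500, 400)


@pytest.mark.parametrize(
    "group,expected",
    [
        ("all", {"both": 15, "only_pwd": 2, "only_tld": 2, "neither": 3}),
        ("general_demand", {"both": 11, "only_pwd": 1, "only_tld": 3, "neither": 7}),
        ("high_level_of_need", {"both": 4, "only_pwd": 1, "only_tld": 4, "neither": 13}),
    ],
)
def test_published_area_table_category_counts(group, expected):
    results = area_results_from_table(published.area_table(), group)
    summary = indicators.summarize(results)
    assert summary == expected
    assert sum(summary.values()) == 22


def test_summarize_empty_is_all_zero():
    assert indicators.summarize([]) == {"both": 0, "only_pwd": 0, "only_tld": 0, "neither": 0}
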