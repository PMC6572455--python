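import itertools

import numpy as np
import pytest
from scipy import stats

from careaccess import joinpoint
from careaccess.joinpoint import InfeasibleFitError, fit_piecewise, select_model
from careaccess.spatial import DistanceCurve
from careaccess.synthetic_data import gen_frequency_curve


def exhaustive_oracle(curve, k, min_seg=3):
    """Independent enumeration: every admissible breakpoint set on the
    half-bin grid, each fitted by its own normal-equations solve."""
    x, y = curve.midpoints, curve.counts.astype(float)
    cand = sorted(set(x) | set((x[:-1] + x[1:]) / 2))
    best = None
    for bps in itertools.combinations(cand, k):
        left = [int(np.sum(x <= b)) for b in bps]
        seg_sizes = np.diff([0, *left, len(x)])
        if seg_sizes.min() < min_seg:
            continue
        X = np.column_stack([np.ones_like(x), x] + [np.maximum(0, x - b) for b in bps])
        beta = np.linalg.solve(X.T @ X + 1e-12 * np.eye(X.shape[1]), X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        if best is None or rss < best[0] - 1e-9:
            best = (rss, bps)
    return best


def test_noiseless_peak_recovered_exactly():
    # y rises at slope 2 to x=300, then falls at slope -1
    curve = gen_frequency_curve([300], [2, -1], 5, 12, 50, 0)
    fit = fit_piecewise(curve, k=1)
    assert fit.breakpoints == (300.0,)
    assert fit.slopes == pytest.approx((2.0, -1.0))
    assert fit.rss == pytest.approx(0.0, abs=1e-12)
    assert fit.slope_changes == pytest.approx((-3.0,))


def test_k0_equals_closed_form_ols(rng):
    counts = rng.integers(5, 80, size=10).astype(float)
    curve = DistanceCurve("A", counts)
    fit = fit_piecewise(curve, k=0)
    ols = stats.linregress(curve.midpoints, counts)
    assert fit.slopes[0] == pytest.approx(ols.slope)
    assert fit.intercept == pytest.approx(ols.intercept)


@pytest.mark.parametrize("seed", [0, 7, 42])
def test_grid_search_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    curve = DistanceCurve("A", rng.integers(0, 100, size=12).astype(float))
    fit = fit_piecewise(curve, k=2)
    rss_oracle, bps_oracle = exhaustive_oracle(curve, k=2)
    assert fit.rss == pytest.approx(rss_oracle, abs=1e-6)
    assert fit.breakpoints == pytest.approx(bps_oracle)


def test_rss_nonincreasing_in_k(rng):
    curve = DistanceCurve("A", rng.integers(0, 100, size=15).astype(float))
    rss = [fit_piecewise(curve, k).rss for k in range(3)]
    assert rss[0] >= rss[1] >= rss[2]


def test_infeasible_k_raises():
    curve = DistanceCurve("A", np.arange(5, dtype=float) + 1)
    with pytest.raises(InfeasibleFitError):
        fit_piecewise(curve, k=1)


def test_bic_selects_single_joinpoint_on_triangle():
    curve = gen_frequency_curve([300], [2, -1], 5, 12, 50, 0)
    fit = select_model(curve, k_max=2, method="bic")
    assert fit.k == 1 and fit.breakpoints == (300.0,)


def test_rise_fall_rise_selected_with_sign_pattern():
    curve = gen_frequency_curve([300, 1500], [0.4, -0.12, 0.05], 40, 40, 50, 0)
    fit = select_model(curve, k_max=3, method="bic")
    assert fit.k == 2
    signs = np.sign(fit.slopes)
    assert signs.tolist() == [1, -1, 1]
    assert fit.breakpoints == pytest.approx((300.0, 1500.0))


def test_degenerate_constant_curve_returns_k0_with_note():
    curve = DistanceCurve("A", np.full(12, 7.0))
    fit = select_model(curve, k_max=2, method="bic")
    assert fit.k == 0 and "degenerate" in fit.note


def test_selection_deterministic_and_seed_reproducible():
    curve = gen_frequency_curve([300, 1500], [0.4, -0.12, 0.05], 40, 30, 50, 4.0, seed=9)
    a = select_model(curve, k_max=2, method="permutation", n_perm=99, seed=5)
    b = select_model(curve, k_max=2, method="permutation", n_perm=99, seed=5)
    assert a == b
    c = fit_piecewise(curve, k=a.k)
    assert c.breakpoints == a.breakpoints and c.rss == pytest.approx(a.rss)


def test_noiseless_slope_change_is_significant():
    curve = gen_frequency_curve([300], [2, -1], 5, 12, 50, 0)
    fit = fit_piecewise(curve, k=1)
    pvals = joinpoint.slope_change_significance(fit, curve, n_perm=99, seed=0)
    assert pvals[0] <= 0.05
    pvals_t = joinpoint.slope_change_significance(fit, curve, method="ttest")
    assert pvals_t[0] <= 0.05


def test_collinear_segments_not_significant():
    # straight line: force a breakpoint, its slope change is ~0
    curve = DistanceCurve("A", 2.0 * (np.arange(12) + 0.5) * 50 + 3)
    fit = fit_piecewise(curve, k=1)
    pvals = joinpoint.slope_change_significance(fit, curve, n_perm=99, seed=0)
    assert pvals[0] > 0.05


def test_detection_power_increases_with_slope_change(rng):
    """Monte-Carlo power at 40 bins: moderate effects reject more often than
    alpha, and bigger slope changes reject more often than smaller ones."""
    n_sims = 40

    def rejection_rate(drop_i, drop):
        hits = 0
        for s in range(n_sims):
            curve = gen_frequency_curve(
                [1000], [0.05, 0.05 - drop], 30, 40, 50, noise_sd=4.0, seed=1000 * drop_i + s
            )
            fit = fit_piecewise(curve, k=1)
            p = joinpoint.slope_change_significance(fit, curve, method="ttest")
            hits += p[0] <= 0.05
        return hits / n_sims

    rates = [rejection_rate(i, drop) for i, drop in enumerate([0.008, 0.03], start=1)]
    assert rates[0] > 0.05
    assert rates[1] >= rates[0]


@pytest.mark.parametrize("noise_sd", [0.0, 1.0, 2.0])
def test_breakpoint_recovery_converges_with_vanishing_noise(noise_sd):
    curve = gen_frequency_curve(
        [300, 1500], [0.4, -0.12, 0.05], 40, 40, 50, noise_sd=noise_sd, seed=21
    )
    fit = fit_piecewise(curve, k=2)
    assert abs(fit.breakpoints[0] - 300) <= 50
    assert abs(fit.breakpoints[1] - 1500) <= 50
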