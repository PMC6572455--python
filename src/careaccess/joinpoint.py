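"""Continuous piecewise-linear (joinpoint) regression on distance curves.

The distance-frequency curve of an area is modelled as a continuous
piecewise-linear function of distance,

    y(x) = b0 + b1*x + sum_i  g_i * max(0, x - tau_i),

with breakpoints ``tau_1 < ... < tau_k`` restricted to a half-bin grid (the
bin midpoints plus the interior bin edges, so that a peak sitting exactly on
a bin boundary is still recoverable) and slope changes ``g_i``.  For a fixed
breakpoint set the model is linear in its coefficients and fitted by least
squares; the breakpoint set itself is chosen by exhaustive grid search over
all placements that leave at least ``min_seg`` bins in every segment, so the
returned fit is the global least-squares optimum on that grid.

Two model-selection routes are provided:

* ``permutation`` (default): a sequential Monte-Carlo test in the style of
  the NCI joinpoint programme.  To test ``k`` joinpoints against ``k-1``,
  residuals of the null (``k-1``) fit are permuted, re-added to the null
  fitted values, and both models are refitted on each permuted series; the
  observed RSS-ratio statistic is compared with its permutation
  distribution.  Testing proceeds upward from ``k=1`` and stops at the first
  non-rejection.
* ``bic``: minimise ``n*log(RSS/n) + p*log(n)`` with ``p = 2 + 2k`` free
  quantities (intercept, base slope, and one slope change plus one location
  per breakpoint).

Per-breakpoint significance of the slope change is assessed either by the
same residual-permutation scheme (dropping the breakpoint under test) or by
a two-sided t-test on its coefficient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import stats

from .spatial import DistanceCurve

SelectionMethod = Literal["bic", "permutation"]

DEFAULT_MIN_SEG = 3
DEFAULT_K_MAX = 4
DEFAULT_N_PERM = 999
DEFAULT_ALPHA = 0.05

_RSS_FLOOR = 1e-10  # treats an (numerically) exact fit as zero residual


class InfeasibleFitError(ValueError):
    """Curve has too few bins for the requested number of breakpoints."""


@dataclass(frozen=True)
class JoinpointFit:
    """A fitted continuous piecewise-linear model.

    ``slopes`` has ``k + 1`` entries (one per segment); ``slope_changes[i]``
    equals ``slopes[i+1] - slopes[i]``.  ``p_values`` are per-breakpoint
    slope-change significance levels (NaN until tested).
    """

    k: int
    breakpoints: tuple[float, ...]
    intercept: float
    slopes: tuple[float, ...]
    rss: float
    n_points: int
    selection: str = "fixed"
    p_values: tuple[float, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.slopes) != self.k + 1:
            raise ValueError("need k+1 segment slopes")
        if len(self.breakpoints) != self.k:
            raise ValueError("need k breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if self.rss < -1e-9:
            raise ValueError("rss must be >= 0")

    @property
    def slope_changes(self) -> tuple[float, ...]:
        return tuple(s2 - s1 for s1, s2 in zip(self.slopes, self.slopes[1:]))

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for tau, g in zip(self.breakpoints, self.slope_changes):
            y = y + g * np.maximum(0.0, x - tau)
        return y

    def significant_breakpoints(self, alpha: float = DEFAULT_ALPHA) -> tuple[bool, ...]:
        if len(self.p_values) != self.k:
            raise ValueError("breakpoints have not been tested")
        return tuple(p <= alpha for p in self.p_values)


def _design(x: np.ndarray, bps: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.maximum(0.0, x - b) for b in bps]
    return np.column_stack(cols)


def _fit_fixed(x: np.ndarray, y: np.ndarray, bps: Sequence[float]) -> tuple[np.ndarray, float]:
    """Least squares with breakpoints held fixed. Returns (beta, rss)."""
    X = _design(x, bps)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)

def _candidate_values(x: np.ndarray, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """Candidate breakpoint locations on the half-bin grid.

    Returns the candidate values and, for each, the number of data points at
    or left of it.  A candidate is admissible when at least ``min_seg``
    points lie on each side.
    """
    vals = np.unique(np.concatenate([x, (x[:-1] + x[1:]) / 2.0]))
    left = np.searchsorted(x, vals, side="right")
    ok = (left >= min_seg) & (len(x) - left >= min_seg)
    return vals[ok], left[ok]


def _combos(x: np.ndarray, k: int, min_seg: int) -> np.ndarray:
    """All admissible breakpoint sets, as an (m, k) array of values.

    Successive breakpoints must have at least ``min_seg`` data points
    between them (counting the point sitting on the later breakpoint).
    """
    if k == 0:
        return np.zeros((1, 0))
    vals, left = _candidate_values(x, min_seg)
    sel = [
        c
        for c in itertools.combinations(range(len(vals)), k)
        if all(left[c[i + 1]] - left[c[i]] >= min_seg for i in range(k - 1))
    ]
    if not sel:
        raise InfeasibleFitError(
            f"{len(x)} bins cannot host {k} breakpoints with min_seg={min_seg}"
        )
    return vals[np.array(sel)]


def _design_batch(x: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Design tensor (m, n, k+2) for every breakpoint set in B (m, k)."""
    m, k = B.shape
    n = len(x)
    ones = np.ones((m, n, 1))
    lin = np.broadcast_to(x, (m, n))[..., None]
    if k == 0:
        return np.concatenate([ones, lin], axis=2)
    hinge = np.maximum(0.0, x[None, :, None] - B[:, None, :])
    return np.concatenate([ones, lin, hinge], axis=2)


_CHUNK = 20_000  # combos per QR batch, bounds peak memory


def _min_rss_over_combos(x: np.ndarray, B: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum RSS over all breakpoint sets, per response row of Y (r, n)."""
    yy = (Y**2).sum(axis=1)
    best = np.full(Y.shape[0], np.inf)
    for s in range(0, len(B), _CHUNK):
        Q = np.linalg.qr(_design_batch(x, B[s : s + _CHUNK]))[0]
        proj = np.einsum("mnp,rn->mrp", Q, Y)
        rss = np.maximum(yy[None, :] - (proj**2).sum(axis=-1), 0.0)
        best = np.minimum(best, rss.min(axis=0))
    return best


def _grid_fit(
    x: np.ndarray, y: np.ndarray, k: int, min_seg: int
) -> tuple[tuple[float, ...], np.ndarray, float]:
    """Exhaustive search over the candidate grid; returns (bps, beta, rss)."""
    B = _combos(x, k, min_seg)
    yy = float(y @ y)
    best_rss, best_i = np.inf, 0
    for s in range(0, len(B), _CHUNK):
        Q = np.linalg.qr(_design_batch(x, B[s : s + _CHUNK]))[0]
        proj = np.einsum("mnp,n->mp", Q, y)
        rss = np.maximum(yy - (proj**2).sum(axis=-1), 0.0)
        i = int(np.argmin(rss))
        if rss[i] < best_rss - 1e-12:
            best_rss, best_i = float(rss[i]), s + i
    bps = tuple(float(b) for b in B[best_i])
    beta, rss = _fit_fixed(x, y, bps)
    return bps, beta, rss


def _fit_from_beta(
    x: np.ndarray, bps: tuple[float, ...], beta: np.ndarray, rss: float, selection: str
) -> JoinpointFit:
    slope_changes = beta[2:]
    slopes = tuple(np.cumsum(np.concatenate([[beta[1]], slope_changes])))
    return JoinpointFit(
        k=len(bps),
        breakpoints=bps,
        intercept=float(beta[0]),
        slopes=tuple(float(s) for s in slopes),
        rss=float(max(rss, 0.0)),
        n_points=len(x),
        selection=selection,
    )


def fit_piecewise(curve: DistanceCurve, k: int, min_seg: int = DEFAULT_MIN_SEG) -> JoinpointFit:
    """Best continuous piecewise-linear fit with exactly ``k`` breakpoints.

    Exhaustive over the candidate grid of bin midpoints, hence deterministic
    and globally optimal on that grid.
    """
    if curve.is_empty():
        raise InfeasibleFitError("empty curve")
    if min_seg < 2:
        raise ValueError("min_seg must be >= 2 (segments need a defined slope)")
    x, y = curve.midpoints, curve.counts.astype(float)
    if len(x) < (k + 1) * min_seg:
        raise InfeasibleFitError(
            f"{len(x)} bins cannot host {k} breakpoints with min_seg={min_seg}"
        )
    bps, beta, rss = _grid_fit(x, y, k, min_seg)
    return _fit_from_beta(x, bps, beta, rss, selection="fixed")


def _max_feasible_k(n: int, k_max: int, min_seg: int) -> int:
    return min(k_max, max(0, n // min_seg - 1))


def _perm_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    k_null: int,
    k_alt: int,
    min_seg: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for k_alt joinpoints against the k_null model."""
    bps0, beta0, rss0 = _grid_fit(x, y, k_null, min_seg)
    _, _, rss1 = _grid_fit(x, y, k_alt, min_seg)
    t_obs = (rss0 - rss1) / max(rss1, _RSS_FLOOR)

    fitted0 = _design(x, bps0) @ beta0
    resid0 = y - fitted0
    perms = np.stack([rng.permutation(resid0) for _ in range(n_perm)])
    Y = fitted0[None, :] + perms

    rss_null = _min_rss_over_combos(x, _combos(x, k_null, min_seg), Y)
    rss_alt = _min_rss_over_combos(x, _combos(x, k_alt, min_seg), Y)
    t_perm = (rss_null - rss_alt) / np.maximum(rss_alt, _RSS_FLOOR)
    return float((1 + int((t_perm >= t_obs - 1e-12).sum())) / (n_perm + 1))


def select_model(
    curve: DistanceCurve,
    k_max: int = DEFAULT_K_MAX,
    method: SelectionMethod = "permutation",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_seg: int = DEFAULT_MIN_SEG,
) -> JoinpointFit:
    """Choose the number of joinpoints and return the selected fit.

    The returned fit carries per-breakpoint p-values from
    :func:`slope_change_significance` (matching the selection route:
    permutation test or t-test).
    """
    if curve.is_empty():
        raise InfeasibleFitError("empty curve")
    x, y = curve.midpoints, curve.counts.astype(float)
    n = len(x)
    k_cap = _max_feasible_k(n, k_max, min_seg)

    if np.allclose(y, y[0]):
        combo, beta, rss = _grid_fit(x, y, 0, min_seg)
        fit = _fit_from_beta(x, combo, beta, rss, selection=method)
        return replace(fit, note="degenerate: constant curve, k=0 by definition")

    if method == "bic":
        best_fit, best_bic = None, np.inf
        for k in range(0, k_cap + 1):
            combo, beta, rss = _grid_fit(x, y, k, min_seg)
            p = 2 + 2 * k
            bic = n * np.log(max(rss, _RSS_FLOOR) / n) + p * np.log(n)
            if bic < best_bic - 1e-12:
                best_fit, best_bic = _fit_from_beta(x, combo, beta, rss, "bic"), bic
        fit = best_fit
    elif method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        k_sel = 0
        for k in range(1, k_cap + 1):
            p = _perm_pvalue(x, y, k - 1, k, min_seg, n_perm, rng)
            if p <= alpha:
                k_sel = k
            else:
                break
        combo, beta, rss = _grid_fit(x, y, k_sel, min_seg)
        fit = _fit_from_beta(x, combo, beta, rss, "permutation")
    else:
        raise ValueError(f"unknown selection method {method!r}")

    if fit.k > 0:
        test = "permutation" if method == "permutation" else "ttest"
        pvals = slope_change_significance(
            fit, curve, alpha=alpha, n_perm=n_perm, seed=seed, method=test, min_seg=min_seg
        )
        fit = replace(fit, p_values=pvals)
    return fit


def slope_change_significance(
    fit: JoinpointFit,
    curve: DistanceCurve,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    method: Literal["permutation", "ttest"] = "permutation",
    min_seg: int = DEFAULT_MIN_SEG,
) -> tuple[float, ...]:
    """Two-sided significance of each breakpoint's slope change.

    ``permutation``: drop the breakpoint under test (other breakpoints held
    fixed), permute the residuals of that reduced fit and compare RSS-ratio
    statistics.  ``ttest``: t-test on the slope-change coefficient of the
    full fixed-breakpoint fit.  Returns one p-value per breakpoint; use
    :meth:`JoinpointFit.significant_breakpoints` to threshold them.
    """
    x, y = curve.midpoints, curve.counts.astype(float)
    bps = list(fit.breakpoints)
    if not bps:
        return ()
    pvals: list[float] = []
    if method == "ttest":
        X = _design(x, bps)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(x) - X.shape[1]
        if dof <= 0:
            return tuple(np.nan for _ in bps)
        s2 = float(resid @ resid) / dof
        if s2 <= _RSS_FLOOR:
            # (numerically) perfect fit: nonzero slope change is unambiguous
            return tuple(0.0 if abs(g) > 1e-9 else 1.0 for g in fit.slope_changes)
        cov = s2 * np.linalg.pinv(X.T @ X)
        for i in range(len(bps)):
            se = np.sqrt(cov[2 + i, 2 + i])
            t = beta[2 + i] / se if se > 0 else np.inf
            pvals.append(float(2 * stats.t.sf(abs(t), dof)))
        return tuple(pvals)

    rng = np.random.default_rng(seed)
    _, rss_full = _fit_fixed(x, y, bps)
    for i, g in enumerate(fit.slope_changes):
        if abs(g) < 1e-12:
            pvals.append(1.0)  # collinear segments: nothing to test
            continue
        reduced = bps[:i] + bps[i + 1 :]
        beta_r, rss_r = _fit_fixed(x, y, reduced)
        t_obs = (rss_r - rss_full) / max(rss_full, _RSS_FLOOR)
        fitted_r = _design(x, reduced) @ beta_r
        resid_r = y - fitted_r
        count = 0
        Y = fitted_r[None, :] + np.stack([rng.permutation(resid_r) for _ in range(n_perm)])
        Qr, _ = np.linalg.qr(_design(x, reduced))
        Qf, _ = np.linalg.qr(_design(x, bps))
        rss_r_perm = np.maximum((Y**2).sum(1) - ((Y @ Qr) ** 2).sum(1), 0.0)
        rss_f_perm = np.maximum((Y**2).sum(1) - ((Y @ Qf) ** 2).sum(1), 0.0)
        t_perm = (rss_r_perm - rss_f_perm) / np.maximum(rss_f_perm, _RSS_FLOOR)
        count = int((t_perm >= t_obs - 1e-12).sum())
        pvals.append(float((1 + count) / (n_perm + 1)))
    return tuple(pvals)


def fit_to_dict(fit: JoinpointFit, seed: int | None = None) -> dict:
    """JSON-ready export of a fit."""
    return {
        "k": fit.k,
        "breakpoints": list(fit.breakpoints),
        "intercept": fit.intercept,
        "slopes": list(fit.slopes),
        "slope_changes": list(fit.slope_changes),
        "p_values": list(fit.p_values),
        "rss": fit.rss,
        "n_points": fit.n_points,
        "selection": fit.selection,
        "seed": seed,
        "note": fit.note,
    }
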