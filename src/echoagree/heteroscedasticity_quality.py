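"""Precision across the measurement range and image-quality effects.

Straight quantile-regression lines at tau = 0.16, 0.50 and 0.84 describe
how paired differences spread as a function of measurement magnitude
(pair mean); the precision-range curve is half the gap between the outer
quantile lines, optionally scaled by 1/sqrt(2) like the pointwise
precision.  Image-quality strata (good / moderate / low) are compared
with the Kruskal-Wallis test for median differences and the Levene test
(median-centered Brown-Forsythe variant by default) for equality of
variance.

The quantile fit minimizes the pinball loss
``sum rho_tau(d_i - a - b x_i)`` with ``rho_tau(u) = u (tau - 1{u<0})``
*exactly*: by vertex enumeration over lines through data-point pairs for
small n (the LP optimum lies on such a line) and by linear programming
otherwise.  No smoothed approximation is used, so fits can be checked
against a brute-force oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy import stats as _sps
from scipy.optimize import linprog

from .agreement_stats import SQRT2, DifferenceSet, InsufficientDataError
from .core_io import MeasurementTable, QUALITY_CATEGORIES, quality_category

DEFAULT_TAUS = (0.16, 0.50, 0.84)

# Above this size pairwise vertex enumeration (O(n^3)) gives way to an LP.
_VERTEX_MAX_N = 200


@dataclass
class QuantileLine:
    """One fitted straight quantile line with its achieved pinball loss."""

    tau: float
    intercept: float
    slope: float
    pinball_loss: float


@dataclass
class PrecisionRangeModel:
    """Quantile lines at tau = 0.16 / 0.50 / 0.84 and the scaling choice."""

    line16: QuantileLine
    line50: QuantileLine
    line84: QuantileLine
    scaled: bool = True


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: tuple
    df_denom: int | None = None


@dataclass
class QualityImpactResult:
    """Quality-stratified median and variance tests for one reader pair."""

    parameter: str
    ref_reader: str
    comp_reader: str
    scale: str
    group_sizes: dict
    kruskal_wallis: GroupTestResult
    levene: GroupTestResult | None


def pinball_loss(residuals, tau: float) -> float:
    """sum of rho_tau over residuals, rho_tau(u) = u * (tau - 1{u < 0})."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0.0))))


def _fit_intercept_only(d: np.ndarray, tau: float) -> tuple[float, float]:
    # Minimizer set of the pinball loss over constants is an order-statistic
    # interval; the tie-break picks its smallest element.
    cand = np.unique(d)
    losses = np.array([pinball_loss(d - c, tau) for c in cand])
    best = losses.min()
    c = float(cand[losses <= best + 1e-12 * (1.0 + abs(best))][0])
    return c, pinball_loss(d - c, tau)


def _fit_vertex(x: np.ndarray, d: np.ndarray, tau: float) -> QuantileLine:
    n = len(x)
    i, j = np.triu_indices(n, 1)
    dx = x[j] - x[i]
    keep = dx != 0.0
    i, j, dx = i[keep], j[keep], dx[keep]
    b = (d[j] - d[i]) / dx
    a = d[i] - b * x[i]
    resid = d[None, :] - a[:, None] - b[:, None] * x[None, :]
    loss = np.sum(resid * (tau - (resid < 0.0)), axis=1)
    best = loss.min()
    cand = np.flatnonzero(loss <= best + 1e-9 * (1.0 + abs(best)))
    # Deterministic tie-break: smallest |slope|, then smallest intercept.
    k = cand[np.lexsort((a[cand], np.abs(b[cand])))][0]
    return QuantileLine(tau, float(a[k]), float(b[k]), float(loss[k]))


def _fit_lp(x: np.ndarray, d: np.ndarray, tau: float) -> QuantileLine:
    n = len(x)
    # Variables: a+, a-, b+, b-, u_1..u_n, v_1..v_n  (all >= 0);
    # constraints: (a+ - a-) + (b+ - b-) x_i + u_i - v_i = d_i.
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    ones = np.ones(n)
    A = sparse.hstack(
        [
            sparse.csc_matrix(ones[:, None]),
            sparse.csc_matrix(-ones[:, None]),
            sparse.csc_matrix(x[:, None]),
            sparse.csc_matrix(-x[:, None]),
            sparse.identity(n, format="csc"),
            -sparse.identity(n, format="csc"),
        ],
        format="csc",
    )
    res = linprog(c, A_eq=A, b_eq=d, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = float(res.x[0] - res.x[1])
    b = float(res.x[2] - res.x[3])
    return QuantileLine(tau, a, b, pinball_loss(d - a - b * x, tau))


def quantile_line_fit(x, d, tau: float, method: str = "auto") -> QuantileLine:
    """Exact straight-line quantile regression of d on x at level tau.

    When all x coincide the slope is unidentifiable; an intercept-only fit
    (the sample tau-quantile) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    if x.shape != d.shape or x.ndim != 1:
        raise ValueError("x and d must be 1-D arrays of equal length")
    if len(x) < 3:
        raise InsufficientDataError("quantile fit needs at least 3 points")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if np.ptp(x) == 0.0:
        warnings.warn(
            "all range-axis values identical: slope unidentifiable, fitting intercept only",
            stacklevel=2,
        )
        c, loss = _fit_intercept_only(d, tau)
        return QuantileLine(tau, c, 0.0, loss)
    if method == "auto":
        method = "vertex" if len(x) <= _VERTEX_MAX_N else "lp"
    if method == "vertex":
        return _fit_vertex(x, d, tau)
    if method == "lp":
        return _fit_lp(x, d, tau)
    raise ValueError(f"method must be 'auto', 'vertex' or 'lp', got {method!r}")


def fit_precision_range(x, d, scaled: bool = True, method: str = "auto") -> PrecisionRangeModel:
    """Fit the three standard quantile lines to (range axis, differences)."""
    lines = {tau: quantile_line_fit(x, d, tau, method=method) for tau in DEFAULT_TAUS}
    return PrecisionRangeModel(
        line16=lines[0.16], line50=lines[0.50], line84=lines[0.84], scaled=scaled
    )


def precision_range_curve(model: PrecisionRangeModel, x_values) -> np.ndarray:
    """Precision as a function of magnitude: (q84(x) - q16(x)) / 2.

    Divided by sqrt(2) when the model is scaled.  Negative values indicate
    crossing quantile lines; they are returned as-is with a warning rather
    than clipped.
    """
    x = np.atleast_1d(np.asarray(x_values, dtype=float))
    q16 = model.line16.intercept + model.line16.slope * x
    q84 = model.line84.intercept + model.line84.slope * x
    p = (q84 - q16) / 2.0
    if model.scaled:
        p = p / SQRT2
    if np.any(p < 0.0):
        warnings.warn(
            "quantile lines cross inside the evaluated range: negative precision values",
            stacklevel=2,
        )
    return p


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal-Wallis H on midranks with tie correction.

    Degenerate all-identical data returns H = 0, p = 1 instead of erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise InsufficientDataError("Kruskal-Wallis needs at least 3 observations")
    sizes = tuple(len(g) for g in groups)
    if np.ptp(pooled) == 0.0:
        return GroupTestResult(0.0, k - 1, 1.0, sizes)
    h, p = _sps.kruskal(*groups)
    return GroupTestResult(float(h), k - 1, float(p), sizes)


def levene_test(groups, center: str = "median") -> GroupTestResult:
    """Levene/Brown-Forsythe test of equal variance across groups.

    One-way ANOVA F on absolute deviations from the group center; the
    default median centering is the robust Brown-Forsythe variant.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("Levene test needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs at least 2 observations")
    sizes = tuple(len(g) for g in groups)
    big_n = sum(sizes)
    centers = [np.median(g) if center == "median" else np.mean(g) for g in groups]
    devs = [np.abs(g - c) for g, c in zip(groups, centers)]
    if max(float(np.max(dv)) for dv in devs) == 0.0:
        return GroupTestResult(0.0, k - 1, 1.0, sizes, df_denom=big_n - k)
    w, p = _sps.levene(*groups, center=center)
    return GroupTestResult(float(w), k - 1, float(p), sizes, df_denom=big_n - k)


def quality_stratified_tests(
    table: MeasurementTable,
    parameter: str,
    ref_reader: str,
    comp_reader: str,
    scale: str = "relative",
    levene_center: str = "median",
) -> QualityImpactResult:
    """Test whether image quality shifts bias (KW) or precision (Levene).

    Quality is a property of the acquired image, shared by all readers of
    it; the reference reader's recorded score defines the stratum of each
    pair.  Groups with a single pair enter the Kruskal-Wallis test but are
    excluded from the Levene test (which needs >= 2 per group); the Levene
    result is None when fewer than two usable strata remain.
    """
    from .agreement_stats import paired_differences

    ds = paired_differences(table, parameter, ref_reader, comp_reader)
    df = table.df
    ref_rows = df[(df["parameter"] == parameter) & (df["reader"] == ref_reader)]
    scores = ref_rows.set_index("subject_id")["quality_score"]

    d = ds.diffs(scale)
    subjects = ds.axis_subjects(scale)
    by_cat: dict[str, list[float]] = {c: [] for c in QUALITY_CATEGORIES}
    for sid, val in zip(subjects, d):
        q = scores.get(sid)
        if q is None or (isinstance(q, float) and math.isnan(q)):
            continue
        by_cat[quality_category(q)].append(float(val))
    groups = {c: np.asarray(v) for c, v in by_cat.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need at least 2 quality strata with data")
    kw = kruskal_wallis(list(groups.values()))
    lev_groups = [g for g in groups.values() if len(g) >= 2]
    lev = levene_test(lev_groups, center=levene_center) if len(lev_groups) >= 2 else None
    return QualityImpactResult(
        parameter=parameter,
        ref_reader=ref_reader,
        comp_reader=comp_reader,
        scale=scale,
        group_sizes={c: len(g) for c, g in groups.items()},
        kruskal_wallis=kw,
        levene=lev,
    )
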