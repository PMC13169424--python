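"""Duplicate-read agreement statistics.

For a (reference, comparator) reader pair on one parameter the paired
differences ``d_i = comp_i - ref_i`` (positive when the comparator reads
higher) are analyzed on a nominal scale or on a relative scale
``r_i = 100 * d_i / pair mean``.  Bias is the sample median; precision is
half the central 68% spread, ``(P84 - P16) / 2``, optionally divided by
sqrt(2) to convert the dispersion of a *difference of two reads* into
per-read dispersion.  Confidence intervals come from a seeded percentile
bootstrap that resamples the paired differences.  Classical companions
(Bland-Altman limits of agreement, RMS error, Spearman correlation) and
the laboratory-medicine reference change value are included for context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import stats as _sps

from .core_io import MeasurementTable

SQRT2 = math.sqrt(2.0)

#: Percentile pair whose half-spread equals 1 SD for normal data.
PRECISION_PERCENTILES = (16.0, 84.0)


class InsufficientDataError(ValueError):
    """Too few paired observations for the requested statistic."""


@dataclass
class YieldResult:
    """Read availability of a comparator relative to a reference reader."""

    parameter: str
    ref_reader: str
    comp_reader: str
    n_ref: int
    n_comp: int
    n_common: int
    relative_yield_pct: float


@dataclass
class DifferenceSet:
    """Paired reads of one parameter for one (reference, comparator) pair.

    Nominal differences, relative differences (pair-mean denominator) and
    the measurement-range axis (pair mean) are derived lazily.  Pairs whose
    mean is nonpositive are excluded from relative-scale quantities, with
    the exclusion count recorded.
    """

    parameter: str
    ref_reader: str
    comp_reader: str
    subjects: np.ndarray
    ref: np.ndarray
    comp: np.ndarray

    def __post_init__(self):
        self.subjects = np.asarray(self.subjects)
        self.ref = np.asarray(self.ref, dtype=float)
        self.comp = np.asarray(self.comp, dtype=float)
        if not (len(self.ref) == len(self.comp) == len(self.subjects)):
            raise ValueError("ref, comp and subjects must have equal length")
        if len(self.ref) < 1:
            raise InsufficientDataError("difference set needs at least one pair")

    @property
    def n(self) -> int:
        return len(self.ref)

    @cached_property
    def nominal_diffs(self) -> np.ndarray:
        return self.comp - self.ref

    @cached_property
    def range_axis(self) -> np.ndarray:
        return (self.ref + self.comp) / 2.0

    @cached_property
    def _relative_mask(self) -> np.ndarray:
        return self.range_axis > 0.0

    @cached_property
    def relative_diffs(self) -> np.ndarray:
        m = self._relative_mask
        return 100.0 * self.nominal_diffs[m] / self.range_axis[m]

    @property
    def n_excluded_relative(self) -> int:
        return int((~self._relative_mask).sum())

    def diffs(self, scale: str) -> np.ndarray:
        if scale == "nominal":
            return self.nominal_diffs
        if scale == "relative":
            return self.relative_diffs
        raise ValueError(f"scale must be 'nominal' or 'relative', got {scale!r}")

    def axis(self, scale: str) -> np.ndarray:
        if scale == "nominal":
            return self.range_axis
        if scale == "relative":
            return self.range_axis[self._relative_mask]
        raise ValueError(f"scale must be 'nominal' or 'relative', got {scale!r}")

    def axis_subjects(self, scale: str) -> np.ndarray:
        return self.subjects if scale == "nominal" else self.subjects[self._relative_mask]


@dataclass
class AgreementSummary:
    """Headline agreement metrics for one parameter and reader pair."""

    parameter: str
    ref_reader: str
    comp_reader: str
    scale: str
    n: int
    bias: float
    precision_unscaled: float
    precision: float
    ci_bias: tuple
    ci_precision: tuple
    B: int
    seed: int
    n_excluded_relative: int = 0
    relative_yield_pct: float = float("nan")


@dataclass
class RCVResult:
    """Reference change value decomposition (all CVs in percent)."""

    cv_analytic: float
    cv_biological: float
    z: float
    cv_total: float
    rcv_pct: float


def compute_yield(
    table: MeasurementTable, parameter: str, ref_reader: str, comp_reader: str
) -> YieldResult:
    """Relative yield: share of reference reads the comparator also produced."""
    df = table.df
    sub = df[df["parameter"] == parameter]
    ref_ids = set(sub.loc[sub["reader"] == ref_reader, "subject_id"])
    comp_ids = set(sub.loc[sub["reader"] == comp_reader, "subject_id"])
    if not ref_ids:
        raise InsufficientDataError(
            f"no {ref_reader} reads of {parameter}: relative yield undefined"
        )
    n_common = len(ref_ids & comp_ids)
    return YieldResult(
        parameter=parameter,
        ref_reader=ref_reader,
        comp_reader=comp_reader,
        n_ref=len(ref_ids),
        n_comp=len(comp_ids),
        n_common=n_common,
        relative_yield_pct=100.0 * n_common / len(ref_ids),
    )


def paired_differences(
    table: MeasurementTable, parameter: str, ref_reader: str, comp_reader: str
) -> DifferenceSet:
    """Collect subjects read by both readers into a :class:`DifferenceSet`."""
    df = table.df
    sub = df[df["parameter"] == parameter]
    ref = sub[sub["reader"] == ref_reader].set_index("subject_id")["value"]
    comp = sub[sub["reader"] == comp_reader].set_index("subject_id")["value"]
    common = ref.index.intersection(comp.index).sort_values()
    if len(common) == 0:
        raise InsufficientDataError(
            f"no common {parameter} reads for ({ref_reader}, {comp_reader})"
        )
    return DifferenceSet(
        parameter=parameter,
        ref_reader=ref_reader,
        comp_reader=comp_reader,
        subjects=common.to_numpy(),
        ref=ref.loc[common].to_numpy(dtype=float),
        comp=comp.loc[common].to_numpy(dtype=float),
    )


def robust_bias(ds: DifferenceSet, scale: str = "nominal") -> float:
    """Median paired difference (linear interpolation at even n)."""
    d = ds.diffs(scale)
    if len(d) < 1:
        raise InsufficientDataError("bias needs at least one difference")
    return float(np.median(d))


def _precision_from_diffs(d: np.ndarray, scaled: bool) -> float:
    lo, hi = np.percentile(d, PRECISION_PERCENTILES)
    p = (hi - lo) / 2.0
    return p / SQRT2 if scaled else p


def percentile_precision(ds: DifferenceSet, scale: str = "nominal", scaled: bool = True) -> float:
    """Half the P84-P16 spread of the differences; / sqrt(2) when scaled.

    Percentiles interpolate linearly between order statistics, the k-th of n
    points sitting at probability (k - 1) / (n - 1).
    """
    d = ds.diffs(scale)
    if len(d) < 2:
        raise InsufficientDataError("precision needs at least two differences")
    return float(_precision_from_diffs(d, scaled))


def bootstrap_ci(
    statistic: str,
    ds: DifferenceSet,
    B: int = 1000,
    seed: int = 0,
    scale: str = "nominal",
    scaled: bool = True,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap 95% CI for ``bias`` or ``precision``.

    The resampling unit is the paired difference (one subject), preserving
    pairing; the interval is the (2.5, 97.5) percentile span of the B
    resampled statistics.
    """
    if statistic not in ("bias", "precision"):
        raise ValueError(f"statistic must be 'bias' or 'precision', got {statistic!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    d = ds.diffs(scale)
    if len(d) < 2:
        raise InsufficientDataError("bootstrap needs at least two differences")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(B, len(d)))
    samples = d[idx]
    if statistic == "bias":
        boot = np.median(samples, axis=1)
    else:
        lo, hi = np.percentile(samples, PRECISION_PERCENTILES, axis=1)
        boot = (hi - lo) / 2.0
        if scaled:
            boot = boot / SQRT2
    lo_ci, hi_ci = np.percentile(boot, [2.5, 97.5])
    return float(lo_ci), float(hi_ci)


def bland_altman_loa(ds: DifferenceSet, scale: str = "nominal") -> tuple[float, float, float]:
    """Mean difference and limits of agreement, mean +/- 1.96 * sample SD."""
    d = ds.diffs(scale)
    if len(d) < 2:
        raise InsufficientDataError("limits of agreement need at least two differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def rms_error(ds: DifferenceSet, scale: str = "nominal") -> float:
    """Root mean square difference: global measure of bias plus imprecision.

    Satisfies ``rms^2 = mean(d)^2 + population variance(d)`` exactly, so it
    always dominates the dispersion-only measures when bias is present.
    """
    d = ds.diffs(scale)
    if len(d) < 1:
        raise InsufficientDataError("RMS needs at least one difference")
    return float(np.sqrt(np.mean(d**2)))


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson on midranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise InsufficientDataError("Spearman correlation needs at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("undefined correlation: zero rank variance")
    return float(_sps.spearmanr(x, y).statistic)


def reference_change_value(
    cv_analytic: float, cv_biological: float = 0.0, z: float = 1.96
) -> RCVResult:
    """Smallest serial change exceeding combined analytic + biological noise.

    ``RCV = sqrt(2) * z * cv_total`` with ``cv_total`` the quadrature sum of
    the analytic and within-subject biological CVs (percent).
    """
    if cv_analytic < 0 or cv_biological < 0:
        raise ValueError("coefficients of variation must be >= 0")
    if z <= 0:
        raise ValueError("z must be positive")
    cv_total = math.hypot(cv_analytic, cv_biological)
    return RCVResult(
        cv_analytic=float(cv_analytic),
        cv_biological=float(cv_biological),
        z=float(z),
        cv_total=cv_total,
        rcv_pct=SQRT2 * z * cv_total,
    )


def summarize_agreement(
    table: MeasurementTable,
    parameter: str,
    ref_reader: str,
    comp_reader: str,
    scale: str = "relative",
    B: int = 1000,
    seed: int = 0,
) -> AgreementSummary:
    """One-stop yield + bias + precision summary with bootstrap CIs."""
    yld = compute_yield(table, parameter, ref_reader, comp_reader)
    ds = paired_differences(table, parameter, ref_reader, comp_reader)
    bias = robust_bias(ds, scale)
    prec_raw = percentile_precision(ds, scale, scaled=False)
    prec = prec_raw / SQRT2
    ci_bias = bootstrap_ci("bias", ds, B=B, seed=seed, scale=scale)
    ci_prec = bootstrap_ci("precision", ds, B=B, seed=seed + 1, scale=scale, scaled=True)
    return AgreementSummary(
        parameter=parameter,
        ref_reader=ref_reader,
        comp_reader=comp_reader,
        scale=scale,
        n=len(ds.diffs(scale)),
        bias=bias,
        precision_unscaled=prec_raw,
        precision=prec,
        ci_bias=ci_bias,
        ci_precision=ci_prec,
        B=B,
        seed=seed,
        n_excluded_relative=ds.n_excluded_relative,
        relative_yield_pct=yld.relative_yield_pct,
    )
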