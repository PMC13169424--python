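"""PH discrimination: matching, ROC/AUC, DeLong comparison, labeling.

AUC is the midrank (Mann-Whitney) estimator: the mean over all
positive/negative pairs of 1 if the positive marker exceeds the negative,
1/2 on ties.  Variances and the paired comparison follow DeLong's
structural-component construction: per-positive components
``V10_i = (TZ_i - TX_i) / n`` and per-negative components
``V01_j = 1 - (TZ_j - TY_j) / m`` (TZ combined midranks, TX/TY
within-class midranks), with variances and covariances of the AUCs from
the component sample covariances scaled by 1/m and 1/n.  Markers where
*lower* values indicate disease (TAPSE, RVFAC) are sign-flipped via the
orientation registry before ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core_io import MeasurementTable

#: +1 where higher values indicate disease, -1 where lower values do.
PARAMETER_ORIENTATION = {
    "TRV": 1,
    "RV_basal_diameter": 1,
    "TAPSE": -1,
    "RA_area": 1,
    "RVEDA": 1,
    "RVESA": 1,
    "RVFAC": -1,
}

#: Guideline TRV bands (m/s) for the echocardiographic PH probability
#: category; editable configuration, not part of this package's statistics.
GUIDELINE_TRV_BANDS = {"low_max": 2.8, "intermediate_max": 3.4}

_PH_MPAP_THRESHOLD = 20.0  # strict: PH iff MPAP > 20 mm Hg
_REFERRAL_MPAP_MAX = 35.0


@dataclass
class MatchedCohort:
    pairs: list  # (case_id, control_id)
    unmatched_cases: list
    unmatched_controls: list
    criteria: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    ci_95: tuple
    variance: float


@dataclass
class DeLongComparison:
    auc1: float
    auc2: float
    var1: float
    var2: float
    covariance: float
    z: float
    p_value: float


def classify_ph(mpap_mmhg: float) -> str:
    """PH iff MPAP strictly exceeds 20 mm Hg; 20.0 itself is no_PH."""
    if mpap_mmhg <= 0:
        raise ValueError("MPAP must be positive")
    return "PH" if mpap_mmhg > _PH_MPAP_THRESHOLD else "no_PH"


def referral_eligible(mpap_mmhg: float) -> bool:
    """Mild-PH referral band membership: MPAP <= 35 mm Hg."""
    if mpap_mmhg <= 0:
        raise ValueError("MPAP must be positive")
    return mpap_mmhg <= _REFERRAL_MPAP_MAX


def match_case_control(cases, controls, caliper_years: float | None = None) -> MatchedCohort:
    """Greedy 1:1 age/sex matching with deterministic tie-breaks.

    Sex must match exactly; each case takes the nearest-age unused control,
    cases being processed hardest-first (fewest eligible controls at the
    outset).  Age gaps beyond the caliper are rejected.  Ties in difficulty
    break by case id; ties in age gap break by control id.  Unmatched
    subjects are listed, never fatal.
    """
    cases = [(str(i), float(a), str(s)) for i, a, s in cases]
    controls = [(str(i), float(a), str(s)) for i, a, s in controls]
    if not cases or not controls:
        raise ValueError("need non-empty case and control sets")

    def eligible(case):
        _, age, sex = case
        return [
            c for c in controls
            if c[2] == sex and (caliper_years is None or abs(c[1] - age) <= caliper_years)
        ]

    order = sorted(cases, key=lambda c: (len(eligible(c)), c[0]))
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    unmatched_cases: list[str] = []
    for cid, age, sex in order:
        cands = [
            (abs(c[1] - age), c[0])
            for c in controls
            if c[2] == sex
            and c[0] not in used
            and (caliper_years is None or abs(c[1] - age) <= caliper_years)
        ]
        if not cands:
            unmatched_cases.append(cid)
            continue
        gap, ctrl_id = min(cands)
        used.add(ctrl_id)
        pairs.append((cid, ctrl_id))
    pairs.sort()
    return MatchedCohort(
        pairs=pairs,
        unmatched_cases=sorted(unmatched_cases),
        unmatched_controls=sorted(c[0] for c in controls if c[0] not in used),
        criteria={"sex": "exact", "caliper_years": caliper_years},
    )


def _delong_components(marker: np.ndarray, labels: np.ndarray):
    pos = marker[labels]
    neg = marker[~labels]
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise ValueError("need at least one positive and one negative subject")
    tz = _sps.rankdata(np.concatenate([pos, neg]))
    tx = _sps.rankdata(pos)
    ty = _sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(v10.mean()), v10, v01


def _prepare(marker, labels, higher_is_disease):
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if marker.shape != labels.shape or marker.ndim != 1:
        raise ValueError("marker and labels must be 1-D and equal length")
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    if not higher_is_disease:
        marker = -marker
    return marker, labels


def auc(marker, labels, higher_is_disease: bool = True) -> ROCResult:
    """Midrank AUC with a DeLong-variance Wald 95% CI (clipped to [0, 1])."""
    marker, labels = _prepare(marker, labels, higher_is_disease)
    a, v10, v01 = _delong_components(marker, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    half = 1.96 * math.sqrt(var)
    return ROCResult(
        auc=a,
        n_pos=m,
        n_neg=n,
        ci_95=(max(0.0, a - half), min(1.0, a + half)),
        variance=var,
    )


def delong_compare(marker1, marker2, labels, higher_is_disease: bool = True) -> DeLongComparison:
    """Paired test of AUC difference for two markers on the same subjects.

    Two-sided normal p-value.  A self-comparison (identical markers) has a
    degenerate variance and returns z = 0, p = 1; a degenerate variance
    with *unequal* AUCs is reported as non-computable (NaN z and p) with a
    warning.
    """
    m1, labels1 = _prepare(marker1, labels, higher_is_disease)
    m2, labels2 = _prepare(marker2, labels, higher_is_disease)
    a1, v10_1, v01_1 = _delong_components(m1, labels1)
    a2, v10_2, v01_2 = _delong_components(m2, labels2)
    m, n = len(v10_1), len(v01_1)
    if m < 2 or n < 2:
        raise ValueError("DeLong comparison needs at least 2 subjects per class")
    s10 = np.cov(v10_1, v10_2, ddof=1)
    s01 = np.cov(v01_1, v01_2, ddof=1)
    var1 = float(s10[0, 0]) / m + float(s01[0, 0]) / n
    var2 = float(s10[1, 1]) / m + float(s01[1, 1]) / n
    cov = float(s10[0, 1]) / m + float(s01[0, 1]) / n
    denom_sq = var1 + var2 - 2.0 * cov
    if denom_sq <= 1e-15:
        if abs(a1 - a2) < 1e-12:
            z, p = 0.0, 1.0
        else:
            warnings.warn(
                "degenerate variance of the AUC difference with unequal AUCs: "
                "comparison not computable",
                stacklevel=2,
            )
            z, p = float("nan"), float("nan")
    else:
        z = (a1 - a2) / math.sqrt(denom_sq)
        p = 2.0 * float(_sps.norm.sf(abs(z)))
    return DeLongComparison(
        auc1=a1, auc2=a2, var1=var1, var2=var2, covariance=cov, z=z, p_value=p
    )


def supporting_criteria_score(trv_ms, n_supporting_signs: int) -> str:
    """Guideline echocardiographic PH probability category.

    TRV bands (editable in :data:`GUIDELINE_TRV_BANDS`): <= 2.8 m/s low,
    2.8-3.4 intermediate, > 3.4 high; two or more supporting signs raise
    the category one level (capped at high).  A missing TRV with >= 2
    signs maps to intermediate, otherwise low.
    """
    if n_supporting_signs < 0:
        raise ValueError("number of supporting signs must be >= 0")
    levels = ["low", "intermediate", "high"]
    missing = trv_ms is None or (isinstance(trv_ms, float) and math.isnan(trv_ms))
    if missing:
        return "intermediate" if n_supporting_signs >= 2 else "low"
    if trv_ms <= GUIDELINE_TRV_BANDS["low_max"]:
        idx = 0
    elif trv_ms <= GUIDELINE_TRV_BANDS["intermediate_max"]:
        idx = 1
    else:
        idx = 2
    if n_supporting_signs >= 2:
        idx = min(idx + 1, 2)
    return levels[idx]


def referral_roc(
    table: MeasurementTable,
    hemodynamics: pd.DataFrame,
    parameter: str,
    reader: str,
    compare_reader: str | None = None,
):
    """ROC of a parameter against the MPAP > 20 mm Hg PH label.

    Subjects above the 35 mm Hg referral band are excluded.  Returns a dict
    of per-reader :class:`ROCResult` plus a :class:`DeLongComparison` when a
    second reader is given (restricted to subjects read by both).
    """
    hemo = hemodynamics.set_index("subject_id")["mpap_mmhg"]
    hemo = hemo[hemo.apply(referral_eligible)]
    orientation = PARAMETER_ORIENTATION.get(parameter, 1)
    df = table.df
    sub = df[df["parameter"] == parameter]
    values = {
        r: sub[sub["reader"] == r].set_index("subject_id")["value"]
        for r in ([reader] if compare_reader is None else [reader, compare_reader])
    }
    out: dict = {"parameter": parameter, "rocs": {}, "comparison": None}
    common = hemo.index
    for r, v in values.items():
        common = common.intersection(v.index)
    common = common.sort_values()
    labels = (hemo.loc[common] > _PH_MPAP_THRESHOLD).to_numpy()
    for r, v in values.items():
        out["rocs"][r] = auc(
            v.loc[common].to_numpy(dtype=float), labels, higher_is_disease=orientation > 0
        )
    if compare_reader is not None:
        out["comparison"] = delong_compare(
            values[reader].loc[common].to_numpy(dtype=float),
            values[compare_reader].loc[common].to_numpy(dtype=float),
            labels,
            higher_is_disease=orientation > 0,
        )
    out["n_subjects"] = int(len(common))
    return out


def matched_case_control_roc(
    table: MeasurementTable,
    parameter: str,
    reader: str,
    compare_reader: str | None = None,
    caliper_years: float | None = None,
):
    """Case-control ROC after greedy age/sex matching of PAH vs healthy."""
    df = table.df
    demo = (
        df[df["group"].isin(["healthy", "PAH"])]
        .drop_duplicates("subject_id")
        .set_index("subject_id")
    )
    cases = [(i, r["age_years"], r["sex"]) for i, r in demo[demo["group"] == "PAH"].iterrows()]
    controls = [
        (i, r["age_years"], r["sex"]) for i, r in demo[demo["group"] == "healthy"].iterrows()
    ]
    matched = match_case_control(cases, controls, caliper_years=caliper_years)
    keep = {sid for pair in matched.pairs for sid in pair}
    sub = df[(df["parameter"] == parameter) & (df["subject_id"].isin(keep))]
    orientation = PARAMETER_ORIENTATION.get(parameter, 1)
    readers = [reader] if compare_reader is None else [reader, compare_reader]
    values = {r: sub[sub["reader"] == r].set_index("subject_id")["value"] for r in readers}
    common = None
    for v in values.values():
        common = v.index if common is None else common.intersection(v.index)
    common = common.sort_values()
    labels = (demo.loc[common, "group"] == "PAH").to_numpy()
    out: dict = {"parameter": parameter, "rocs": {}, "comparison": None, "matching": matched}
    for r, v in values.items():
        out["rocs"][r] = auc(
            v.loc[common].to_numpy(dtype=float), labels, higher_is_disease=orientation > 0
        )
    if compare_reader is not None:
        out["comparison"] = delong_compare(
            values[reader].loc[common].to_numpy(dtype=float),
            values[compare_reader].loc[common].to_numpy(dtype=float),
            labels,
            higher_is_disease=orientation > 0,
        )
    out["n_subjects"] = int(len(common))
    return out
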