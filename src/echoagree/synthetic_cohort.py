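"""Synthetic echocardiographic cohorts with known ground truth.

Two generators emulate the statistical structure of a two-part reader
study of automated right-heart echocardiography:

* a **case-control cohort** (healthy volunteers vs pulmonary arterial
  hypertension) in which each subject carries a latent severity factor
  that jointly shifts all right-heart parameters, and each reader
  (automated ``DL``, view-agnostic core lab ``CL1``, same-view core lab
  ``CL2``) produces a multiplicatively biased, imprecise read with a
  per-parameter probability of yielding a value at all;
* a **referral cohort** of patients catheterized for suspected PH, with
  continuous mean pulmonary artery pressure (MPAP) restricted to the
  10-35 mm Hg band and peak TRV tied to MPAP through a configurable
  sPAP-MPAP coupling and the simplified Bernoulli relation
  ``TRV = sqrt((sPAP - RAP) / 4)``.

Every generated read traces back to a ground-truth entry, so downstream
estimators (median bias, scaled percentile precision, yields, AUCs) can
be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core_io import (
    DEFAULT_UNITS,
    MEASUREMENT_COLUMNS,
    PARAMETERS,
    QUALITY_CATEGORIES,
    MeasurementTable,
    load_yaml,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# Defaults.  Truth distributions are per-parameter healthy/PAH mean +/- SD in
# conventional units with physiologic truncation bounds; the loading weights
# each parameter on a shared latent severity factor (negative for parameters
# that fall as the right heart deteriorates).
# --------------------------------------------------------------------------

_DEFAULT_DISTRIBUTIONS = [
    # parameter, mean_h, sd_h, mean_case, sd_case, lo, hi, loading
    ("TRV", 2.1, 0.5, 4.1, 0.7, 0.5, 7.0, 0.7),
    ("RV_basal_diameter", 37.8, 8.3, 54.8, 10.2, 15.0, 95.0, 0.7),
    ("TAPSE", 25.1, 3.6, 16.1, 4.8, 3.0, 45.0, -0.7),
    ("RA_area", 15.9, 4.1, 23.3, 9.3, 4.0, 70.0, 0.7),
    ("RVEDA", 22.2, 5.5, 37.4, 11.6, 6.0, 90.0, 0.7),
    ("RVESA", 13.3, 3.4, 30.5, 11.2, 3.0, 85.0, 0.7),
    ("RVFAC", 39.9, 3.6, 19.7, 6.5, 2.0, 75.0, -0.7),
]

# Default reader-error targets: relative (%) median bias and scaled
# percentile precision of each comparator against the CL1 reference,
# and read yields in a 434-subject case-control cohort.
_BIAS_DL = {
    "TRV": 0.90, "RV_basal_diameter": -6.35, "TAPSE": 1.28, "RA_area": 1.71,
    "RVEDA": -11.0, "RVESA": -14.29, "RVFAC": 11.46,
}
_BIAS_CL2 = {
    "TRV": -6.02, "RV_basal_diameter": -0.36, "TAPSE": 0.0, "RA_area": 4.67,
    "RVEDA": -6.89, "RVESA": -8.18, "RVFAC": 2.70,
}
_PRECISION_DL = {
    "TRV": 6.70, "RV_basal_diameter": 10.13, "TAPSE": 11.49, "RA_area": 10.17,
    "RVEDA": 9.24, "RVESA": 12.35, "RVFAC": 17.34,
}
_PRECISION_CL2 = {
    "TRV": 5.35, "RV_basal_diameter": 7.24, "TAPSE": 6.15, "RA_area": 9.85,
    "RVEDA": 7.46, "RVESA": 9.14, "RVFAC": 10.01,
}
_CL_READ_COUNTS = {
    "TRV": 396, "RV_basal_diameter": 422, "TAPSE": 316, "RA_area": 426,
    "RVEDA": 408, "RVESA": 408, "RVFAC": 413,
}
_RELATIVE_YIELD_DL = {
    "TRV": 0.934, "RV_basal_diameter": 0.808, "TAPSE": 0.956, "RA_area": 0.871,
    "RVEDA": 0.811, "RVESA": 0.813, "RVFAC": 0.785,
}
_N_CASE_CONTROL_TOTAL = 434


@dataclass
class ParameterDistribution:
    """Truth distribution of one parameter in healthy and case groups."""

    parameter: str
    mean_healthy: float
    sd_healthy: float
    mean_case: float
    sd_case: float
    lower_bound: float
    upper_bound: float
    severity_loading: float = 0.7

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ConfigError(f"unknown parameter {self.parameter!r}")
        if self.sd_healthy <= 0 or self.sd_case <= 0:
            raise ConfigError(f"{self.parameter}: SDs must be positive")
        if not self.lower_bound < self.upper_bound:
            raise ConfigError(f"{self.parameter}: lower_bound must be below upper_bound")
        if not -1.0 <= self.severity_loading <= 1.0:
            raise ConfigError(f"{self.parameter}: severity_loading must lie in [-1, 1]")


@dataclass
class ReaderErrorModel:
    """Multiplicative error model of one reader.

    A present read is ``theta * (1 + delta)`` with
    ``delta ~ N(bias_pct/100, (sd_pct * quality_multiplier / 100)^2)``.
    ``bias_pct_by_parameter`` / ``sd_pct_by_parameter`` override the scalar
    defaults per parameter.  ``yield_prob`` is the per-parameter probability
    that the reader produces a value at all.  An optional contamination
    component (probability of a read with ``contamination_scale`` times the
    SD) models gross estimation failures such as non-modal Doppler tracing;
    it is off by default.
    """

    reader: str
    bias_pct: float = 0.0
    sd_pct: float = 0.0
    bias_pct_by_parameter: dict = field(default_factory=dict)
    sd_pct_by_parameter: dict = field(default_factory=dict)
    quality_sd_multiplier: dict = field(
        default_factory=lambda: {"good": 1.0, "moderate": 1.25, "low": 1.5}
    )
    quality_bias_offset_pct: dict = field(
        default_factory=lambda: {"good": 0.0, "moderate": 0.0, "low": 0.0}
    )
    yield_prob: dict = field(default_factory=dict)
    contamination_prob: float = 0.0
    contamination_scale: float = 5.0

    def __post_init__(self):
        if self.sd_pct < 0 or any(v < 0 for v in self.sd_pct_by_parameter.values()):
            raise ConfigError(f"{self.reader}: sd_pct must be >= 0")
        if any(not 0.0 <= v <= 1.0 for v in self.yield_prob.values()):
            raise ConfigError(f"{self.reader}: yield probabilities must lie in [0, 1]")
        if self.quality_sd_multiplier.get("good", 1.0) != 1.0:
            raise ConfigError(f"{self.reader}: quality multiplier for 'good' must be 1")
        if any(v < 1.0 for v in self.quality_sd_multiplier.values()):
            raise ConfigError(f"{self.reader}: quality SD multipliers must be >= 1")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ConfigError(f"{self.reader}: contamination_prob must lie in [0, 1]")

    def bias(self, parameter: str) -> float:
        return float(self.bias_pct_by_parameter.get(parameter, self.bias_pct))

    def sd(self, parameter: str) -> float:
        return float(self.sd_pct_by_parameter.get(parameter, self.sd_pct))

    def yprob(self, parameter: str) -> float:
        return float(self.yield_prob.get(parameter, 1.0))


@dataclass
class GroupDemographics:
    age_mean: float
    age_sd: float
    p_female: float

    def __post_init__(self):
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigError("p_female must lie in [0, 1]")
        if self.age_sd < 0:
            raise ConfigError("age_sd must be >= 0")


def default_case_control_readers() -> list[ReaderErrorModel]:
    """CL1/DL/CL2 error models reproducing the default pairwise targets.

    Scaled percentile precision of a (ref, comp) pair under this generator is
    ``sqrt((s_ref^2 + s_comp^2) / 2)``.  Each core-lab reader is assigned the
    CL2-vs-CL1 precision as its per-read SD, and the automated reader gets
    ``s_DL = sqrt(2 * p_DL^2 - s_CL^2)`` so both printed pairwise precisions
    are reproduced simultaneously.
    """
    s_cl = dict(_PRECISION_CL2)
    s_dl = {
        p: math.sqrt(max(2.0 * _PRECISION_DL[p] ** 2 - s_cl[p] ** 2, 0.0))
        for p in s_cl
    }
    cl_yield = {p: c / _N_CASE_CONTROL_TOTAL for p, c in _CL_READ_COUNTS.items()}
    return [
        ReaderErrorModel("CL1", sd_pct_by_parameter=dict(s_cl), yield_prob=dict(cl_yield)),
        ReaderErrorModel(
            "DL",
            bias_pct_by_parameter=dict(_BIAS_DL),
            sd_pct_by_parameter=s_dl,
            yield_prob=dict(_RELATIVE_YIELD_DL),
        ),
        ReaderErrorModel(
            "CL2",
            bias_pct_by_parameter=dict(_BIAS_CL2),
            sd_pct_by_parameter=dict(s_cl),
            yield_prob=dict(cl_yield),
        ),
    ]


def default_referral_readers() -> list[ReaderErrorModel]:
    s_cl = dict(_PRECISION_CL2)
    s_dl = {
        p: math.sqrt(max(2.0 * _PRECISION_DL[p] ** 2 - s_cl[p] ** 2, 0.0))
        for p in s_cl
    }
    yields = {p: 0.93 if p == "TRV" else 0.90 for p in s_cl}
    return [
        ReaderErrorModel("CLINICAL", sd_pct_by_parameter=dict(s_cl), yield_prob=dict(yields)),
        ReaderErrorModel(
            "DL",
            bias_pct_by_parameter=dict(_BIAS_DL),
            sd_pct_by_parameter=s_dl,
            yield_prob=dict(yields),
        ),
    ]


@dataclass
class ReferralConfig:
    """Referral (RHC) cohort block: mild-PH band with MPAP-coupled truth."""

    n_subjects: int = 196
    mpap_lower: float = 10.0
    mpap_upper: float = 35.0
    p_mpap_below_20: float = 89 / 196
    rap_mmhg: float = 5.0
    spap_slope: float = 1.5
    spap_intercept: float = 0.0
    age_mean: float = 62.0
    age_sd: float = 16.0
    p_female: float = 0.53
    readers: list[ReaderErrorModel] = field(default_factory=default_referral_readers)

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if not (0 < self.mpap_lower < self.mpap_upper <= 35.0):
            raise ConfigError("MPAP support must satisfy 0 < lower < upper <= 35 mm Hg")
        if not 0.0 <= self.p_mpap_below_20 <= 1.0:
            raise ConfigError("p_mpap_below_20 must lie in [0, 1]")
        for m in (self.mpap_lower, self.mpap_upper):
            if self.spap_slope * m + self.spap_intercept <= self.rap_mmhg:
                raise ConfigError(
                    "sPAP must exceed RAP over the whole MPAP support (TRV undefined otherwise)"
                )


@dataclass
class CohortConfig:
    """Full generator configuration for both cohorts."""

    n_healthy: int = 213
    n_case: int = 221
    distributions: list[ParameterDistribution] = field(
        default_factory=lambda: [ParameterDistribution(*row) for row in _DEFAULT_DISTRIBUTIONS]
    )
    readers: list[ReaderErrorModel] = field(default_factory=default_case_control_readers)
    quality_probs: dict = field(
        default_factory=lambda: {"good": 0.60, "moderate": 0.25, "low": 0.15}
    )
    demographics: dict = field(
        default_factory=lambda: {
            "healthy": GroupDemographics(55.0, 17.0, 0.46),
            "PAH": GroupDemographics(48.0, 14.0, 0.78),
        }
    )
    referral: ReferralConfig = field(default_factory=ReferralConfig)

    def __post_init__(self):
        if self.n_healthy <= 0 or self.n_case <= 0:
            raise ConfigError("group sizes must be positive")
        probs = [self.quality_probs.get(c, 0.0) for c in QUALITY_CATEGORIES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("quality_probs must be nonnegative and sum to 1")
        seen = set()
        for d in self.distributions:
            if d.parameter in seen:
                raise ConfigError(f"duplicate distribution for {d.parameter}")
            seen.add(d.parameter)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        data = dict(data or {})
        kwargs: dict = {}
        if "n_healthy" in data:
            kwargs["n_healthy"] = int(data["n_healthy"])
        if "n_case" in data:
            kwargs["n_case"] = int(data["n_case"])
        if "distributions" in data:
            kwargs["distributions"] = [
                ParameterDistribution(**d) for d in data["distributions"]
            ]
        if "readers" in data:
            kwargs["readers"] = [ReaderErrorModel(**r) for r in data["readers"]]
        if "quality_probs" in data:
            kwargs["quality_probs"] = dict(data["quality_probs"])
        if "demographics" in data:
            kwargs["demographics"] = {
                g: GroupDemographics(**v) for g, v in data["demographics"].items()
            }
        if "referral" in data:
            ref = dict(data["referral"])
            if "readers" in ref:
                ref["readers"] = [ReaderErrorModel(**r) for r in ref["readers"]]
            kwargs["referral"] = ReferralConfig(**ref)
        return cls(**kwargs)


def load_cohort_config(path) -> CohortConfig:
    return CohortConfig.from_dict(load_yaml(path))


@dataclass
class TruthTable:
    """Ground truth per (subject, parameter) plus realized read inclusion.

    Columns: subject_id, parameter, theta, severity, group, mpap_mmhg,
    and one ``present_<reader>`` indicator per configured reader.
    """

    df: pd.DataFrame


def true_trv_from_mpap(
    mpap_mmhg: float, rap_mmhg: float = 5.0, slope: float = 1.5, intercept: float = 0.0
) -> float:
    """Peak TRV implied by MPAP via sPAP coupling and simplified Bernoulli.

    ``sPAP = slope * MPAP + intercept``; ``TRV = sqrt((sPAP - RAP) / 4)``.
    """
    spap = slope * mpap_mmhg + intercept
    if spap <= rap_mmhg:
        raise ConfigError("sPAP <= RAP: TRV undefined")
    return math.sqrt((spap - rap_mmhg) / 4.0)


def _clip_value(value: float, dist: ParameterDistribution) -> float:
    # Keep reads physically admissible (positive; RVFAC strictly < 100).
    lo = 1e-6
    hi = 100.0 - 1e-6 if dist.parameter == "RVFAC" else math.inf
    return min(max(value, lo), hi)


def _draw_quality(rng: np.random.Generator, probs: np.ndarray) -> tuple[str, int]:
    cat = QUALITY_CATEGORIES[rng.choice(3, p=probs)]
    if cat == "good":
        return cat, int(rng.integers(4, 6))
    if cat == "moderate":
        return cat, 3
    return cat, int(rng.integers(1, 3))


def _read_value(
    rng: np.random.Generator,
    theta: float,
    dist: ParameterDistribution,
    reader: ReaderErrorModel,
    quality_cat: str,
) -> float:
    sd_read = reader.sd(dist.parameter) * reader.quality_sd_multiplier.get(quality_cat, 1.0)
    if reader.contamination_prob and rng.random() < reader.contamination_prob:
        sd_read *= reader.contamination_scale
    bias = reader.bias(dist.parameter) + reader.quality_bias_offset_pct.get(quality_cat, 0.0)
    delta = rng.normal(bias / 100.0, sd_read / 100.0)
    return _clip_value(theta * (1.0 + delta), dist)


def generate_case_control_cohort(
    config: CohortConfig, seed: int
) -> tuple[MeasurementTable, TruthTable]:
    """Simulate the two-group cohort; fully reproducible given ``seed``.

    Per subject, a latent severity ``z ~ N(0,1)`` combines with an
    independent normal through the per-parameter loading to produce the true
    value, truncated to physiologic bounds.  Image quality is drawn once per
    (subject, parameter) and shared by all readers of that image.  Each
    per-subject random stream is a deterministic child of the root seed, so
    regenerating any subject reproduces it exactly.
    """
    qp = np.array([config.quality_probs[c] for c in QUALITY_CATEGORIES], dtype=float)
    reader_names = [r.reader for r in config.readers]
    rows: list[tuple] = []
    truth_rows: list[dict] = []
    subjects = [
        (f"CC{i:05d}", "healthy" if i < config.n_healthy else "PAH")
        for i in range(config.n_healthy + config.n_case)
    ]
    for i, (sid, group) in enumerate(subjects):
        rng = np.random.default_rng([int(seed), i])
        demo = config.demographics[group]
        age = float(max(18.0, rng.normal(demo.age_mean, demo.age_sd)))
        sex = "F" if rng.random() < demo.p_female else "M"
        z = float(rng.normal())
        for dist in config.distributions:
            if group == "healthy":
                mu, sdv = dist.mean_healthy, dist.sd_healthy
            else:
                mu, sdv = dist.mean_case, dist.sd_case
            lam = dist.severity_loading
            theta = mu + sdv * (lam * z + math.sqrt(1.0 - lam * lam) * rng.normal())
            theta = min(max(theta, dist.lower_bound), dist.upper_bound)
            qcat, qscore = _draw_quality(rng, qp)
            presence = {}
            for reader in config.readers:
                present = bool(rng.random() < reader.yprob(dist.parameter))
                presence[reader.reader] = present
                if not present:
                    continue
                value = _read_value(rng, theta, dist, reader, qcat)
                rows.append(
                    (sid, "case_control", group, dist.parameter, reader.reader,
                     value, DEFAULT_UNITS[dist.parameter], qscore, age, sex)
                )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "parameter": dist.parameter,
                    "theta": theta,
                    "severity": z,
                    "group": group,
                    "mpap_mmhg": np.nan,
                    **{f"present_{r}": presence[r] for r in reader_names},
                }
            )
    table = MeasurementTable(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))
    return table, TruthTable(pd.DataFrame(truth_rows))


def generate_referral_cohort(
    config: CohortConfig, seed: int
) -> tuple[MeasurementTable, pd.DataFrame, TruthTable]:
    """Simulate the catheterization-referral cohort.

    MPAP is drawn on the configured (lower, upper) band with the configured
    mass below 20 mm Hg; true TRV follows from the sPAP-MPAP coupling; the
    remaining parameters interpolate between healthy and case means with the
    MPAP percentile acting as the severity axis.  Returns
    (measurements, hemodynamics, truth).
    """
    rc = config.referral
    qp = np.array([config.quality_probs[c] for c in QUALITY_CATEGORIES], dtype=float)
    reader_names = [r.reader for r in rc.readers]
    rows: list[tuple] = []
    hemo_rows: list[tuple] = []
    truth_rows: list[dict] = []
    for i in range(rc.n_subjects):
        rng = np.random.default_rng([int(seed), 7, i])
        sid = f"RF{i:05d}"
        age = float(max(18.0, rng.normal(rc.age_mean, rc.age_sd)))
        sex = "F" if rng.random() < rc.p_female else "M"
        if rng.random() < rc.p_mpap_below_20:
            mpap = float(rng.uniform(rc.mpap_lower, min(20.0, rc.mpap_upper)))
        else:
            mpap = float(rng.uniform(max(20.0, rc.mpap_lower), rc.mpap_upper))
        trv_true = true_trv_from_mpap(mpap, rc.rap_mmhg, rc.spap_slope, rc.spap_intercept)
        u = (mpap - rc.mpap_lower) / (rc.mpap_upper - rc.mpap_lower)
        severity = float(_sps.norm.ppf(min(max(u, 1e-4), 1.0 - 1e-4)))
        days = int(round(rng.exponential(23.0 / math.log(2.0))))
        hemo_rows.append((sid, mpap, days))
        for dist in config.distributions:
            if dist.parameter == "TRV":
                theta = trv_true
            else:
                lam = abs(dist.severity_loading)
                theta = (
                    dist.mean_healthy
                    + u * (dist.mean_case - dist.mean_healthy)
                    + dist.sd_healthy * math.sqrt(1.0 - lam * lam) * rng.normal()
                )
            theta = min(max(theta, dist.lower_bound), dist.upper_bound)
            qcat, qscore = _draw_quality(rng, qp)
            presence = {}
            for reader in rc.readers:
                present = bool(rng.random() < reader.yprob(dist.parameter))
                presence[reader.reader] = present
                if not present:
                    continue
                value = _read_value(rng, theta, dist, reader, qcat)
                rows.append(
                    (sid, "referral", "unknown", dist.parameter, reader.reader,
                     value, DEFAULT_UNITS[dist.parameter], qscore, age, sex)
                )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "parameter": dist.parameter,
                    "theta": theta,
                    "severity": severity,
                    "group": "unknown",
                    "mpap_mmhg": mpap,
                    **{f"present_{r}": presence[r] for r in reader_names},
                }
            )
    table = MeasurementTable(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))
    hemo = pd.DataFrame(hemo_rows, columns=["subject_id", "mpap_mmhg", "days_echo_to_rhc"])
    return table, hemo, TruthTable(pd.DataFrame(truth_rows))
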