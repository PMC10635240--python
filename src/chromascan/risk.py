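"""Five-year cumulative colorectal-cancer risk model.

The population-level 5-year CRC risk combines three ingredients: the
cumulative probability that a patient with no cancer history develops a
future advanced adenoma (AAr), the per-patient annual risk that an advanced
adenoma progresses to CRC (stratified by sex and by age below/above 80,
converted to a cumulative probability over the horizon), and the cumulative
risk of metachronous CRC (CRCm) for patients with a cancer history:

    risk = [ AAr * sum_i cum(AA->CRC_i) + Nc * CRCm ] / (Na + Nc)

with ``cum(r) = 1 - exp(-r * t)`` converting an annual hazard to a
cumulative probability over ``t`` years.

The shipped per-stratum annual risks are PLACEHOLDER values: the source
surveillance literature does not print them, so they are configuration, not
constants, and every report carries the configuration fingerprint.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RiskStratum",
    "RiskModelParams",
    "RegressionResult",
    "cumulative_risk",
    "crc_5yr_risk",
    "regress_d_vs_risk",
    "classify_risk_history",
    "DEFAULT_HISTORY_RULES",
]


@dataclass(frozen=True)
class RiskStratum:
    sex: str
    age_band: str  # "<80" or ">=80"
    annual_aa_to_crc: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.age_band not in ("<80", ">=80"):
            raise ValueError("age_band must be '<80' or '>=80'")
        if not 0.0 <= self.annual_aa_to_crc <= 1.0:
            raise ValueError("annual risk must lie in [0, 1]")


def _default_strata() -> list[RiskStratum]:
    # PLACEHOLDER annual AA->CRC hazards; replace with surveillance-table values.
    return [
        RiskStratum("male", "<80", 0.026),
        RiskStratum("male", ">=80", 0.050),
        RiskStratum("female", "<80", 0.021),
        RiskStratum("female", ">=80", 0.043),
    ]


@dataclass
class RiskModelParams:
    """Inputs to the population 5-year risk equation."""

    na: int
    nc: int
    aar: float
    crcm: float
    strata: list[RiskStratum] = field(default_factory=_default_strata)
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.na < 0 or self.nc < 0:
            raise ValueError("patient counts must be non-negative")
        if self.na + self.nc == 0:
            raise ValueError("need at least one patient (Na + Nc > 0)")
        for p in (self.aar, self.crcm):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")

    def annual_for(self, sex: str, age: float) -> float:
        band = ">=80" if age >= 80 else "<80"
        for s in self.strata:
            if s.sex == sex and s.age_band == band:
                return s.annual_aa_to_crc
        raise KeyError(f"no stratum for sex={sex!r}, age_band={band!r}")

    def fingerprint(self) -> str:
        payload = {
            "na": self.na,
            "nc": self.nc,
            "aar": self.aar,
            "crcm": self.crcm,
            "horizon": self.horizon,
            "strata": [
                [s.sex, s.age_band, s.annual_aa_to_crc] for s in self.strata
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def cumulative_risk(annual_risk: float, time: float) -> float:
    """Convert an annual hazard to a cumulative probability: 1 - exp(-r t)."""
    if annual_risk < 0 or time < 0:
        raise ValueError("annual_risk and time must be non-negative")
    return 1.0 - math.exp(-annual_risk * time)


def crc_5yr_risk(params: RiskModelParams, per_patient_annual: np.ndarray) -> float:
    """Population cumulative CRC risk over the horizon.

    ``per_patient_annual`` holds one annual AA->CRC hazard per no-cancer-
    history patient (length Na), each drawn from that patient's sex/age
    stratum; hazards are converted to cumulative probabilities over the
    horizon before entering the equation.
    """
    annual = np.asarray(per_patient_annual, dtype=np.float64)
    if annual.ndim != 1 or annual.size != params.na:
        raise ValueError("per_patient_annual must have one entry per Na patient")
    if np.any(annual < 0) or np.any(annual > 1):
        raise ValueError("annual risks must lie in [0, 1]")
    cum = 1.0 - np.exp(-annual * params.horizon)
    total = params.aar * cum.sum() + params.nc * params.crcm
    return float(total / (params.na + params.nc))


def regress_d_vs_risk(group_mean_d: np.ndarray, group_risk: np.ndarray) -> RegressionResult:
    """OLS of group-level mean D on modeled risk; r^2 is the squared Pearson r."""
    d = np.asarray(group_mean_d, dtype=np.float64)
    r = np.asarray(group_risk, dtype=np.float64)
    if d.shape != r.shape or d.ndim != 1 or d.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(r) == 0:
        raise ValueError("risk values have zero variance (degenerate regressor)")
    if np.ptp(d) == 0:
        raise ValueError("D values have zero variance")
    fit = sps.linregress(r, d)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(d.size),
    )


#: finding code -> history category; the surveillance literature implies the
#: mapping but does not print it, so it ships as a configurable rule table.
DEFAULT_HISTORY_RULES: dict[str, str] = {
    "none": "no history",
    "hyperplastic": "no history",
    "diminutive_adenoma": "low-risk history",
    "small_adenoma": "low-risk history",
    "nondiminutive_adenoma": "low-risk history",
    "advanced_adenoma": "high-risk history",
    "multiple_adenomas": "high-risk history",
    "high_grade_dysplasia": "high-risk history",
    "crc": "high-risk history",
}

_CATEGORY_RANK = {"no history": 0, "low-risk history": 1, "high-risk history": 2}


def classify_risk_history(
    findings: list[str],
    rules: dict[str, str] | None = None,
) -> str:
    """Map a patient's prior colonoscopy findings to a risk-history category.

    The category is the highest-risk one implied by any finding across the
    surveillance record; an empty record is "no history".
    """
    rules = rules if rules is not None else DEFAULT_HISTORY_RULES
    if not findings:
        return "no history"
    best = "no history"
    for code in findings:
        if code not in rules:
            raise KeyError(f"unknown finding code {code!r}")
        cat = rules[code]
        if cat not in _CATEGORY_RANK:
            raise ValueError(f"rule table maps {code!r} to unknown category {cat!r}")
        if _CATEGORY_RANK[cat] > _CATEGORY_RANK[best]:
            best = cat
    return best
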