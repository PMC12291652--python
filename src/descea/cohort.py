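"""Synthetic 1:3 matched case-control cohorts and their summary moments.

The generator emulates the statistical structure of the source cohort:
14 desensitized (DES) patients against 42 non-desensitized (NDES)
controls, right-skewed per-patient hospital costs (per-arm gamma,
moment-matched to the configured mean/SD) and Bernoulli cure and 30-day
survival outcomes at the configured arm rates.  ``cohort_to_moments``
reduces a cohort back to the summary statistics the calibration module
consumes, closing the loop cohort -> moments -> calibration -> PSA.

Per-arm cost SDs are not published; the defaults split the published
patient-level difference spread (SD 34,270) across the arms in
proportion to the arm means.  The published rate-difference SDs (0.017
cure, 0.015 survival) are far smaller than two-proportion standard
errors at n=14/42, so they cannot be derived from the cohort; the
config carries them as explicit calibration inputs instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import SummaryMoments, fit_gamma_moments
from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "PatientRecord",
    "CohortConfig",
    "CohortMoments",
    "generate_cohort",
    "cohort_to_moments",
    "cohort_to_frame",
    "read_cohort_csv",
    "write_cohort_csv",
]

# Default per-arm cost SDs: allocate the published difference spread
# (sqrt(sd_des^2 + sd_ndes^2) = 34,270) proportionally to the arm means.
_DIFF_COST_SD = 34_270.0
_DES_MEAN = 53_665.0
_NDES_MEAN = 14_102.0
_RATIO = _DES_MEAN / _NDES_MEAN
_DEFAULT_SD_NDES = _DIFF_COST_SD / math.sqrt(_RATIO**2 + 1.0)
_DEFAULT_SD_DES = _RATIO * _DEFAULT_SD_NDES

COHORT_COLUMNS = ["patient_id", "arm", "cost", "cured", "survived_30d", "sex", "age"]


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient."""

    patient_id: int
    arm: str  # "DES" or "NDES"
    cost: float  # EUR, >= 0
    cured: bool
    survived_30d: bool
    sex: str  # "M" or "F"
    age: float  # years

    def __post_init__(self) -> None:
        if self.arm not in ("DES", "NDES"):
            raise InvalidParameterError(f"arm must be DES or NDES, got {self.arm!r}")
        if self.cost < 0:
            raise InvalidParameterError(f"cost must be >= 0, got {self.cost}")
        if self.age <= 0:
            raise InvalidParameterError(f"age must be > 0, got {self.age}")


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a synthetic case-control cohort.

    Defaults reproduce the source study's arm sizes, arm cost means,
    cure/survival rates and mean age.  ``cure_diff_sd``/``surv_diff_sd``
    are the externally supplied rate-difference SDs used downstream for
    calibration (they are not derivable from the cohort itself).
    """

    n_des: int = 14
    n_ndes: int = 42
    cost_mean_des: float = _DES_MEAN
    cost_mean_ndes: float = _NDES_MEAN
    cost_sd_des: float = _DEFAULT_SD_DES
    cost_sd_ndes: float = _DEFAULT_SD_NDES
    cure_p_des: float = 0.714
    cure_p_ndes: float = 0.548
    surv_p_des: float = 0.857
    surv_p_ndes: float = 0.714
    cure_diff_sd: float = 0.017
    surv_diff_sd: float = 0.015
    mean_age: float = 73.3
    female_weight: float = 0.5
    seed: int = 20250625

    def __post_init__(self) -> None:
        if self.n_des < 1 or self.n_ndes < 1:
            raise InvalidParameterError(
                f"arm sizes must be >= 1, got n_des={self.n_des}, n_ndes={self.n_ndes}"
            )
        for name in ("cure_p_des", "cure_p_ndes", "surv_p_des", "surv_p_ndes",
                     "female_weight"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {p}")
        for name in ("cost_mean_des", "cost_mean_ndes", "cost_sd_des", "cost_sd_ndes"):
            v = getattr(self, name)
            if v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class CohortMoments:
    """Per-arm and difference summary moments of a cohort.

    Rates carry binomial SDs per arm; the rate-difference SD is the
    two-proportion standard error sqrt(p1 q1/n1 + p2 q2/n2).  The cost
    difference SD is the patient-level spread sqrt(sd1^2 + sd2^2), the
    convention that matches the magnitude of published difference SDs.
    """

    cost_des: SummaryMoments
    cost_ndes: SummaryMoments
    cost_diff: SummaryMoments
    cure_des: SummaryMoments
    cure_ndes: SummaryMoments
    cure_diff: SummaryMoments
    surv_des: SummaryMoments
    surv_ndes: SummaryMoments
    surv_diff: SummaryMoments


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic under a fixed seed.

    DES records come first (ids 0..n_des-1), then NDES.  Per arm, the
    draw order is costs, cures, survivals, sexes.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    pid = 0
    for arm, n, c_mean, c_sd, p_cure, p_surv in (
        ("DES", config.n_des, config.cost_mean_des, config.cost_sd_des,
         config.cure_p_des, config.surv_p_des),
        ("NDES", config.n_ndes, config.cost_mean_ndes, config.cost_sd_ndes,
         config.cure_p_ndes, config.surv_p_ndes),
    ):
        spec = fit_gamma_moments(SummaryMoments(mean=c_mean, sd=c_sd))
        costs = rng.gamma(spec.shape, spec.scale, n)
        cured = rng.random(n) < p_cure
        survived = rng.random(n) < p_surv
        female = rng.random(n) < config.female_weight
        for i in range(n):
            records.append(
                PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    cost=float(costs[i]),
                    cured=bool(cured[i]),
                    survived_30d=bool(survived[i]),
                    sex="F" if female[i] else "M",
                    age=config.mean_age,
                )
            )
            pid += 1
    return records


def _arm_cost_moments(costs: np.ndarray) -> SummaryMoments:
    sd = float(np.std(costs, ddof=1)) if costs.size > 1 else 0.0
    return SummaryMoments(
        mean=float(np.mean(costs)),
        sd=sd,
        min_value=float(np.min(costs)),
        max_value=float(np.max(costs)),
        n=int(costs.size),
    )


def _rate_moments(flags: np.ndarray) -> SummaryMoments:
    p = float(np.mean(flags))
    return SummaryMoments(mean=p, sd=math.sqrt(p * (1.0 - p)), n=int(flags.size))


def _rate_diff(a: SummaryMoments, b: SummaryMoments) -> SummaryMoments:
    p1, n1 = a.mean, a.n
    p2, n2 = b.mean, b.n
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return SummaryMoments(mean=p1 - p2, sd=se)


def cohort_to_moments(records: Sequence[PatientRecord]) -> CohortMoments:
    """Reduce a cohort to the per-arm and difference summary statistics."""
    des = [r for r in records if r.arm == "DES"]
    ndes = [r for r in records if r.arm == "NDES"]
    if not des or not ndes:
        raise EmptyInputError(
            f"both arms must be non-empty, got {len(des)} DES and {len(ndes)} NDES"
        )
    c_des = np.array([r.cost for r in des])
    c_ndes = np.array([r.cost for r in ndes])
    cost_des = _arm_cost_moments(c_des)
    cost_ndes = _arm_cost_moments(c_ndes)
    diff_mean = cost_des.mean - cost_ndes.mean
    pooled_min = float(min(c_des.min(), c_ndes.min()))
    pooled_max = float(max(c_des.max(), c_ndes.max()))
    # pooled range only annotates the difference when it brackets it
    # (similar arm means can push the difference below every observed cost)
    if not (pooled_min <= diff_mean <= pooled_max):
        pooled_min = pooled_max = None
    cost_diff = SummaryMoments(
        mean=diff_mean,
        sd=math.sqrt(cost_des.sd**2 + cost_ndes.sd**2),
        min_value=pooled_min,
        max_value=pooled_max,
    )
    cure_des = _rate_moments(np.array([r.cured for r in des]))
    cure_ndes = _rate_moments(np.array([r.cured for r in ndes]))
    surv_des = _rate_moments(np.array([r.survived_30d for r in des]))
    surv_ndes = _rate_moments(np.array([r.survived_30d for r in ndes]))
    return CohortMoments(
        cost_des=cost_des,
        cost_ndes=cost_ndes,
        cost_diff=cost_diff,
        cure_des=cure_des,
        cure_ndes=cure_ndes,
        cure_diff=_rate_diff(cure_des, cure_ndes),
        surv_des=surv_des,
        surv_ndes=surv_ndes,
        surv_diff=_rate_diff(surv_des, surv_ndes),
    )


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "arm": r.arm,
                "cost": r.cost,
                "cured": r.cured,
                "survived_30d": r.survived_30d,
                "sex": r.sex,
                "age": r.age,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"cohort CSV missing columns: {missing}")
    return [
        PatientRecord(
            patient_id=int(row.patient_id),
            arm=str(row.arm),
            cost=float(row.cost),
            cured=bool(row.cured),
            survived_30d=bool(row.survived_30d),
            sex=str(row.sex),
            age=float(row.age),
        )
        for row in frame.itertuples()
    ]
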