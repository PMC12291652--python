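"""Remaining life expectancy and life-years-gained conversion.

The cohort's remaining life expectancy is a sex-weighted average of the
national life-expectancy figures minus the cohort's mean age.  A
survival-rate difference between strategies converts to life-years
gained (LYG) by multiplying it by those remaining years: the extra
survivors each live out the cohort's expected remaining lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["LifeExpectancyInputs", "remaining_life_years", "lyg_from_survival_difference"]


@dataclass(frozen=True)
class LifeExpectancyInputs:
    """Cohort mean age, sex-specific life expectancies and the female share.

    All ages in years; ``female_weight`` is the proportion of women used
    in the sex average (0.5 = unweighted average of the sexes).
    """

    mean_age: float
    le_male: float
    le_female: float
    female_weight: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_weight <= 1.0):
            raise InvalidParameterError(
                f"female_weight must lie in [0, 1], got {self.female_weight}"
            )
        if self.mean_age >= self.le_male and self.mean_age >= self.le_female:
            raise InvalidParameterError(
                f"mean_age {self.mean_age} is not below either life expectancy "
                f"({self.le_male}, {self.le_female}); remaining years would be non-positive"
            )


def remaining_life_years(inputs: LifeExpectancyInputs) -> float:
    """Sex-weighted remaining life expectancy in years.

    (1-w)*(le_male - mean_age) + w*(le_female - mean_age), strictly positive
    for valid inputs.
    """
    w = inputs.female_weight
    years = (1.0 - w) * (inputs.le_male - inputs.mean_age) + w * (
        inputs.le_female - inputs.mean_age
    )
    if years <= 0:
        raise InvalidParameterError(
            f"remaining life years must be positive, got {years} "
            f"(mean_age {inputs.mean_age} too close to life expectancy)"
        )
    return years


def lyg_from_survival_difference(survival_diff: float, remaining_years: float) -> float:
    """Life-years gained per patient from a survival-rate difference.

    Bilinear: survival_diff * remaining_years.  A negative difference
    yields negative LYG (the comparator strategy gains).
    """
    if remaining_years <= 0:
        raise InvalidParameterError(f"remaining_years must be > 0, got {remaining_years}")
    return survival_diff * remaining_years
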