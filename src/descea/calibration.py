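"""Method-of-moments calibration of PSA sampling distributions.

Cost quantities (continuous, right-skewed, positive) are modelled with
gamma distributions in shape--scale form; probability quantities
(differences of cure and survival rates, bounded in (0,1)) with beta
distributions.  Calibration inverts the closed-form mean/SD of each
family so the fitted distribution reproduces the observed summary
moments exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleMomentsError, InvalidParameterError

__all__ = [
    "SummaryMoments",
    "GammaSpec",
    "BetaSpec",
    "fit_gamma_moments",
    "fit_beta_moments",
    "distribution_moments",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Printed tables conventionally use half-up rounding, which differs
    from Python's banker's rounding on exact ties.
    """
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SummaryMoments:
    """Mean/SD (and optional range and sample size) of an observed quantity.

    Units follow the quantity: EUR for costs, a proportion for rates.
    """

    mean: float
    sd: float
    min_value: float | None = None
    max_value: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError(f"sd must be >= 0, got {self.sd}")
        if self.min_value is not None and self.max_value is not None:
            if not (self.min_value <= self.mean <= self.max_value):
                raise InvalidParameterError(
                    f"mean {self.mean} outside [min_value {self.min_value}, "
                    f"max_value {self.max_value}]"
                )


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution in shape--scale parameterization.

    ``shape`` is dimensionless; ``scale`` carries the units of the
    modelled quantity (EUR here).  Analytic mean = shape*scale,
    variance = shape*scale**2.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise InvalidParameterError(f"shape must be > 0, got {self.shape}")
        if self.scale <= 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return self.scale * math.sqrt(self.shape)


@dataclass(frozen=True)
class BetaSpec:
    """Beta distribution with both parameters dimensionless.

    Analytic mean = alpha/(alpha+beta), which always lies in (0,1).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


def fit_gamma_moments(moments: SummaryMoments) -> GammaSpec:
    """Fit a gamma distribution whose analytic mean/SD equal the observed ones.

    shape = (mean/sd)^2, scale = sd^2/mean.  Requires mean > 0 and sd > 0.
    """
    if moments.mean <= 0:
        raise InvalidParameterError(f"mean must be > 0 for a gamma fit, got {moments.mean}")
    if moments.sd <= 0:
        raise InvalidParameterError(f"sd must be > 0 for a gamma fit, got {moments.sd}")
    shape = (moments.mean / moments.sd) ** 2
    scale = moments.sd**2 / moments.mean
    return GammaSpec(shape=shape, scale=scale)


def fit_beta_moments(moments: SummaryMoments) -> BetaSpec:
    """Fit a beta distribution whose analytic mean/SD equal the observed ones.

    With kappa = mean(1-mean)/sd^2 - 1:
    alpha = mean*kappa, beta = (1-mean)*kappa.
    Requires 0 < mean < 1 and 0 < sd^2 < mean(1-mean); moments outside
    that region admit no beta distribution.
    """
    m = moments.mean
    if not (0.0 < m < 1.0):
        raise InvalidParameterError(f"mean must lie in (0, 1) for a beta fit, got {m}")
    if moments.sd <= 0:
        raise InvalidParameterError(f"sd must be > 0 for a beta fit, got {moments.sd}")
    var = moments.sd**2
    bound = m * (1.0 - m)
    if var >= bound:
        raise InfeasibleMomentsError(
            f"variance {var} must be < mean*(1-mean) = {bound} for a beta fit"
        )
    kappa = bound / var - 1.0
    return BetaSpec(alpha=m * kappa, beta=(1.0 - m) * kappa)


def distribution_moments(spec: GammaSpec | BetaSpec) -> SummaryMoments:
    """Closed-form mean/SD of a calibrated distribution.

    The exact inverse of the moment fits: round-tripping through
    ``fit_gamma_moments``/``fit_beta_moments`` recovers the spec.
    """
    if isinstance(spec, (GammaSpec, BetaSpec)):
        return SummaryMoments(mean=spec.mean, sd=spec.sd)
    raise TypeError(f"expected GammaSpec or BetaSpec, got {type(spec).__name__}")


def params_consistent_with_printed(
    fitted: GammaSpec | BetaSpec,
    printed: GammaSpec | BetaSpec,
    moments: SummaryMoments,
    param_decimals: tuple[int, int],
    moment_decimals: tuple[int, int],
) -> bool:
    """Check a supplied (printed) spec against the moment fit, at printed rounding.

    Accepts when EITHER the fitted parameters round to the printed ones,
    OR the printed spec's analytic moments round back to the supplied
    mean/SD.  The second direction matters because printed parameters are
    often fitted from unrounded moments: refitting from the rounded table
    values then lands near, but not exactly on, the printed parameters.
    """
    if type(fitted) is not type(printed):
        return False
    if isinstance(fitted, GammaSpec):
        f_params = (fitted.shape, fitted.scale)
        p_params = (printed.shape, printed.scale)
    else:
        f_params = (fitted.alpha, fitted.beta)
        p_params = (printed.alpha, printed.beta)
    params_match = all(
        round_half_up(f, d) == round_half_up(p, d)
        for f, p, d in zip(f_params, p_params, param_decimals)
    )
    if params_match:
        return True
    pm = distribution_moments(printed)
    return round_half_up(pm.mean, moment_decimals[0]) == round_half_up(
        moments.mean, moment_decimals[0]
    ) and round_half_up(pm.sd, moment_decimals[1]) == round_half_up(
        moments.sd, moment_decimals[1]
    )
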