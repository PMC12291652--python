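"""Second-order Monte Carlo engine and summaries.

Each draw samples the model *parameters* — incremental cost (gamma),
cure-rate difference (beta) and survival-rate difference (beta) —
mutually independently, then propagates them through the decision
model: LYG = survival difference x remaining life-years, per-draw ICERs,
and net monetary benefit (NMB) at each willingness-to-pay threshold.
Summaries over the draws reproduce the probabilistic results table:
means, SDs, percentile 95% CIs, the probability of additional cost and
the cost-effectiveness acceptability curve (CEAC).

Two ICER conventions exist and genuinely differ for skewed draws: the
mean of the per-draw ratios (which has a per-draw SD) and the ratio of
the mean cost to the mean LYG.  Both are computed and reported; the
mean of ratios is the headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import BetaSpec, GammaSpec
from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "ModelParameters",
    "PsaDraw",
    "OutcomeSummary",
    "PsaSummary",
    "IcerStatistics",
    "DeterministicResults",
    "run_psa",
    "summarize",
    "icer_statistics",
    "deterministic_analysis",
    "draws_to_frame",
]

DEFAULT_N_SIMS = 1000
DEFAULT_SEED = 20250625  # documented default; any int < 2**31 works
DEFAULT_WTP_THRESHOLDS = (25_000.0, 30_000.0)

OUTCOME_NAMES = ("inc_cost", "cure_diff", "surv_diff", "lyg", "icer_lyg", "icer_cure")


@dataclass(frozen=True)
class ModelParameters:
    """Everything the simulation needs: distributions, horizon, settings."""

    cost_dist: GammaSpec
    cure_diff_dist: BetaSpec
    surv_diff_dist: BetaSpec
    remaining_years: float
    wtp_thresholds: tuple[float, ...] = DEFAULT_WTP_THRESHOLDS
    n_sims: int = DEFAULT_N_SIMS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise InvalidParameterError(f"n_sims must be >= 1, got {self.n_sims}")
        if self.remaining_years <= 0:
            raise InvalidParameterError(
                f"remaining_years must be > 0, got {self.remaining_years}"
            )
        thr = tuple(float(t) for t in self.wtp_thresholds)
        if any(t <= 0 for t in thr):
            raise InvalidParameterError(f"wtp_thresholds must be positive, got {thr}")
        if list(thr) != sorted(thr):
            raise InvalidParameterError(f"wtp_thresholds must be sorted ascending, got {thr}")
        object.__setattr__(self, "wtp_thresholds", thr)


@dataclass(frozen=True)
class PsaDraw:
    """One Monte Carlo realization of the decision model."""

    draw_id: int
    inc_cost: float        # EUR
    cure_diff: float       # proportion
    surv_diff: float       # proportion
    lyg: float             # years
    icer_lyg: float        # EUR per life-year gained
    icer_cure: float       # EUR per additional cure
    nmb: dict[float, float] = field(default_factory=dict)  # threshold -> EUR


@dataclass(frozen=True)
class OutcomeSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PsaSummary:
    """Draw-level summaries: the probabilistic results table plus the CEAC."""

    outcomes: dict[str, OutcomeSummary]
    p_additional_cost: float
    ceac: dict[float, float]
    ratio_of_means_icer: float
    n_draws: int


class IcerStatistics(NamedTuple):
    mean_of_ratios: float
    ratio_of_means: float
    sd_of_ratios: float


class DeterministicResults(NamedTuple):
    inc_cost: float
    cure_diff: float
    surv_diff: float


def run_psa(params: ModelParameters) -> list[PsaDraw]:
    """Run the second-order Monte Carlo simulation.

    Draws are mutually independent and the three parameter streams come
    from a single seeded generator in a fixed order (cost, cure,
    survival), so an identical seed reproduces the draw sequence
    bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_sims
    inc_cost = rng.gamma(params.cost_dist.shape, params.cost_dist.scale, n)
    cure = rng.beta(params.cure_diff_dist.alpha, params.cure_diff_dist.beta, n)
    surv = rng.beta(params.surv_diff_dist.alpha, params.surv_diff_dist.beta, n)
    lyg = surv * params.remaining_years
    icer_lyg = inc_cost / lyg
    icer_cure = inc_cost / cure
    draws = []
    for i in range(n):
        nmb = {lam: lam * lyg[i] - inc_cost[i] for lam in params.wtp_thresholds}
        draws.append(
            PsaDraw(
                draw_id=i,
                inc_cost=float(inc_cost[i]),
                cure_diff=float(cure[i]),
                surv_diff=float(surv[i]),
                lyg=float(lyg[i]),
                icer_lyg=float(icer_lyg[i]),
                icer_cure=float(icer_cure[i]),
                nmb=nmb,
            )
        )
    return draws


def draws_to_frame(draws: Sequence[PsaDraw]) -> pd.DataFrame:
    """Tabulate draws, one NMB column per threshold (``nmb_<threshold>``)."""
    if not draws:
        raise EmptyInputError("no draws to tabulate")
    records = []
    for d in draws:
        row = {
            "draw_id": d.draw_id,
            "inc_cost": d.inc_cost,
            "cure_diff": d.cure_diff,
            "surv_diff": d.surv_diff,
            "lyg": d.lyg,
            "icer_lyg": d.icer_lyg,
            "icer_cure": d.icer_cure,
        }
        for lam, value in d.nmb.items():
            row[f"nmb_{lam:g}"] = value
        records.append(row)
    return pd.DataFrame.from_records(records)


def summarize(
    draws: Sequence[PsaDraw], thresholds: Sequence[float] | None = None
) -> PsaSummary:
    """Reduce draws to means, SDs, percentile 95% CIs, and probabilities.

    ``p_additional_cost`` is the fraction of draws with positive
    incremental cost; ``ceac[lam]`` the fraction with positive NMB at
    threshold ``lam``.  CIs are empirical 2.5th/97.5th percentiles,
    which preserves the asymmetry of skewed outcome distributions.
    """
    if not draws:
        raise EmptyInputError("cannot summarize an empty draw list")
    if thresholds is None:
        thresholds = sorted(draws[0].nmb.keys())
    frame = draws_to_frame(draws)
    n = len(frame)
    outcomes: dict[str, OutcomeSummary] = {}
    for name in OUTCOME_NAMES:
        x = frame[name].to_numpy()
        lo, hi = np.percentile(x, [2.5, 97.5])
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        outcomes[name] = OutcomeSummary(float(np.mean(x)), sd, float(lo), float(hi))

    inc_cost = frame["inc_cost"].to_numpy()
    lyg = frame["lyg"].to_numpy()
    ceac = {}
    for lam in thresholds:
        nmb = lam * lyg - inc_cost
        ceac[float(lam)] = float(np.mean(nmb > 0))
    return PsaSummary(
        outcomes=outcomes,
        p_additional_cost=float(np.mean(inc_cost > 0)),
        ceac=ceac,
        ratio_of_means_icer=float(np.mean(inc_cost) / np.mean(lyg)),
        n_draws=n,
    )


def icer_statistics(draws: Sequence[PsaDraw]) -> IcerStatistics:
    """Both ICER conventions over the draws.

    ``mean_of_ratios`` averages the per-draw cost/LYG ratios (and is the
    only convention with a per-draw SD); ``ratio_of_means`` divides the
    mean cost by the mean LYG.  They diverge when cost and LYG draws are
    skewed, so both are reported.
    """
    if not draws:
        raise EmptyInputError("cannot compute ICER statistics on an empty draw list")
    lyg = np.array([d.lyg for d in draws])
    if np.any(lyg <= 0):
        raise InvalidParameterError("all lyg draws must be > 0 for ICER statistics")
    inc_cost = np.array([d.inc_cost for d in draws])
    ratios = inc_cost / lyg
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return IcerStatistics(
        mean_of_ratios=float(np.mean(ratios)),
        ratio_of_means=float(np.mean(inc_cost) / np.mean(lyg)),
        sd_of_ratios=sd,
    )


def deterministic_analysis(
    des_cost: float,
    ndes_cost: float,
    des_cure: float,
    ndes_cure: float,
    des_surv: float,
    ndes_surv: float,
) -> DeterministicResults:
    """Point differences, intervention minus comparator."""
    for name, rate in (
        ("des_cure", des_cure),
        ("ndes_cure", ndes_cure),
        ("des_surv", des_surv),
        ("ndes_surv", ndes_surv),
    ):
        if not (0.0 <= rate <= 1.0):
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {rate}")
    return DeterministicResults(
        inc_cost=des_cost - ndes_cost,
        cure_diff=des_cure - ndes_cure,
        surv_diff=des_surv - ndes_surv,
    )
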