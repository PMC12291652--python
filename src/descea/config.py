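"""Run configuration: schema, YAML loading, and validation.

The config mirrors the model's parameter table — one block per
quantity (incremental cost, cure-rate difference, survival-rate
difference) holding the arm means, difference moments, range, the
distribution family and optionally the published distribution
parameters — plus life-expectancy, simulation and output blocks.
Validation collects every problem before raising, so a broken file is
reported in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .calibration import (
    BetaSpec,
    GammaSpec,
    SummaryMoments,
    distribution_moments,
    fit_beta_moments,
    fit_gamma_moments,
    params_consistent_with_printed,
)
from .errors import ConfigValidationError, InvalidParameterError
from .life_years import LifeExpectancyInputs

logger = logging.getLogger(__name__)

__all__ = ["ParameterBlock", "RunConfig", "load_config", "default_config_path", "resolve_distribution"]

# printed rounding per block: (param decimals, moment decimals)
_ROUNDING = {
    "cost_per_patient": ((1, 0), (0, 0)),
    "cure_rate": ((1, 1), (3, 3)),
    "survival_rate": ((1, 1), (3, 3)),
}


@dataclass(frozen=True)
class ParameterBlock:
    """One row of the parameter table."""

    name: str
    des_mean: float
    ndes_mean: float
    difference: float
    sd: float
    distribution: str  # "gamma" or "beta"
    min: float | None = None
    max: float | None = None
    alpha: float | None = None
    beta: float | None = None

    def moments(self) -> SummaryMoments:
        return SummaryMoments(
            mean=self.difference, sd=self.sd, min_value=self.min, max_value=self.max
        )


@dataclass(frozen=True)
class RunConfig:
    cost_per_patient: ParameterBlock
    cure_rate: ParameterBlock
    survival_rate: ParameterBlock
    life_expectancy: LifeExpectancyInputs
    n_sims: int = 1000
    seed: int = 20250625
    wtp_thresholds: tuple[float, ...] = (25_000.0, 30_000.0)
    output_dir: str = "results"
    allow_param_mismatch: bool = False


def default_config_path() -> Path:
    """Path to the bundled config reproducing the published analysis."""
    return Path(str(resources.files("descea").joinpath("data/default_config.yaml")))


def resolve_distribution(block: ParameterBlock):
    """The sampling distribution a parameter block implies.

    Published alpha/beta take precedence (they are the calibration the
    published analysis actually used); otherwise the distribution is
    moment-fitted from the block's difference mean/SD.
    """
    if block.alpha is not None and block.beta is not None:
        if block.distribution == "gamma":
            return GammaSpec(shape=block.alpha, scale=block.beta)
        return BetaSpec(alpha=block.alpha, beta=block.beta)
    if block.distribution == "gamma":
        return fit_gamma_moments(block.moments())
    return fit_beta_moments(block.moments())


def _validate_block(name: str, raw: dict, issues: list[tuple[str, str]]) -> ParameterBlock | None:
    required = ("des_mean", "ndes_mean", "difference", "sd", "distribution")
    block_issues = False
    for key in required:
        if key not in raw:
            issues.append((f"parameters.{name}.{key}", "missing required key"))
            block_issues = True
    if block_issues:
        return None
    dist = str(raw["distribution"]).lower()
    if dist not in ("gamma", "beta"):
        issues.append(
            (f"parameters.{name}.distribution", f"must be 'gamma' or 'beta', got {dist!r}")
        )
        return None
    try:
        block = ParameterBlock(
            name=name,
            des_mean=float(raw["des_mean"]),
            ndes_mean=float(raw["ndes_mean"]),
            difference=float(raw["difference"]),
            sd=float(raw["sd"]),
            distribution=dist,
            min=float(raw["min"]) if "min" in raw and raw["min"] is not None else None,
            max=float(raw["max"]) if "max" in raw and raw["max"] is not None else None,
            alpha=float(raw["alpha"]) if raw.get("alpha") is not None else None,
            beta=float(raw["beta"]) if raw.get("beta") is not None else None,
        )
    except (TypeError, ValueError) as exc:
        issues.append((f"parameters.{name}", str(exc)))
        return None
    mismatch = abs(block.des_mean - block.ndes_mean - block.difference)
    if mismatch > 1.0e-9 + 1.0e-3 * max(1.0, abs(block.difference)):
        issues.append(
            (
                f"parameters.{name}.difference",
                f"difference {block.difference} inconsistent with "
                f"des_mean - ndes_mean = {block.des_mean - block.ndes_mean}",
            )
        )
    try:
        block.moments()
    except InvalidParameterError as exc:
        issues.append((f"parameters.{name}", str(exc)))
        return None
    return block


def _check_printed_params(
    block: ParameterBlock, allow_mismatch: bool, issues: list[tuple[str, str]]
) -> None:
    """Cross-check supplied alpha/beta against the moment fit."""
    if block.alpha is None or block.beta is None:
        return
    param_dec, moment_dec = _ROUNDING.get(block.name, ((1, 1), (3, 3)))
    try:
        if block.distribution == "gamma":
            fitted = fit_gamma_moments(block.moments())
            printed = GammaSpec(shape=block.alpha, scale=block.beta)
        else:
            fitted = fit_beta_moments(block.moments())
            printed = BetaSpec(alpha=block.alpha, beta=block.beta)
    except Exception as exc:
        issues.append((f"parameters.{block.name}", f"cannot fit distribution: {exc}"))
        return
    ok = params_consistent_with_printed(
        fitted, printed, block.moments(), param_dec, moment_dec
    )
    if ok:
        return
    msg = (
        f"supplied alpha/beta ({block.alpha}, {block.beta}) disagree with the "
        f"moment fit beyond printed rounding (fitted "
        f"{distribution_moments(printed).mean:.4g}/{distribution_moments(printed).sd:.4g} "
        f"vs configured {block.moments().mean:.4g}/{block.moments().sd:.4g})"
    )
    if allow_mismatch:
        logger.warning("parameters.%s: %s (override enabled)", block.name, msg)
    else:
        issues.append((f"parameters.{block.name}", msg))


def load_config(path: str | Path | None = None, *, allow_param_mismatch: bool = False) -> RunConfig:
    """Load and validate a run configuration from YAML.

    Raises :class:`ConfigValidationError` listing every offending key.
    ``allow_param_mismatch`` downgrades the printed-parameter
    cross-check from an error to a logged warning.
    """
    if path is None:
        path = default_config_path()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigValidationError([("<root>", "config file must be a mapping")])

    issues: list[tuple[str, str]] = []
    params = raw.get("parameters")
    blocks: dict[str, ParameterBlock | None] = {}
    if not isinstance(params, dict):
        issues.append(("parameters", "missing or not a mapping"))
    else:
        for name in ("cost_per_patient", "cure_rate", "survival_rate"):
            if name not in params:
                issues.append((f"parameters.{name}", "missing block"))
                blocks[name] = None
            else:
                blocks[name] = _validate_block(name, params[name], issues)

    allow = bool(raw.get("validation", {}).get("allow_param_mismatch", allow_param_mismatch))
    for block in blocks.values():
        if block is not None:
            _check_printed_params(block, allow, issues)

    le_raw = raw.get("life_expectancy", {})
    life = None
    if not isinstance(le_raw, dict):
        issues.append(("life_expectancy", "missing or not a mapping"))
    else:
        try:
            life = LifeExpectancyInputs(
                mean_age=float(le_raw.get("mean_age", 73.3)),
                le_male=float(le_raw.get("male", 80.3)),
                le_female=float(le_raw.get("female", 85.8)),
                female_weight=float(le_raw.get("female_weight", 0.5)),
            )
        except (TypeError, ValueError, InvalidParameterError) as exc:
            issues.append(("life_expectancy", str(exc)))

    sim = raw.get("simulation", {}) or {}
    n_sims = int(sim.get("n_sims", 1000))
    seed = int(sim.get("seed", 20250625))
    thresholds = tuple(float(t) for t in sim.get("wtp_thresholds", [25_000, 30_000]))
    if n_sims < 1:
        issues.append(("simulation.n_sims", f"must be >= 1, got {n_sims}"))
    if any(t <= 0 for t in thresholds):
        issues.append(("simulation.wtp_thresholds", f"must all be positive, got {thresholds}"))
    elif list(thresholds) != sorted(thresholds):
        issues.append(("simulation.wtp_thresholds", f"must be sorted ascending, got {thresholds}"))

    out = raw.get("output", {}) or {}
    output_dir = str(out.get("directory", "results"))

    if issues:
        raise ConfigValidationError(issues)
    assert life is not None
    return RunConfig(
        cost_per_patient=blocks["cost_per_patient"],  # type: ignore[arg-type]
        cure_rate=blocks["cure_rate"],  # type: ignore[arg-type]
        survival_rate=blocks["survival_rate"],  # type: ignore[arg-type]
        life_expectancy=life,
        n_sims=n_sims,
        seed=seed,
        wtp_thresholds=thresholds,
        output_dir=output_dir,
        allow_param_mismatch=allow,
    )
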