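"""Monte Carlo engine: determinism, summaries, CEAC behaviour, oracles."""

import dataclasses

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from descea import ModelParameters, deterministic_analysis, icer_statistics, run_psa, summarize
from descea.errors import EmptyInputError, InvalidParameterError
from descea.psa import PsaDraw, draws_to_frame

from conftest import (
    PRINTED_CURE_BETA,
    PRINTED_GAMMA,
    PRINTED_SURV_BETA,
    REMAINING_YEARS,
)


def _params(**overrides):
    base = dict(
        cost_dist=PRINTED_GAMMA,
        cure_diff_dist=PRINTED_CURE_BETA,
        surv_diff_dist=PRINTED_SURV_BETA,
        remaining_years=REMAINING_YEARS,
        wtp_thresholds=(25_000.0, 30_000.0),
        n_sims=1000,
        seed=11,
    )
    base.update(overrides)
    return ModelParameters(**base)


def _constant_draws(cost, lyg, n=5):
    return [
        PsaDraw(
            draw_id=i, inc_cost=cost, cure_diff=0.2, surv_diff=lyg / 10.0,
            lyg=lyg, icer_lyg=cost / lyg, icer_cure=cost / 0.2,
            nmb={25_000.0: 25_000.0 * lyg - cost},
        )
        for i in range(n)
    ]


def test_single_draw_summary_equals_the_draw():
    draws = run_psa(_params(n_sims=1))
    assert len(draws) == 1
    s = summarize(draws)
    d = draws[0]
    assert s.outcomes["inc_cost"].mean == d.inc_cost
    assert s.outcomes["lyg"].mean == d.lyg
    assert s.outcomes["icer_lyg"].mean == d.icer_lyg


def test_draw_invariants_hold(table_draws):
    frame = draws_to_frame(table_draws)
    assert (frame["inc_cost"] > 0).all()
    assert frame["cure_diff"].between(0, 1, inclusive="neither").all()
    assert frame["surv_diff"].between(0, 1, inclusive="neither").all()
    np.testing.assert_allclose(frame["lyg"], frame["surv_diff"] * REMAINING_YEARS)
    np.testing.assert_allclose(frame["icer_lyg"], frame["inc_cost"] / frame["lyg"])
    np.testing.assert_allclose(
        frame["nmb_25000"], 25_000.0 * frame["lyg"] - frame["inc_cost"]
    )


def test_identical_seed_is_bitwise_reproducible():
    p = _params(seed=42)
    a, b = run_psa(p), run_psa(p)
    assert a == b
    assert summarize(a) == summarize(b)
    c = run_psa(_params(seed=43))
    assert c != a


def test_probability_of_additional_cost_is_one_for_gamma_costs(table_draws):
    assert summarize(table_draws).p_additional_cost == 1.0


def test_ceac_monotone_with_limits(table_draws):
    s = summarize(table_draws, thresholds=[0.0, 1_000.0, 25_000.0, 30_000.0, 1e9])
    probs = [s.ceac[t] for t in sorted(s.ceac)]
    assert probs == sorted(probs)
    assert s.ceac[0.0] == 0.0          # NMB at zero WTP is -cost < 0
    assert s.ceac[1e9] == 1.0          # every draw acceptable at absurd WTP


def test_ceac_matches_numerical_integration_oracle():
    """P(lambda * L * S > C) by quadrature over the survival beta, vs Monte Carlo."""
    n = 100_000
    s = summarize(run_psa(_params(n_sims=n, seed=7)), thresholds=[25_000.0])
    gamma = scipy.stats.gamma(a=PRINTED_GAMMA.shape, scale=PRINTED_GAMMA.scale)
    beta = scipy.stats.beta(PRINTED_SURV_BETA.alpha, PRINTED_SURV_BETA.beta)
    exact, _ = scipy.integrate.quad(
        lambda x: gamma.cdf(25_000.0 * REMAINING_YEARS * x) * beta.pdf(x), 0.0, 1.0
    )
    se = np.sqrt(exact * (1 - exact) / n)
    assert s.ceac[25_000.0] == pytest.approx(exact, abs=4 * se)


def test_sample_means_converge_to_closed_form():
    """At 1e5 draws every sampled parameter mean sits within 4 SE of its analytic mean."""
    n = 100_000
    frame = draws_to_frame(run_psa(_params(n_sims=n, seed=3)))
    for column, spec in [
        ("inc_cost", PRINTED_GAMMA),
        ("cure_diff", PRINTED_CURE_BETA),
        ("surv_diff", PRINTED_SURV_BETA),
    ]:
        se = spec.sd / np.sqrt(n)
        assert frame[column].mean() == pytest.approx(spec.mean, abs=4 * se)


def test_mean_of_ratios_matches_inverse_beta_oracle():
    """E[C/ (L*S)] = E[C] * E[1/S] / L with E[1/S] = (a+b-1)/(a-1) for a beta."""
    n = 100_000
    stats = icer_statistics(run_psa(_params(n_sims=n, seed=5)))
    a, b = PRINTED_SURV_BETA.alpha, PRINTED_SURV_BETA.beta
    expected = PRINTED_GAMMA.mean * ((a + b - 1.0) / (a - 1.0)) / REMAINING_YEARS
    se = stats.sd_of_ratios / np.sqrt(n)
    assert stats.mean_of_ratios == pytest.approx(expected, abs=3 * se)


def test_icer_statistics_on_constant_draws():
    stats = icer_statistics(_constant_draws(cost=1000.0, lyg=2.0))
    assert stats.mean_of_ratios == pytest.approx(500.0)
    assert stats.ratio_of_means == pytest.approx(500.0)
    assert stats.sd_of_ratios == 0.0


def test_icer_conventions_diverge_for_skewed_draws(table_draws):
    stats = icer_statistics(table_draws)
    # Jensen: the mean of ratios exceeds the ratio of means when LYG varies
    assert stats.mean_of_ratios > stats.ratio_of_means


def test_summarize_rejects_empty_input():
    with pytest.raises(EmptyInputError):
        summarize([])
    with pytest.raises(EmptyInputError):
        icer_statistics([])


def test_icer_statistics_rejects_nonpositive_lyg():
    bad = _constant_draws(cost=100.0, lyg=2.0)
    bad.append(dataclasses.replace(bad[0], draw_id=99, lyg=-1.0))
    with pytest.raises(InvalidParameterError):
        icer_statistics(bad)


def test_percentile_intervals_bracket_the_mean(table_draws):
    s = summarize(table_draws)
    for name, o in s.outcomes.items():
        assert o.ci_low <= o.ci_high
        assert o.ci_low <= o.mean <= o.ci_high, name


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_sims": 0},
        {"wtp_thresholds": (30_000.0, 25_000.0)},
        {"wtp_thresholds": (-5.0,)},
        {"remaining_years": 0.0},
    ],
)
def test_model_parameter_validation(kwargs):
    with pytest.raises(InvalidParameterError):
        _params(**kwargs)


def test_deterministic_analysis_point_differences():
    det = deterministic_analysis(53_665.0, 14_102.0, 0.714, 0.548, 0.857, 0.714)
    assert det.inc_cost == pytest.approx(39_563.0)
    assert det.cure_diff == pytest.approx(0.166)
    assert det.surv_diff == pytest.approx(0.143)
    same = deterministic_analysis(100.0, 100.0, 0.5, 0.5, 0.5, 0.5)
    assert same == (0.0, 0.0, 0.0)
    with pytest.raises(InvalidParameterError, match="des_cure"):
        deterministic_analysis(1.0, 1.0, 1.5, 0.5, 0.5, 0.5)
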