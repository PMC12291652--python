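import pytest

from descea import (
    BetaSpec,
    GammaSpec,
    ModelParameters,
    SummaryMoments,
    load_config,
    run_psa,
)

# Published parameter table: incremental cost Gamma(1.3, 29,685),
# cure-rate difference Beta(79.9, 401.6), survival-rate difference
# Beta(82.2, 492.4); 9.75 remaining life-years (mean age 73.3 vs
# life expectancies 80.3/85.8, sexes weighted equally).
COST_MOMENTS = SummaryMoments(mean=39_563.0, sd=34_270.0, min_value=11_102.0, max_value=145_441.0)
PRINTED_GAMMA = GammaSpec(shape=1.3, scale=29_685.0)
PRINTED_CURE_BETA = BetaSpec(alpha=79.9, beta=401.6)
PRINTED_SURV_BETA = BetaSpec(alpha=82.2, beta=492.4)
REMAINING_YEARS = 9.75


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def table_params():
    return ModelParameters(
        cost_dist=PRINTED_GAMMA,
        cure_diff_dist=PRINTED_CURE_BETA,
        surv_diff_dist=PRINTED_SURV_BETA,
        remaining_years=REMAINING_YEARS,
        wtp_thresholds=(25_000.0, 30_000.0),
        n_sims=1000,
        seed=20250625,
    )


@pytest.fixture(scope="session")
def table_draws(table_params):
    return run_psa(table_params)
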