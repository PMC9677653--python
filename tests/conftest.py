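import numpy as np
import pytest

from dialysis_cea.io_cli import (
    load_calibrated_mortality,
    load_params,
    load_published_psa,
    load_published_results,
)
from dialysis_cea.param_model import Estimate, LIVING_STATES


@pytest.fixture(scope="session")
def params_config():
    return load_params()


@pytest.fixture(scope="session")
def params(params_config):
    return params_config[0]


@pytest.fixture(scope="session")
def config(params_config):
    return params_config[1]


@pytest.fixture(scope="session")
def mortality():
    return load_calibrated_mortality()


@pytest.fixture(scope="session")
def published():
    return load_published_results()


@pytest.fixture(scope="session")
def published_psa():
    return load_published_psa()


def make_simple_params(
    p_switch=0.0,
    p_pd_cc=0.0,
    p_hd_cc=0.0,
    p_acute=0.0,
    annual_cost=0.0,
    setup=0.0,
    nonmedical=0.0,
    indirect=0.0,
    acute_addon=0.0,
    utility=1.0,
):
    """Minimal all-fixed parameter set for closed-form engine checks."""
    from dialysis_cea.param_model import (
        CostParameters,
        ModelParameters,
        TransitionParameters,
        UtilityParameters,
    )

    def est(v):
        return Estimate(mean=float(v))

    states = [s.value for s in LIVING_STATES]
    transitions = {
        stratum: TransitionParameters(
            stratum=stratum,
            p_switch=est(p_switch),
            p_pd_to_pd_cc=est(p_pd_cc),
            p_hd_to_hd_cc=est(p_hd_cc),
            p_acute={s: est(p_acute) for s in states},
        )
        for stratum in ("PD", "HD")
    }
    costs = CostParameters(
        setup={"PD": est(setup), "HD": est(setup)},
        annual_direct_medical={s: est(annual_cost) for s in states},
        acute_addon=est(acute_addon),
        acute_chronic_addon=est(acute_addon),
        annual_direct_nonmedical={s: est(nonmedical) for s in states},
        annual_indirect={s: est(indirect) for s in states},
    )
    utilities = UtilityParameters(utility={s: est(utility) for s in states})
    return ModelParameters(transitions=transitions, costs=costs, utilities=utilities)


def constant_mortality(q: float):
    """Mortality model with a constant annual death probability q."""
    from dialysis_cea.survival_mortality import MortalityModel

    if q <= 0.0:
        scale = 1e12  # effectively immortal
    else:
        scale = -1.0 / np.log1p(-q)
    return MortalityModel(shape=1.0, scale=scale)
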