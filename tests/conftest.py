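import numpy as np
import pytest
from hypothesis import settings

import methioflux as mf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth_met_plus():
    return mf.default_ground_truth(mf.MET_PLUS, "bj_like")


@pytest.fixture(scope="session")
def truth_met_minus():
    return mf.default_ground_truth(mf.MET_MINUS, "bj_like")


@pytest.fixture(scope="session")
def bundle_met_plus(truth_met_plus):
    return mf.generate_experiment(truth_met_plus, seed=1)


@pytest.fixture(scope="session")
def bundle_met_minus(truth_met_minus):
    return mf.generate_experiment(truth_met_minus, seed=1)


def aux_sizes(truth):
    return {"metp": truth.pool_sizes["metp"], "akb": truth.pool_sizes["akb"]}


@pytest.fixture(scope="session")
def fitted_met_minus(truth_met_minus):
    """A converged fit on observation-level synthetic data (fast, reused)."""
    from methioflux.simulate import generate_observations

    obs = generate_observations(truth_met_minus, seed=3)
    model = mf.MethionineFluxModel(
        obs, mf.MET_MINUS, truth_met_minus.tracer, multistart=3, seed=0,
        aux_pool_sizes=aux_sizes(truth_met_minus))
    return model.fit()
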