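import numpy as np
import pytest

from pensim import engine
from pensim.config import PolicyParams
from pensim.synthetic import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def policy():
    return PolicyParams()


@pytest.fixture(scope="session")
def short_policy():
    """Reduced 2022-2045 horizon for pipeline-variation tests."""
    return PolicyParams(end_year=2045)


@pytest.fixture(scope="session")
def fitted(default_bundle, policy):
    return engine.fit_from_bundle(default_bundle, policy)


@pytest.fixture(scope="session")
def fitted_short(default_bundle, short_policy):
    return engine.fit_from_bundle(default_bundle, short_policy)


@pytest.fixture(scope="session")
def fixed_run(fitted, policy):
    return engine.run_fixed_scenario(fitted, policy)


@pytest.fixture(scope="session")
def fixed_short(fitted_short, short_policy):
    return engine.run_fixed_scenario(fitted_short, short_policy)


@pytest.fixture(scope="session")
def small_mc(fitted_short, short_policy):
    """A small stochastic ensemble on the reduced horizon."""
    return engine.run_monte_carlo(fitted_short, short_policy, n_paths=80,
                                  seed=11)


@pytest.fixture(scope="session")
def zero_noise_bundle():
    cfg = SynthConfig(seed=3, lc_innovation_sd=0.0, lc_resid_sd=0.0)
    cfg.true_ar_unemployment = type(cfg.true_ar_unemployment)(
        0.0, 0.5851, 0.0)
    cfg.true_ar_urbanization = type(cfg.true_ar_urbanization)(
        1.0476, 0.7042, 0.0)
    cfg.true_ar_wage_growth = type(cfg.true_ar_wage_growth)(
        -0.0010, -0.3095, 0.0)
    cfg.true_vasicek = type(cfg.true_vasicek)(0.0015002, 0.95275, 0.0)
    cfg.true_lognormal = type(cfg.true_lognormal)(-3.173, 0.0)
    return generate_bundle(cfg)


def make_rng(seed=0):
    return np.random.default_rng(seed)
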