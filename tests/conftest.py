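import numpy as np
import pytest

from btc_cea.config import ScenarioConfig
from btc_cea.economics import compute_cea, evaluate_arm
from btc_cea.markov import make_arm_trace


@pytest.fixture(scope="session")
def cfg() -> ScenarioConfig:
    return ScenarioConfig.bundled()


@pytest.fixture(scope="session")
def traces(cfg):
    settings = cfg.settings.to_settings()
    return {arm: make_arm_trace(s["os"], s["pfs"], settings)
            for arm, s in cfg.survival_specs().items()}


def run_base_case(cfg, traces, perspective, overrides=None):
    inputs = cfg.build_inputs(perspective, overrides)
    arms = {arm: evaluate_arm(arm, tr, inputs) for arm, tr in traces.items()}
    return compute_cea(arms, inputs.wtp, perspective)


@pytest.fixture(scope="session")
def base_us(cfg, traces):
    return run_base_case(cfg, traces, "us")


@pytest.fixture(scope="session")
def base_china(cfg, traces):
    return run_base_case(cfg, traces, "china")


def modified_config(base: ScenarioConfig, mutate) -> ScenarioConfig:
    """Rebuild a config from its dict form after applying ``mutate(data)``."""
    data = base.model_dump()
    mutate(data)
    return ScenarioConfig.model_validate(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
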