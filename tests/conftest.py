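import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tavicea as tv
from tavicea.states import Arm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_cfg() -> tv.ModelConfig:
    return tv.load_default_config()


@pytest.fixture
def calibrated_cfg() -> tv.ModelConfig:
    return tv.load_default_config("model_calibrated")


def zero_variance(cfg: tv.ModelConfig) -> tv.ModelConfig:
    """A point configuration: all PSA distributions collapsed to their means."""
    out = cfg.model_copy(deep=True)
    for cls in ("I", "II", "III", "IV"):
        setattr(out.utilities.sd_by_nyha, cls, 0.0)
    for item in out.costs:
        if item.sampling == "GAMMA":
            item.sampling = "FIXED"
            item.sd = None
    return out


def random_valid_config(rng: np.random.Generator) -> tv.ModelConfig:
    """A randomized configuration satisfying every semantic invariant."""
    cfg = zero_variance(tv.load_default_config())
    for cls in ("I", "II", "III", "IV"):
        setattr(cfg.utilities.mean_by_nyha, cls, float(rng.uniform(0.05, 0.95)))
    cfg.utilities.stroke_disutility = float(rng.uniform(0.0, 0.6))
    for arm in ("TAVI", "SAVR"):
        rates = getattr(cfg.events, arm)
        for ev in tv.parameters.EVENT_NAMES:
            setattr(rates, ev, float(rng.uniform(0.0, 0.6)))
        entry = getattr(cfg.entry, arm)
        raw = rng.uniform(0.05, 1.0, size=5)
        raw /= raw.sum()
        entry.NYHA1, entry.NYHA2, entry.NYHA3, entry.NYHA4, entry.death = (
            float(x) for x in raw
        )
    cfg.econ.discount_rate = float(rng.uniform(0.0, 0.15))
    assert tv.validate_config(cfg) == []
    return cfg


@pytest.fixture
def base_results(default_cfg):
    return {arm: tv.run_arm(arm, default_cfg) for arm in (Arm.TAVI, Arm.SAVR)}
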