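import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchkin.params import CAPTION_PARAMS, ModelParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def caption():
    """The worked-example parameter set (tau = 0)."""
    return CAPTION_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_params(rng, n: int = 2) -> ModelParams:
    """A feasible random parameter set away from degenerate corners."""
    d = rng.uniform(0.05, 0.95)
    c = rng.uniform(0.0, 0.95)
    p = rng.uniform(0.2, 0.8)
    lo = -min(p, 1 - p) / max(p, 1 - p)
    tau = rng.uniform(lo * 0.9, 0.95)
    mu_P = rng.uniform(0.1, 1.0)
    mu_R = mu_P * rng.uniform(1.0, 5.0)
    q_LR = rng.uniform(0.05, 0.5)
    q_HR = q_LR * rng.uniform(1.0, 5.0)
    q_LP = rng.uniform(0.05, 0.5)
    q_HP = q_LP * rng.uniform(1.0, 5.0)
    return ModelParams(
        d=d, c=c, p=p, tau=tau, mu_R=mu_R, mu_P=mu_P,
        q_HR=q_HR, q_LR=q_LR, q_HP=q_HP, q_LP=q_LP, n=n,
    )
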