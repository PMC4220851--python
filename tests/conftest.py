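import numpy as np
import pytest

from kstoich import ModelParams


@pytest.fixture
def table1() -> ModelParams:
    """Reference parameter set with L = 1.0 and no coercion/treatment."""
    return ModelParams()


@pytest.fixture
def fig1_params() -> ModelParams:
    """Carrying-capacity sweep setting: coercion 0.2, influx 0.05, K_t 0.045."""
    return ModelParams(l=0.2, u=0.05, K_t=0.045, L=1.0)


@pytest.fixture
def fig2_params() -> ModelParams:
    """Growth-rate sweep setting: coercion 0.009, influx 0.02, L = 1.6."""
    return ModelParams(l=0.009, u=0.02, L=1.6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140509)


def random_feasible_states(params: ModelParams, n: int,
                           rng: np.random.Generator,
                           x_max: float | None = None) -> np.ndarray:
    """Sample n random states with positive biomass and theta*y < K_t."""
    x_hi = x_max if x_max is not None else params.L
    xs = rng.uniform(1e-3, x_hi, n)
    ys = rng.uniform(1e-3, 0.95 * params.K_t / params.theta, n)
    return np.column_stack([xs, ys])
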