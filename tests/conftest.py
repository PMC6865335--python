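import numpy as np
import pytest

from colonycml import LatticeState, ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_state(rng) -> LatticeState:
    """A 51x51 periodic lattice with moderate random occupancy."""
    s = rng.uniform(0.0, 0.5, size=(51, 51))
    a = rng.uniform(0.0, 0.5, size=(51, 51))
    return LatticeState(s, a, "periodic")


def scalar_euler_oracle(
    s0: float, a0: float, params: ModelParams, n_steps: int
) -> tuple[list[float], list[float]]:
    """Independent forward-Euler iterator for one isolated compartment.

    With no diffusion and empty neighbors, the neighborhood antagonist
    density reduces to a/2 (self weight 1/2).  Written with plain floats,
    independent of the lattice code path.
    """
    s, a = s0, a0
    ss, aa = [s], [a]
    for _ in range(n_steps):
        n_a = a / 2.0
        ds = params.r_s / (1.0 + (n_a / params.K_a) ** params.hill_n) * (
            1.0 - s - params.alpha * a
        ) * s
        da = params.r_a * (1.0 - a - params.beta * s) * a
        s, a = s + ds, a + da
        ss.append(s)
        aa.append(a)
    return ss, aa
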