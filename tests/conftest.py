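import numpy as np
import pytest

from protonfcs import SAMPLES, FCSModelParams


@pytest.fixture
def nd12():
    return SAMPLES["ND12-flu"]


@pytest.fixture
def flu():
    return SAMPLES["flu"]


@pytest.fixture
def rng():
    return np.random.default_rng(20160510)


def random_valid_params(rng: np.random.Generator) -> FCSModelParams:
    """Random parameter set satisfying the model invariants."""
    fractions = rng.dirichlet([1.0, 1.0, 1.0, 1.5]) * 0.95  # P+T+R < 0.95
    return FCSModelParams(
        N=float(rng.uniform(0.5, 10.0)),
        tau_D=float(10 ** rng.uniform(-5, -3)),
        beta=float(rng.uniform(2.0, 10.0)),
        P=float(fractions[0]),
        tau_prot=float(10 ** rng.uniform(-7, -4)),
        T=float(fractions[1]),
        tau_T=float(rng.uniform(1.4e-6, 1.5e-6)),
        R=float(fractions[2]),
        tau_R=float(10 ** rng.uniform(-5.5, -4)),
    )


def gillespie_telegraph(k_on: float, k_off: float, n_events: int, seed: int):
    """Independent two-state (telegraph) oracle: exact exponential dwell
    sampling with numpy's Generator, no shared code with the simulator.

    Returns (mean deprotonated dwell, mean protonated dwell).
    """
    rng = np.random.default_rng(seed)
    dep = rng.exponential(1.0 / k_on, size=n_events)
    prot = rng.exponential(1.0 / k_off, size=n_events - 1)
    return float(dep.mean()), float(prot.mean())
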