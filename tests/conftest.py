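import numpy as np
import pytest

from navgate.io import default_channel_params, default_msa_params, prototype_drugs
from navgate.model import GateSpec, RateLaw
from navgate.msa import build_msa_model
from navgate.tetracube import build_free_model


@pytest.fixture(scope="session")
def calibrated_gates():
    return default_channel_params()


@pytest.fixture(scope="session")
def cube(calibrated_gates):
    """Drug-free calibrated gating cube."""
    return build_free_model(calibrated_gates)


@pytest.fixture(scope="session")
def msa_model():
    return build_msa_model(default_msa_params())


@pytest.fixture(scope="session")
def prototypes():
    return prototype_drugs()


@pytest.fixture(scope="session")
def toy_gates():
    """Small, hand-specified gate set for structural tests."""
    def law(A, vh, r, sense):
        return RateLaw(A=A, Vhalf=vh, r=r, sense=sense)
    return {
        "activation": GateSpec(
            "activation", law(1000.0, -40.0, 8.0, "depolarized"),
            law(500.0, -60.0, 8.0, "hyperpolarized")),
        "fast_inactivation": GateSpec(
            "fast_inactivation", law(400.0, -70.0, 10.0, "hyperpolarized"),
            law(900.0, -60.0, 9.0, "depolarized")),
        "slow_inactivation": GateSpec(
            "slow_inactivation", law(20.0, -90.0, 15.0, "hyperpolarized"),
            law(0.5, -50.0, 10.0, "depolarized")),
    }


def random_rate_matrix(rng, n):
    """Random irreducible generator matrix for oracle cross-checks."""
    from navgate.engine import RateMatrix
    Q = rng.uniform(0.1, 50.0, size=(n, n))
    # keep it irreducible but sparse-ish
    mask = rng.uniform(size=(n, n)) < 0.7
    Q = Q * mask
    for i in range(n - 1):  # guarantee a connecting chain both ways
        Q[i + 1, i] = max(Q[i + 1, i], 1.0)
        Q[i, i + 1] = max(Q[i, i + 1], 1.0)
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=0)
    return RateMatrix(states=tuple(f"s{i}" for i in range(n)), Q=Q)
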