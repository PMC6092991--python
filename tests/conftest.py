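import logging

import numpy as np
import pytest

import roicsp
from roicsp.pipeline import invert_epochs

# the reduced-filter warning for tiny ROIs is expected noise in tests
logging.getLogger("roicsp.csp").setLevel(logging.ERROR)


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0):
    """Random well-conditioned symmetric positive-definite matrix."""
    A = rng.standard_normal((n, 2 * n))
    return scale * (A @ A.T / (2 * n) + 0.1 * np.eye(n))


@pytest.fixture(scope="session")
def toy_world():
    """Default small toy world: 16 channels, 48 dipoles, 24 two-dipole ROIs."""
    return roicsp.make_toy_world(seed=1)


@pytest.fixture(scope="session")
def bench():
    """One separable benchmark session, inverted to source space."""
    lf, cat, epochs, baseline, truth = roicsp.make_benchmark_session(seed=3)
    src = invert_epochs(epochs, baseline, lf)
    return {"lf": lf, "catalog": cat, "epochs": epochs,
            "baseline": baseline, "truth": truth, "src": src}
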