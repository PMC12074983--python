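import numpy as np
import pytest

from perturbtrace.synthetic import default_compartment_profile
from perturbtrace.traces import CompartmentProfile


@pytest.fixture(scope="session")
def profile27() -> CompartmentProfile:
    return default_compartment_profile()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def profile6() -> CompartmentProfile:
    """Six-TAD toy profile (labels A,A,B,B,A,B) for brute-force checks."""
    return CompartmentProfile(
        labels=("A", "A", "B", "B", "A", "B"),
        scores=np.array([1.0, 0.5, -0.7, -1.2, 0.9, -0.3]),
        midpoints_bp=np.array([1, 2, 4, 7, 8, 10]) * 1_000_000,
    )


def random_trace(rng, n_tad=6, scale=400.0, missing=0):
    pos = rng.normal(0, scale, (n_tad, 3))
    if missing:
        drop = rng.choice(n_tad, size=missing, replace=False)
        pos[drop] = np.nan
    return pos
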