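import numpy as np
import pytest

import cocultrsm as crs


@pytest.fixture(scope="session")
def design34():
    """The study-shaped layout: 3 factors, duplicated factorial and axial
    points, six centers, two blocks -> 34 runs, 15 distinct points."""
    return crs.generate_ccd(
        k=3, factorial_reps=2, axial_reps=2, center_reps=6, n_blocks=2, seed=7
    )


@pytest.fixture(scope="session")
def design15():
    """Single-replicate CCD (8 + 6 + 1 = 15 runs), handy for LOO oracles."""
    return crs.generate_ccd(k=3, factorial_reps=1, axial_reps=1, center_reps=1, seed=3)


@pytest.fixture(scope="session")
def mbe_model():
    return crs.mbe_truth_model()


@pytest.fixture(scope="session")
def cubic_pool():
    return crs.build_terms(3, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
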