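import numpy as np
import pytest

from fuzzycyl import default_truth, make_fuzzy_cloud, scenario_scanners, simulate_scan


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def scan_50m(truth):
    scanners = scenario_scanners("50m")
    points, ids = simulate_scan(truth, scanners)
    return points, ids, scanners


@pytest.fixture(scope="session")
def fuzzy_50m(truth, scan_50m):
    points, ids, scanners = scan_50m
    return make_fuzzy_cloud(points, ids, scanners, truth)


def random_spd(rng, dim=2, scale=1.0):
    """Random symmetric positive-definite matrix with bounded conditioning."""
    A = rng.standard_normal((dim, dim))
    return scale * (A @ A.T + dim * np.eye(dim) * 0.1)
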