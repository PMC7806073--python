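import numpy as np
import pytest

from rowsim.evaluate import MetricConfig, reference_cycle
from rowsim.reference import ReferenceSpec, generate_reference


@pytest.fixture(scope="session")
def spec():
    return ReferenceSpec()


@pytest.fixture(scope="session")
def config():
    return MetricConfig()


@pytest.fixture(scope="session")
def ref_traj_120(spec):
    """Noiseless 120 s reference run at 100 Hz."""
    return generate_reference(spec, duration=120.0, sample_rate=100.0)


@pytest.fixture(scope="session")
def ref_cycle(spec, config):
    """The reference stroke resampled like a participant cycle."""
    return reference_cycle(spec, config)


def brute_force_normalized_dtw(d: np.ndarray) -> float:
    """Independent oracle: minimum of cost/length over ALL warping paths.

    Exhaustive recursion over monotone unit-step paths from (0, 0) to
    (n-1, m-1); tractable only for tiny matrices.
    """
    n, m = d.shape
    best = [np.inf]

    def rec(i, j, cost, length):
        cost += d[i, j]
        length += 1
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], cost / length)
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, cost, length)
        if i + 1 < n:
            rec(i + 1, j, cost, length)
        if j + 1 < m:
            rec(i, j + 1, cost, length)

    rec(0, 0, 0.0, 0)
    return best[0]
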