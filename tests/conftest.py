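import numpy as np
import pytest

from phasesync import BoldTimeSeries, PhaseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cosine_series():
    """0.05 Hz cosine sampled at tr = 2 s, 200 samples, 3 regions."""
    tr = 2.0
    t = np.arange(200) * tr
    f = 0.05
    values = np.vstack([np.cos(2 * np.pi * f * t)] * 3)
    return BoldTimeSeries(values=values, tr=tr, region_ids=("a", "b", "c"))


@pytest.fixture
def random_phases(rng):
    return PhaseMatrix(
        phases=rng.uniform(-np.pi, np.pi, size=(5, 40)),
        tr=2.0,
    )


def order_parameter_bruteforce(phases: np.ndarray) -> np.ndarray:
    """Direct complex-summation oracle for r(t), independent of the package path."""
    n, L = phases.shape
    r = np.empty(L)
    for t in range(L):
        total = 0 + 0j
        for j in range(n):
            total += complex(np.cos(phases[j, t]), np.sin(phases[j, t]))
        r[t] = abs(total / n)
    return r


def bh_bruteforce(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up definition applied literally: largest k with p_(k) <= k*q/m."""
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
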