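import numpy as np
import pytest

from crimpute.data import CompetingRisksDataset, TimeGrid


def make_dataset(time, status, k, p=1, rng=None):
    """Small competing-risks dataset with placeholder covariates."""
    time = np.asarray(time)
    if rng is None:
        cov = np.zeros((time.size, p))
    else:
        cov = rng.standard_normal((time.size, p))
    return CompetingRisksDataset(
        time=time, status=np.asarray(status), covariates=cov, grid=TimeGrid(k)
    )


@pytest.fixture
def toy_censoring():
    """Four records (T~, status): (1,0), (2,1), (2,0), (3,2) on k=4.

    Hand life table (events leave the censoring risk set first):
    G^(1) = 1 - 1/4 = 3/4;  G^(2) = 3/4 * (1 - 1/(3-1)) = 3/8;
    G^(3) carried forward = 3/8.
    """
    return make_dataset([1, 2, 2, 3], [0, 1, 0, 2], k=4)


@pytest.fixture
def toy_aj():
    """Four records (1,1), (2,2), (3,0), (4,1) on k=4.

    Hand Aalen-Johansen: F1(1) = 1/4, S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2,
    no event at 3, F1(4) = 1/4 + S(3) * 1/1 = 3/4.
    """
    return make_dataset([1, 2, 3, 4], [1, 2, 0, 1], k=4)


@pytest.fixture(scope="session")
def random_cr_datasets():
    """A batch of random small competing-risks datasets for property tests."""
    rng = np.random.default_rng(12345)
    out = []
    for _ in range(25):
        n = int(rng.integers(5, 60))
        k = int(rng.integers(3, 9))
        time = rng.integers(1, k + 1, n)
        status = rng.integers(0, 3, n)
        out.append(make_dataset(time, status, k, p=2, rng=rng))
    return out


def brute_force_cindex(time, status, marker, t):
    """Exhaustive-pair concordance at time t, no censoring weights.

    Ordered pairs (i, j), i != j, with status_i == 1, T_i <= t and
    (T_i < T_j or status_j >= 2); concordant when marker_i > marker_j,
    ties count 1/2.  Returns NaN when no pair is comparable.
    """
    n = len(time)
    num = den = 0.0
    for i in range(n):
        if status[i] != 1 or time[i] > t:
            continue
        for j in range(n):
            if j == i:
                continue
            if not (time[j] > time[i] or status[j] >= 2):
                continue
            den += 1.0
            if marker[i] > marker[j]:
                num += 1.0
            elif marker[i] == marker[j]:
                num += 0.5
    return num / den if den > 0 else float("nan")
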