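import numpy as np
import pytest

from icdmr.io import IntensityMatrix


@pytest.fixture(scope="session", autouse=True)
def warm_engine():
    """Trigger the one-off compilation of the EM kernel before timing-sensitive tests."""
    from icdmr.mixture import em_fit_matrix

    em_fit_matrix(np.random.default_rng(0).standard_normal((4, 6)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240512)


def make_matrix(values, chrom=None, samples=None, pos=None):
    """Small IntensityMatrix helper for tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t, n = values.shape
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * t, dtype=object)
    if pos is None:
        pos = np.zeros(t, dtype=int)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            pos[idx] = 1 + 50 * np.arange(len(idx))
    samples = samples if samples is not None else [f"s{j}" for j in range(n)]
    return IntensityMatrix(
        probe_ids=np.array([f"p{i}" for i in range(t)], dtype=object),
        chrom=chrom,
        pos=np.asarray(pos),
        samples=samples,
        values=values,
    )


@pytest.fixture
def bimodal_values(rng):
    """50 samples split evenly around -2 and +2 with tiny jitter."""
    v = np.concatenate([np.full(25, -2.0), np.full(25, 2.0)])
    return v + rng.uniform(-0.01, 0.01, size=50)
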