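import numpy as np
import pytest

from macronull import BandDomain, IncidenceMatrix, RangeEntry


@pytest.fixture
def domain() -> BandDomain:
    return BandDomain(18, 56)


@pytest.fixture
def tiny_domain() -> BandDomain:
    return BandDomain(0, 6)


@pytest.fixture
def triangular4() -> IncidenceMatrix:
    """Perfectly nested packed 4x4 matrix with row fills 4,3,2,1."""
    v = np.array(
        [
            [1, 1, 1, 1],
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return IncidenceMatrix(v, ["a", "b", "c", "d"])


@pytest.fixture
def checkerboard2() -> IncidenceMatrix:
    return IncidenceMatrix(np.array([[1, 0], [0, 1]], dtype=np.int8), ["a", "b"])


def random_matrix(n_rows: int, n_cols: int, fill: float, seed: int) -> IncidenceMatrix:
    rng = np.random.default_rng(seed)
    v = (rng.random((n_rows, n_cols)) < fill).astype(np.int8)
    return IncidenceMatrix(v, [f"s{i}" for i in range(n_rows)])


def random_ranges(n: int, domain: BandDomain, seed: int) -> list[RangeEntry]:
    rng = np.random.default_rng(seed)
    lo = rng.uniform(domain.north_limit, domain.south_limit, n)
    hi = rng.uniform(lo, domain.south_limit)
    return [RangeEntry(f"s{i}", float(a), float(b)) for i, (a, b) in enumerate(zip(lo, hi))]
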