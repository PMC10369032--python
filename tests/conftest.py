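"""Shared fixtures: small genotype spaces and naive counting oracles."""

import numpy as np
import pytest
from hypothesis import settings

from gprobust.hamming import GenotypeSpace, neighbors

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cube3():
    """H_{3,2}: binary sequences of length 3 (the 3-cube, 8 vertices)."""
    return GenotypeSpace(k=2, length=3)


@pytest.fixture(scope="session")
def square():
    """H_{2,2}: binary sequences of length 2 (the square, 4 vertices)."""
    return GenotypeSpace(k=2, length=2)


@pytest.fixture(scope="session")
def triangle_pair():
    """H_{2,3}: ternary sequences of length 2 (9 vertices)."""
    return GenotypeSpace(k=3, length=2)


@pytest.fixture(scope="session")
def cube4():
    """H_{4,2}: binary sequences of length 4 (16 vertices)."""
    return GenotypeSpace(k=2, length=4)


@pytest.fixture(scope="session")
def naive_sums_of_digits():
    """Definition-level oracle: sum the base-k digit sums of 0..n-1."""

    def oracle(n: int, k: int) -> int:
        total = 0
        for i in range(n):
            while i:
                i, r = divmod(i, k)
                total += r
        return total

    return oracle


@pytest.fixture(scope="session")
def naive_induced_edges():
    """Count within-set Hamming edges by double loop over neighbors."""

    def oracle(vertices, space) -> int:
        vs = set(vertices)
        return sum(1 for u in vs for v in neighbors(u, space) if v in vs) // 2

    return oracle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230169)
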