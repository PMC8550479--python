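import numpy as np
import pytest

import mapspace as ms

SIGMA = 1.9  # Angstrom, the package default


@pytest.fixture(scope="session")
def chain3():
    """3 collinear atoms at 3.8 A spacing: every coupling is hand-computable."""
    st = ms.make_fixture(ms.FixtureSpec(kind="chain", n_atoms=3))
    return st, ms.compute_couplings(st, sigma=SIGMA)


@pytest.fixture(scope="session")
def gas12():
    """12-atom random gas, small enough for exact enumeration at N=6."""
    st = ms.make_fixture(
        ms.FixtureSpec(kind="random-gas", n_atoms=12, box=12.0, seed=3))
    return st, ms.compute_couplings(st, sigma=SIGMA)


@pytest.fixture(scope="session")
def dense16():
    """Dense 16-atom gas (high zbar): the globular-scaling regime."""
    st = ms.make_fixture(
        ms.FixtureSpec(kind="random-gas", n_atoms=16, box=7.0,
                       min_separation=1.2, seed=11))
    return st, ms.compute_couplings(st, sigma=SIGMA)


@pytest.fixture(scope="session")
def gas50():
    st = ms.make_fixture(
        ms.FixtureSpec(kind="random-gas", n_atoms=50, box=22.0, seed=7))
    return st, ms.compute_couplings(st, sigma=SIGMA)


@pytest.fixture(scope="session")
def gas6():
    st = ms.make_fixture(
        ms.FixtureSpec(kind="random-gas", n_atoms=6, box=9.0, seed=5))
    return st, ms.compute_couplings(st, sigma=SIGMA)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def all_mappings(n):
    """Every non-empty mapping of an n-atom structure (2^n - 1 of them)."""
    out = []
    for code in range(1, 2 ** n):
        chi = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        out.append(ms.Mapping(chi))
    return out
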