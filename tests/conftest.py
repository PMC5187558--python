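import numpy as np
import pytest

from cvmlat import BistateLattice, generate_grid, generate_pattern


@pytest.fixture
def motif32() -> BistateLattice:
    """Four repeats of the 8-unit motif AAABABBB (the h=1 census pattern)."""
    return generate_pattern("equilibrium_motif", 32)


@pytest.fixture
def ferro32() -> BistateLattice:
    """32-unit circular chain: two like-domains, one interior defect each."""
    return generate_pattern("ferro_defect", 32)


def random_chains(n_lattices: int, max_n: int = 64, seed: int = 0):
    rng = np.random.default_rng(seed)
    for _ in range(n_lattices):
        n = int(rng.integers(3, max_n + 1))
        yield BistateLattice(rng.integers(0, 2, size=n, dtype=np.int8))


def random_grids(n_lattices: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    for _ in range(n_lattices):
        r = 2 * int(rng.integers(1, 4))
        c = int(rng.integers(3, 64 // r + 1))
        yield generate_grid(r, c, seed=int(rng.integers(2**31)))
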