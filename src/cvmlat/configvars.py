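"""Configuration-variable counting on bistate lattices.

The cluster variation method scores a lattice by the frequencies of its
local patterns ("configuration variables"):

* x1, x2 — single units in state A / B;
* y1, y2, y3 — nearest-neighbour pairs AA / {AB, BA} / BB;
* w1, w2, w3 — next-nearest-neighbour pairs (the two end units of each
  triplet window), same classes as y;
* z1..z6 — triplets AAA / {AAB, BAA} / ABA / BAB / {ABB, BBA} / BBB.

Classes pooling two orderings carry a degeneracy factor (beta2 = 2 for
pairs, gamma2 = gamma5 = 2 for triplets); all other factors are 1.
Fractions are stored *per arrangement*: the pooled class count divided by
(degeneracy x window total), so that x1 + x2 = sum(beta_i y_i) =
sum(beta_i w_i) = sum(gamma_i z_i) = 1.  Aggregated (degeneracy-weighted)
values are exposed alongside.

Counting conventions: a 1-D chain of N units contributes N circular
triplet windows (and N pair, N next-nearest windows).  A 2-D staggered
grid of N = R x C units is counted row-pair by row-pair: each adjacent
row pair (with vertical wrap) forms a circular zigzag chain of 2C units,
giving 2C windows per pair and 2N triplet windows overall — twice the
unit count, with every diagonal adjacency counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import BistateLattice

__all__ = [
    "DegeneracyTable",
    "DEGENERACY",
    "ConfigurationCounts",
    "ConfigurationFractions",
    "count_singles",
    "count_pairs",
    "count_triplets",
    "count_all",
]

# triplet code (4*s0 + 2*s1 + s2, A=0/B=1) -> class index 0..5 (z1..z6)
_TRIPLET_CLASS = np.array([0, 1, 2, 4, 1, 3, 4, 5])
# pair code (2*s0 + s1) -> class index 0..2 (y1..y3 / w1..w3)
_PAIR_CLASS = np.array([0, 1, 1, 2])


@dataclass(frozen=True)
class DegeneracyTable:
    """Arrangement multiplicities for the pooled configuration classes."""

    beta: tuple[int, int, int] = (1, 2, 1)
    gamma: tuple[int, int, int, int, int, int] = (1, 2, 1, 1, 2, 1)

    def __post_init__(self) -> None:
        assert sum(self.beta) == 4, "pair classes must cover the 4 ordered pairs"
        assert sum(self.gamma) == 8, "triplet classes must cover the 8 ordered triplets"


DEGENERACY = DegeneracyTable()
_BETA = np.array(DEGENERACY.beta)
_GAMMA = np.array(DEGENERACY.gamma)


def _row_pair_chains(grid: np.ndarray) -> list[np.ndarray]:
    """Circular zigzag chains for every vertically-wrapped adjacent row pair.

    Odd rows sit half a cell right of even rows, so the zigzag interleave
    order depends on the parity of the lower row index r: for even r the
    chain runs (r+1,0),(r,0),(r+1,1),(r,1),... and for odd r it runs
    (r,0),(r+1,0),(r,1),(r+1,1),...; either way consecutive chain entries
    are diagonal nearest neighbours and the wrap closes the loop.
    """
    n_rows, n_cols = grid.shape
    chains = []
    for r in range(n_rows):
        top = grid[r]
        bottom = grid[(r + 1) % n_rows]
        chain = np.empty(2 * n_cols, dtype=grid.dtype)
        if r % 2 == 0:
            chain[0::2] = bottom
            chain[1::2] = top
        else:
            chain[0::2] = top
            chain[1::2] = bottom
        chains.append(chain)
    return chains


def _chains(lattice: BistateLattice) -> list[np.ndarray]:
    if lattice.dims == 1:
        return [lattice.states]
    return _row_pair_chains(lattice.states)


def _count_windows(chain: np.ndarray, span: int, classes: np.ndarray, n_classes: int) -> np.ndarray:
    code = np.zeros(chain.size, dtype=np.intp)
    for k in range(span):
        code = 2 * code + np.roll(chain, -k)
    return np.bincount(classes[code], minlength=n_classes)


@dataclass(frozen=True)
class ConfigurationFractions:
    """Per-arrangement configuration-variable fractions.

    ``z2`` is the fraction of *one* ordering (say AAB); the pooled class
    occupies ``2 * z2`` of the triplet census.  Use :meth:`aggregated_z`
    and :meth:`aggregated_y` for degeneracy-weighted values.
    """

    x1: float
    x2: float
    y: tuple[float, float, float]
    w: tuple[float, float, float]
    z: tuple[float, float, float, float, float, float]

    @property
    def y2(self) -> float:
        return self.y[1]

    def aggregated_y(self) -> tuple[float, float, float]:
        return tuple(b * v for b, v in zip(_BETA, self.y))

    def aggregated_w(self) -> tuple[float, float, float]:
        return tuple(b * v for b, v in zip(_BETA, self.w))

    def aggregated_z(self) -> tuple[float, ...]:
        return tuple(g * v for g, v in zip(_GAMMA, self.z))

    def swap_states(self) -> "ConfigurationFractions":
        """Fractions of the A<->B relabelled lattice."""
        z = self.z
        return ConfigurationFractions(
            x1=self.x2,
            x2=self.x1,
            y=self.y[::-1],
            w=self.w[::-1],
            z=(z[5], z[4], z[3], z[2], z[1], z[0]),
        )

    def residuals(self) -> dict[str, float]:
        """Deviations of the normalisation and consistency identities.

        All are exactly zero for fractions counted on a lattice:
        the three normalisations, the pair/triplet consistency
        y2 = z2 + z4 = z3 + z5, and y1 = z1 + z2, y3 = z6 + z5.
        """
        y1, y2, y3 = self.y
        z1, z2, z3, z4, z5, z6 = self.z
        return {
            "x_norm": self.x1 + self.x2 - 1.0,
            "y_norm": sum(self.aggregated_y()) - 1.0,
            "w_norm": sum(self.aggregated_w()) - 1.0,
            "z_norm": sum(self.aggregated_z()) - 1.0,
            "y2_z2z4": y2 - (z2 + z4),
            "y2_z3z5": y2 - (z3 + z5),
            "y1_z1z2": y1 - (z1 + z2),
            "y3_z6z5": y3 - (z6 + z5),
        }

    def max_residual(self) -> float:
        return max(abs(v) for v in self.residuals().values())


@dataclass(frozen=True)
class ConfigurationCounts:
    """Raw integer window counts per configuration class.

    ``X``, ``Y``, ``W``, ``Z`` pool orderings within each class (e.g.
    ``Z[1]`` counts AAB and BAA windows together).  ``triplet_total`` is
    N for a chain and 2N for a grid; pair and next-nearest totals always
    equal the triplet total.
    """

    n_units: int
    dims: int
    X: tuple[int, int]
    Y: tuple[int, int, int]
    W: tuple[int, int, int]
    Z: tuple[int, int, int, int, int, int]
    window_total: int

    @property
    def triplet_total(self) -> int:
        return self.window_total

    @property
    def pair_total(self) -> int:
        return self.window_total

    @property
    def nnn_total(self) -> int:
        return self.window_total

    def fractions(self) -> ConfigurationFractions:
        t = self.window_total
        return ConfigurationFractions(
            x1=self.X[0] / self.n_units,
            x2=self.X[1] / self.n_units,
            y=tuple(c / (b * t) for c, b in zip(self.Y, DEGENERACY.beta)),
            w=tuple(c / (b * t) for c, b in zip(self.W, DEGENERACY.beta)),
            z=tuple(c / (g * t) for c, g in zip(self.Z, DEGENERACY.gamma)),
        )

    def pooled_triplet_fractions(self) -> dict[str, float]:
        """State-symmetric pooling (z1 with z6, z2 with z5, z3 with z4).

        For the A<->B symmetric example patterns these coincide with the
        unpooled per-arrangement values; both are exposed so asymmetric
        lattices can be examined either way.
        """
        t = self.window_total
        z = self.Z
        return {
            "z1z6": (z[0] + z[5]) / (2 * t),
            "z2z5": (z[1] + z[4]) / (4 * t),
            "z3z4": (z[2] + z[3]) / (2 * t),
        }


def count_singles(lattice: BistateLattice) -> tuple[float, float]:
    """Fractions (x1, x2) of units in states A and B."""
    n_a = lattice.count_a()
    return n_a / lattice.n_units, 1.0 - n_a / lattice.n_units


def count_pairs(lattice: BistateLattice, kind: str = "nearest"):
    """Pair class counts and per-arrangement fractions.

    ``nearest`` counts consecutive zigzag-order pairs (diagonal
    adjacencies in 2-D); ``next_nearest`` counts the end-unit pairs of
    the triplet windows (within-row pairs in 2-D).  Returns
    ``(counts, fractions, total)`` with counts pooled as (like-A, unlike,
    like-B).
    """
    if kind not in ("nearest", "next_nearest"):
        raise ValueError(f"kind must be 'nearest' or 'next_nearest', got {kind!r}")
    span_roll = 1 if kind == "nearest" else 2
    counts = np.zeros(3, dtype=np.int64)
    total = 0
    for chain in _chains(lattice):
        code = 2 * chain.astype(np.intp) + np.roll(chain, -span_roll)
        counts += np.bincount(_PAIR_CLASS[code], minlength=3)
        total += chain.size
    counts = tuple(int(c) for c in counts)
    fractions = tuple(c / (b * total) for c, b in zip(counts, DEGENERACY.beta))
    return counts, fractions, total


def count_triplets(lattice: BistateLattice):
    """Triplet class counts and per-arrangement fractions.

    Windows are all circular (i, i+1, i+2) spans of each zigzag chain:
    N windows for a 1-D chain, 2N for a 2-D grid (each adjacent row pair
    contributes one "V" and one inverted-V window per column).  Returns
    ``(counts, fractions, total)`` with counts pooled per class z1..z6.
    """
    counts = np.zeros(6, dtype=np.int64)
    total = 0
    for chain in _chains(lattice):
        counts += _count_windows(chain.astype(np.intp), 3, _TRIPLET_CLASS, 6)
        total += chain.size
    counts = tuple(int(c) for c in counts)
    fractions = tuple(c / (g * total) for c, g in zip(counts, DEGENERACY.gamma))
    return counts, fractions, total


def count_all(lattice: BistateLattice) -> ConfigurationCounts:
    """Count every configuration variable of a lattice in one pass."""
    n_a = lattice.count_a()
    y_counts, _, y_total = count_pairs(lattice, "nearest")
    w_counts, _, w_total = count_pairs(lattice, "next_nearest")
    z_counts, _, z_total = count_triplets(lattice)
    assert y_total == w_total == z_total
    return ConfigurationCounts(
        n_units=lattice.n_units,
        dims=lattice.dims,
        X=(n_a, lattice.n_units - n_a),
        Y=y_counts,
        W=w_counts,
        Z=z_counts,
        window_total=z_total,
    )
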