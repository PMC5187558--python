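"""Bistate lattices: 1-D zigzag chains and 2-D staggered grids.

A lattice is a collection of units, each in one of two states, ``A``
("on"/active) or ``B`` ("off"/inactive).  A 1-D lattice is a single
zigzag chain stored in linear (zigzag) order; drawn on paper it is two
staggered half-rows of M units each, N = 2M total, with nearest
neighbours on the diagonals, but all window counting happens along the
linear order, so that is what we store.

A 2-D lattice is a staggered grid of R rows by C columns in which
odd-indexed rows are offset by half a cell.  A unit (r, c) has diagonal
nearest neighbours (r+1, c) and (r+1, c+1) when r is even, and
(r+1, c-1) and (r+1, c) when r is odd, with all indices wrapped
periodically ("envelope" wrap).  The vertical wrap only closes
consistently when R is even, so even R is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BistateLattice",
    "LatticeFormatError",
    "PatternParameterError",
    "PATTERN_KINDS",
    "read_lattice",
    "write_lattice",
    "generate_pattern",
    "generate_grid",
]

#: Pattern kinds understood by :func:`generate_pattern`.
PATTERN_KINDS = ("ferro_defect", "equilibrium_motif", "antiferro_defect", "random")

_CHAR_TO_STATE = {"A": 0, "B": 1, "1": 0, "0": 1}
_STATE_TO_CHAR = np.array(["A", "B"])


class LatticeFormatError(ValueError):
    """Raised when lattice text is malformed (ragged rows, bad characters...)."""


class PatternParameterError(ValueError):
    """Raised when generator parameters violate a pattern's size constraints."""


@dataclass(frozen=True)
class BistateLattice:
    """A bistate (A/B) lattice in one or two dimensions.

    Parameters
    ----------
    states
        Integer array of unit states, 0 for A and 1 for B.  Shape ``(N,)``
        for a chain, ``(R, C)`` for a staggered grid.

    Notes
    -----
    Chains need N >= 3 (at least one triplet window).  Grids need an even
    number of rows R >= 2 (envelope vertical wrap on a staggered grid) and
    C >= 3 columns.
    """

    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.states, dtype=np.int8))
        if arr.ndim not in (1, 2):
            raise LatticeFormatError(f"lattice must be 1-D or 2-D, got ndim={arr.ndim}")
        if not np.isin(arr, (0, 1)).all():
            raise LatticeFormatError("unit states must all be A (0) or B (1)")
        if arr.ndim == 1:
            if arr.size < 3:
                raise LatticeFormatError(f"chain needs at least 3 units, got {arr.size}")
        else:
            r, c = arr.shape
            if r % 2:
                raise LatticeFormatError(f"grid needs an even number of rows, got R={r}")
            if r < 2 or c < 3:
                raise LatticeFormatError(f"grid needs R >= 2 and C >= 3, got R={r}, C={c}")
        arr.setflags(write=False)
        object.__setattr__(self, "states", arr)

    @property
    def dims(self) -> int:
        return self.states.ndim

    @property
    def n_units(self) -> int:
        return int(self.states.size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.states.shape

    def swap_states(self) -> "BistateLattice":
        """Return the A<->B relabelled lattice."""
        return BistateLattice(1 - self.states)

    def count_a(self) -> int:
        return int((self.states == 0).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BistateLattice):
            return NotImplemented
        return self.states.shape == other.states.shape and bool(
            (self.states == other.states).all()
        )

    def __hash__(self) -> int:
        return hash((self.states.shape, self.states.tobytes()))

    def __str__(self) -> str:
        return write_lattice(self)


def read_lattice(text: str) -> BistateLattice:
    """Parse lattice text into a :class:`BistateLattice`.

    One line of ``A``/``B`` characters is a 1-D chain; k > 1 lines form a
    2-D staggered grid with R = k rows.  ``1``/``0`` are accepted as
    aliases for A/B.  Round-trips byte-exactly with :func:`write_lattice`
    (modulo the alias normalisation).
    """
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise LatticeFormatError("empty lattice text")
    width = len(lines[0])
    rows = []
    for i, line in enumerate(lines):
        if len(line) != width:
            raise LatticeFormatError(
                f"ragged row at line {i + 1}: length {len(line)} != {width}"
            )
        row = []
        for j, ch in enumerate(line):
            try:
                row.append(_CHAR_TO_STATE[ch])
            except KeyError:
                raise LatticeFormatError(
                    f"illegal character {ch!r} at line {i + 1}, column {j + 1}"
                ) from None
        rows.append(row)
    arr = np.array(rows[0] if len(rows) == 1 else rows, dtype=np.int8)
    return BistateLattice(arr)


def write_lattice(lattice: BistateLattice) -> str:
    """Serialise a lattice as lines of ``A``/``B`` characters."""
    chars = _STATE_TO_CHAR[lattice.states]
    if lattice.dims == 1:
        return "".join(chars)
    return "\n".join("".join(row) for row in chars)


def _ferro_defect(size: int) -> np.ndarray:
    # Two like-domains of size/2, each with one opposite unit at the domain
    # midpoint (interior, >= 2 positions from each boundary).
    half = size // 2
    if half < 5:
        raise PatternParameterError(
            f"ferro_defect needs size >= 10 to keep defects interior, got {size}"
        )
    chain = np.empty(size, dtype=np.int8)
    chain[:half] = 0
    chain[half:] = 1
    chain[half // 2] = 1
    chain[half + half // 2] = 0
    return chain


def _equilibrium_motif(size: int) -> np.ndarray:
    # Repeats of the 8-unit motif A,A,A,B,A,B,B,B whose triplet census is
    # the h=1 equilibrium distribution (each of the 8 ordered triplets once).
    motif = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=np.int8)
    return np.tile(motif, size // 8)


def _antiferro_defect(size: int) -> np.ndarray:
    # Strict alternation except for exactly one A-A and one B-B adjacency.
    # Built from the circular run decomposition: size/2 - 1 runs of each
    # state, one A-run and one B-run of length 2 (placed half the run
    # sequence apart), all others of length 1.
    if size < 6:
        raise PatternParameterError(f"antiferro_defect needs size >= 6, got {size}")
    r = size // 2 - 1
    a_runs = [2] + [1] * (r - 1)
    b_runs = [1] * r
    b_runs[r // 2] = 2
    out: list[int] = []
    for a_len, b_len in zip(a_runs, b_runs):
        out.extend([0] * a_len)
        out.extend([1] * b_len)
    return np.array(out, dtype=np.int8)


def generate_pattern(kind: str, size: int, seed: int | None = None) -> BistateLattice:
    """Generate a 1-D circular-chain test pattern.

    Parameters
    ----------
    kind
        One of:

        ``ferro_defect``
            Ferromagnetic-like: two like-domains of ``size/2`` units, each
            carrying one isolated opposite-state defect at its midpoint.
        ``equilibrium_motif``
            Repeats of the 8-unit motif ``AAABABBB``, whose circular
            triplet census equals the zero-interaction (h = 1)
            equilibrium distribution.
        ``antiferro_defect``
            Antiferromagnetic-like: strict A/B alternation except exactly
            one A-A and one B-B adjacency, mutually non-adjacent.
        ``random``
            Independent unit draws with P(A) = 0.5 from ``seed``.
    size
        Total unit count.  Must be even for the defect patterns, divisible
        by 8 for ``equilibrium_motif``, and >= 3 for ``random``.
    seed
        Seed for ``random``; ignored by the deterministic kinds.

    Notes
    -----
    The three deterministic kinds all have equal A and B counts
    (x1 = x2 = 0.5), the equiprobable regime in which the closed-form
    equilibrium and the h-inversion are valid.
    """
    if kind not in PATTERN_KINDS:
        raise PatternParameterError(
            f"unknown pattern kind {kind!r}; expected one of {PATTERN_KINDS}"
        )
    if kind == "random":
        if size < 3:
            raise PatternParameterError(f"random pattern needs size >= 3, got {size}")
        rng = np.random.default_rng(seed)
        return BistateLattice(rng.integers(0, 2, size=size, dtype=np.int8))
    if kind == "equilibrium_motif":
        if size % 8:
            raise PatternParameterError(
                f"equilibrium_motif size must be divisible by 8, got {size}"
            )
        return BistateLattice(_equilibrium_motif(size))
    if size % 2:
        raise PatternParameterError(f"{kind} size must be even, got {size}")
    if kind == "ferro_defect":
        return BistateLattice(_ferro_defect(size))
    return BistateLattice(_antiferro_defect(size))


def generate_grid(rows: int, cols: int, seed: int | None = None) -> BistateLattice:
    """Generate a random 2-D staggered grid, each unit A or B with P = 0.5."""
    if rows % 2 or rows < 2 or cols < 3:
        raise PatternParameterError(
            f"grid needs even R >= 2 and C >= 3, got R={rows}, C={cols}"
        )
    rng = np.random.default_rng(seed)
    return BistateLattice(rng.integers(0, 2, size=(rows, cols), dtype=np.int8))
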