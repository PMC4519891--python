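"""Face-centered cubic (FCC) lattice geometry and chain encoding.

A protein conformation is modelled as a self-avoiding walk (SAW) of Cα
positions on the FCC lattice.  Every lattice point has 12 neighbours at
squared Euclidean distance 2, reached by the displacement vectors with two
components in {-1,+1} and one zero component.  A conformation is encoded
as a string of absolute moves, each a direction label in 1..12, so a chain
of n residues carries n-1 moves.

Lattice units are converted to Ångström by the uniform factor 3.8/sqrt(2),
which maps the nearest-neighbour step onto the mean Cα–Cα virtual bond
length of 3.8 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "CA_STEP_ANGSTROM",
    "Direction",
    "DIRECTIONS",
    "Conformation",
    "InvalidMoveError",
    "SelfAvoidanceError",
    "direction_vectors",
    "decode_moves",
    "parse_moves",
    "format_moves",
    "neighbors",
    "contact_pairs",
    "scale_coordinates",
    "random_saw",
]

#: Mean Cα–Cα virtual bond length in real proteins, in Å.
CA_STEP_ANGSTROM = 3.8

#: Uniform lattice-to-Å scaling; one FCC step has length sqrt(2) lattice units.
LATTICE_SCALE = CA_STEP_ANGSTROM / math.sqrt(2.0)


class Direction(NamedTuple):
    """One of the 12 FCC moves: integer label, mnemonic name, unit step."""

    label: int
    name: str
    vector: tuple[int, int, int]


# Label order 1..12.  The published table assigns front/back/left/right/up/
# down mnemonics; BR is (+1,0,-1), completing the standard FCC neighbourhood
# {(±1,±1,0), (±1,0,±1), (0,±1,±1)} (12 distinct vectors, closed under
# negation).
DIRECTIONS: tuple[Direction, ...] = (
    Direction(1, "FL", (1, 1, 0)),
    Direction(2, "FR", (1, -1, 0)),
    Direction(3, "FU", (-1, 1, 0)),
    Direction(4, "FD", (-1, -1, 0)),
    Direction(5, "BL", (1, 0, 1)),
    Direction(6, "BR", (1, 0, -1)),
    Direction(7, "BU", (-1, 0, 1)),
    Direction(8, "BD", (-1, 0, -1)),
    Direction(9, "LU", (0, 1, 1)),
    Direction(10, "LD", (0, 1, -1)),
    Direction(11, "RU", (0, -1, 1)),
    Direction(12, "RD", (0, -1, -1)),
)

_VECTOR_TO_LABEL: dict[tuple[int, int, int], int] = {
    d.vector: d.label for d in DIRECTIONS
}

#: (12, 3) integer array of the direction vectors in label order.
DIRECTION_ARRAY: np.ndarray = np.array([d.vector for d in DIRECTIONS], dtype=np.int64)


class InvalidMoveError(ValueError):
    """A move symbol outside 1..12, or a move string of the wrong length."""


class SelfAvoidanceError(ValueError):
    """The walk revisits a lattice point.

    Attributes
    ----------
    index : int
        0-based index of the first chain position that collides with an
        earlier one.
    """

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"walk self-intersects at position {index}")


def direction_vectors() -> tuple[Direction, ...]:
    """Return the 12 FCC directions in label order 1..12."""
    return DIRECTIONS


def neighbors(point: Sequence[int]) -> list[tuple[int, int, int]]:
    """The 12 lattice neighbours of ``point`` (squared distance 2)."""
    x, y, z = (int(c) for c in point)
    return [(x + dx, y + dy, z + dz) for dx, dy, dz in DIRECTION_ARRAY.tolist()]


def parse_moves(text: str) -> tuple[int, ...]:
    """Parse a move string of whitespace-separated labels in 1..12."""
    moves = []
    for tok in text.split():
        try:
            m = int(tok)
        except ValueError:
            raise InvalidMoveError(f"move symbol {tok!r} is not an integer") from None
        if not 1 <= m <= 12:
            raise InvalidMoveError(f"move symbol {m} outside 1..12")
        moves.append(m)
    return tuple(moves)


def format_moves(moves: Iterable[int]) -> str:
    """Inverse of :func:`parse_moves`."""
    return " ".join(str(m) for m in moves)


@dataclass(frozen=True)
class Conformation:
    """A sequence placed on a self-avoiding FCC walk.

    ``coords`` is an (n, 3) integer array starting at the origin; step
    ``i`` equals the direction vector of ``moves[i]``.
    """

    sequence: str
    moves: tuple[int, ...]
    coords: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=np.int64))
        self.coords.setflags(write=False)

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Conformation):
            return NotImplemented
        return self.sequence == other.sequence and self.moves == other.moves

    def __hash__(self) -> int:
        return hash((self.sequence, self.moves))

    @property
    def n(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Assert the SAW invariants (origin start, unit FCC steps, distinct)."""
        if self.coords.shape != (self.n, 3):
            raise ValueError("coords shape does not match sequence length")
        if self.n and self.coords[0].any():
            raise ValueError("walk must start at the origin")
        steps = np.diff(self.coords, axis=0)
        for i, step in enumerate(steps):
            if tuple(step.tolist()) not in _VECTOR_TO_LABEL:
                raise InvalidMoveError(f"step {i} is not an FCC direction")
        seen: set[tuple[int, int, int]] = set()
        for i, p in enumerate(map(tuple, self.coords.tolist())):
            if p in seen:
                raise SelfAvoidanceError(i)
            seen.add(p)


def moves_from_coords(coords: np.ndarray) -> tuple[int, ...]:
    """Recover the absolute move labels from a coordinate walk."""
    steps = np.diff(np.asarray(coords, dtype=np.int64), axis=0)
    try:
        return tuple(_VECTOR_TO_LABEL[tuple(s)] for s in map(tuple, steps.tolist()))
    except KeyError as exc:
        raise InvalidMoveError(f"step {exc.args[0]} is not an FCC direction") from None


def conformation_from_coords(sequence: str, coords: np.ndarray) -> Conformation:
    """Build a :class:`Conformation` from raw coordinates (origin-shifted)."""
    coords = np.asarray(coords, dtype=np.int64)
    coords = coords - coords[0]
    return Conformation(sequence, moves_from_coords(coords), coords)


def decode_moves(sequence: str, moves: str | Sequence[int]) -> Conformation:
    """Decode an absolute move string into lattice coordinates.

    Raises
    ------
    InvalidMoveError
        If a symbol is outside 1..12 or the move count is not ``n - 1``.
    SelfAvoidanceError
        If the walk revisits a point; ``index`` names the first collision.
    """
    if isinstance(moves, str):
        moves = parse_moves(moves)
    else:
        moves = tuple(int(m) for m in moves)
        for m in moves:
            if not 1 <= m <= 12:
                raise InvalidMoveError(f"move symbol {m} outside 1..12")
    n = len(sequence)
    if len(moves) != n - 1:
        raise InvalidMoveError(
            f"expected {n - 1} moves for a sequence of length {n}, got {len(moves)}"
        )
    coords = np.zeros((n, 3), dtype=np.int64)
    if moves:
        coords[1:] = np.cumsum(DIRECTION_ARRAY[np.array(moves) - 1], axis=0)
    seen: set[tuple[int, int, int]] = set()
    for i, p in enumerate(map(tuple, coords.tolist())):
        if p in seen:
            raise SelfAvoidanceError(i)
        seen.add(p)
    return Conformation(sequence, moves, coords)


def is_self_avoiding(coords: np.ndarray) -> bool:
    """True when no lattice point repeats."""
    pts = list(map(tuple, np.asarray(coords, dtype=np.int64).tolist()))
    return len(set(pts)) == len(pts)


def contact_pairs(conformation: Conformation) -> set[tuple[int, int]]:
    """Topological contacts: pairs (i, j), j >= i+2, at lattice-neighbour
    distance (squared distance 2).  Chain-adjacent pairs never count.

    Returns 0-based index pairs with i < j.
    """
    coords = conformation.coords
    occupied = {tuple(p): i for i, p in enumerate(coords.tolist())}
    pairs: set[tuple[int, int]] = set()
    for i, p in enumerate(coords.tolist()):
        for q in neighbors(p):
            j = occupied.get(q)
            if j is not None and j >= i + 2:
                pairs.add((i, j))
    return pairs


def scale_coordinates(conformation: Conformation | np.ndarray) -> np.ndarray:
    """Map lattice coordinates to Å so consecutive Cα–Cα distance is 3.8 Å."""
    coords = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation)
    )
    return coords.astype(np.float64) * LATTICE_SCALE


def random_saw(
    n: int,
    rng: np.random.Generator | int,
    sequence: str | None = None,
    max_restarts: int = 10_000,
) -> Conformation:
    """Sample a random self-avoiding FCC walk of ``n`` points.

    Grows the chain one step at a time, choosing uniformly among unoccupied
    neighbours; a dead end triggers a full restart.  Deterministic for a
    given seed.  ``sequence`` defaults to poly-alanine of length ``n``.
    """
    if n < 2:
        raise ValueError("a walk needs at least 2 points")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")
    dirs = DIRECTION_ARRAY.tolist()
    for _ in range(max_restarts):
        pts: list[tuple[int, int, int]] = [(0, 0, 0)]
        occupied = {pts[0]}
        moves: list[int] = []
        while len(pts) < n:
            order = rng.permutation(12)
            for k in order:
                dx, dy, dz = dirs[k]
                x, y, z = pts[-1]
                q = (x + dx, y + dy, z + dz)
                if q not in occupied:
                    pts.append(q)
                    occupied.add(q)
                    moves.append(int(k) + 1)
                    break
            else:
                break  # dead end: restart
        if len(pts) == n:
            return Conformation(sequence, tuple(moves), np.array(pts, dtype=np.int64))
    raise RuntimeError(f"failed to sample a SAW of length {n} in {max_restarts} tries")
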