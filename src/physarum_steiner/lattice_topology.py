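"""Grids, site states, identification-space topologies and active zones.

The organism lives on an ``M x M`` square grid.  Every site carries one of
three states: ``OUTSIDE`` (not part of any organism), ``CYTOPLASM`` (interior
material, may never touch the outside) and ``MEMBRANE`` (boundary material,
must touch the outside).  Adjacency is the von Neumann 4-neighborhood mapped
through the edge identifications of the chosen surface, which is how the same
automaton runs unchanged on the bounded square, the torus, the Klein bottle,
the real projective plane and the sphere.

Coordinates are ``(x, y)`` with ``x`` the column growing eastward and ``y``
the row growing southward, both 0-based.  Internally sites are flattened
row-major (``index = y * M + x``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np


class SiteState(enum.IntEnum):
    """State of a single grid site."""

    OUTSIDE = 0
    CYTOPLASM = 1
    MEMBRANE = 2


#: Direction offsets in the fixed order used everywhere: north, east, south,
#: west.  ``(dx, dy)`` with y growing southward, so north is ``(0, -1)``.
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, -1), (1, 0), (0, 1), (-1, 0))

TOPOLOGY_KINDS = ("bounded", "torus", "klein", "rp2", "sphere")


@dataclass(frozen=True)
class Topology:
    """An ``M x M`` square with optional edge identifications.

    ``bounded`` has no identifications (edge sites simply have fewer
    neighbors).  The closed surfaces glue the square's edges pairwise:

    * ``torus``  -- both direction pairs wrap modulo ``M``.
    * ``klein``  -- east/west wrap plainly; north/south glue with a
      horizontal flip: north of ``(x, 0)`` is ``(M-1-x, M-1)``.
    * ``rp2``    -- both pairs glue with a flip (north/south as ``klein``,
      east of ``(M-1, y)`` is ``(0, M-1-y)``).
    * ``sphere`` -- the north edge is glued to the west edge and the south
      edge to the east edge by transposition (north of ``(x, 0)`` is
      ``(0, x)``); the two fixed corners lose their self-neighbors.
    """

    kind: str
    M: int

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.kind!r}; expected one of {TOPOLOGY_KINDS}")
        if self.M < 3:
            raise ValueError(f"grid side M must be >= 3, got {self.M}")

    def neighbor_table(self) -> np.ndarray:
        """Flat neighbor table of shape ``(M*M, 4)``; ``-1`` marks a missing
        direction (off-grid on ``bounded``, dropped self/duplicate on
        ``sphere``).  Columns follow :data:`DIRECTIONS` (N, E, S, W)."""
        return _neighbor_table(self.kind, self.M)


def _map_direction(kind: str, M: int, x: int, y: int, dx: int, dy: int) -> tuple[int, int] | None:
    nx, ny = x + dx, y + dy
    if 0 <= nx < M and 0 <= ny < M:
        return nx, ny
    if kind == "bounded":
        return None
    if kind == "torus":
        return nx % M, ny % M
    if kind == "klein":
        if nx < 0 or nx >= M:  # east/west wrap plainly
            return nx % M, ny
        if ny < 0:  # crossing the north edge flips x
            return M - 1 - x, M - 1
        return M - 1 - x, 0
    if kind == "rp2":
        if ny < 0:
            return M - 1 - x, M - 1
        if ny >= M:
            return M - 1 - x, 0
        if nx < 0:
            return M - 1, M - 1 - y
        return 0, M - 1 - y
    # sphere: north<->west and south<->east glued by transposition
    if ny < 0:
        return 0, x
    if nx < 0:
        return y, 0
    if ny >= M:
        return M - 1, x
    return y, M - 1


@lru_cache(maxsize=None)
def _neighbor_table(kind: str, M: int) -> np.ndarray:
    table = np.full((M * M, 4), -1, dtype=np.int32)
    for y in range(M):
        for x in range(M):
            i = y * M + x
            seen: list[int] = []
            for d, (dx, dy) in enumerate(DIRECTIONS):
                mapped = _map_direction(kind, M, x, y, dx, dy)
                if mapped is None:
                    continue
                nx, ny = mapped
                j = ny * M + nx
                if j == i or j in seen:  # self-identification / duplicate
                    continue
                seen.append(j)
                table[i, d] = j
    table.setflags(write=False)
    return table


def neighbors(p: tuple[int, int], topology: Topology) -> list[tuple[int, int]]:
    """Ordered (N, E, S, W) list of the distinct neighbors of site ``p``.

    Off-grid directions on the bounded square and the sphere's corner
    self-identifications are omitted.
    """
    x, y = p
    M = topology.M
    if not (0 <= x < M and 0 <= y < M):
        raise ValueError(f"site {p} outside the {M}x{M} grid")
    row = topology.neighbor_table()[y * M + x]
    return [(int(j) % M, int(j) // M) for j in row if j >= 0]


@dataclass(frozen=True)
class ActiveZone:
    """A terminal of the Steiner instance: a 2x2 block of sites.

    ``anchor`` is the (column, row) of the block's top-left site.
    """

    anchor: tuple[int, int]

    @property
    def sites(self) -> tuple[tuple[int, int], ...]:
        x, y = self.anchor
        return ((x, y), (x + 1, y), (x, y + 1), (x + 1, y + 1))

    def flat_sites(self, M: int) -> list[int]:
        return [y * M + x for (x, y) in self.sites]

    def validate(self, M: int, obstacle: np.ndarray | None = None) -> None:
        x, y = self.anchor
        if not (0 <= x <= M - 2 and 0 <= y <= M - 2):
            raise ValueError(f"active zone anchored at {self.anchor} does not fit a {M}x{M} grid")
        if obstacle is not None:
            for sx, sy in self.sites:
                if obstacle[sy, sx]:
                    raise ValueError(f"active zone at {self.anchor} overlaps an obstacle at {(sx, sy)}")


def validate_zones(zones: Sequence[ActiveZone], M: int, obstacle: np.ndarray | None = None) -> None:
    """Check every zone is in-grid, obstacle-free and pairwise disjoint."""
    occupied: dict[tuple[int, int], int] = {}
    for k, z in enumerate(zones):
        z.validate(M, obstacle)
        for site in z.sites:
            if site in occupied:
                raise ValueError(f"active zones {occupied[site]} and {k} overlap at site {site}")
            occupied[site] = k


class Lattice:
    """Mutable simulation grid: site states, origin-cell IDs, obstacles.

    ``origin_id`` tracks which spawned cell each piece of material came from
    (0 where there is no material); it rides along with the material as
    bubbles swap it around, so fused organisms remain attributable to their
    founders.  Obstacle sites are permanently ``OUTSIDE``: never a stimulus,
    never entered by material or bubbles.
    """

    __slots__ = ("topology", "states", "origin_id", "obstacle")

    def __init__(
        self,
        topology: Topology,
        states: np.ndarray | None = None,
        origin_id: np.ndarray | None = None,
        obstacle: np.ndarray | None = None,
    ) -> None:
        M = topology.M
        self.topology = topology
        self.states = np.zeros((M, M), dtype=np.uint8) if states is None else np.asarray(states, dtype=np.uint8)
        self.origin_id = (
            np.zeros((M, M), dtype=np.int32) if origin_id is None else np.asarray(origin_id, dtype=np.int32)
        )
        self.obstacle = (
            np.zeros((M, M), dtype=bool) if obstacle is None else np.asarray(obstacle, dtype=bool)
        )
        for name in ("states", "origin_id", "obstacle"):
            arr = getattr(self, name)
            if arr.shape != (M, M):
                raise ValueError(f"{name} must have shape {(M, M)}, got {arr.shape}")
        if self.states[self.obstacle].any():
            raise ValueError("obstacle sites must be OUTSIDE")

    @property
    def M(self) -> int:
        return self.topology.M

    def copy(self) -> "Lattice":
        return Lattice(self.topology, self.states.copy(), self.origin_id.copy(), self.obstacle.copy())

    def organism_mask(self) -> np.ndarray:
        return self.states > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lattice):
            return NotImplemented
        return (
            self.topology == other.topology
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.origin_id, other.origin_id)
            and np.array_equal(self.obstacle, other.obstacle)
        )


def count_area(lattice: Lattice) -> int:
    """Number of organism sites (cytoplasm + membrane)."""
    return int(np.count_nonzero(lattice.states))


def connected_components(lattice: Lattice) -> np.ndarray:
    """Label organism sites into 4-connected components under the topology.

    Returns an ``(M, M)`` int32 array: 0 on non-organism sites, labels
    ``1..k`` on organism sites.  Two organism sites share a label iff they
    are connected through organism sites under the topology's neighbor
    relation.
    """
    from ._kernels import label_components

    M = lattice.M
    labels = np.zeros(M * M, dtype=np.int32)
    queue = np.empty(M * M, dtype=np.int32)
    label_components(lattice.states.reshape(-1), lattice.topology.neighbor_table(), labels, queue)
    return labels.reshape(M, M)


def load_obstacle_mask(path: str, M: int | None = None) -> np.ndarray:
    """Read an obstacle mask from an ASCII grid ('#'=obstacle, '.'=free) or a
    PGM (P2/P5) image where pixel value 0 means obstacle."""
    with open(path, "rb") as fh:
        head = fh.read(2)
    if head in (b"P2", b"P5"):
        from PIL import Image

        img = np.asarray(Image.open(path))
        mask = img == 0
    else:
        rows: list[list[bool]] = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                bad = set(line) - {"#", "."}
                if bad:
                    raise ValueError(f"obstacle mask contains invalid characters {sorted(bad)}")
                rows.append([c == "#" for c in line])
        if not rows:
            raise ValueError("obstacle mask file is empty")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("obstacle mask rows have inconsistent lengths")
        mask = np.array(rows, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"obstacle mask must be square, got shape {mask.shape}")
    if M is not None and mask.shape != (M, M):
        raise ValueError(f"obstacle mask shape {mask.shape} does not match grid side M={M}")
    return mask


def save_obstacle_mask(mask: np.ndarray, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in np.asarray(mask, dtype=bool):
            fh.write("".join("#" if c else "." for c in row) + "\n")
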