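"""The CELL model: shaped virtual Physarum cells and bubble transport.

A cell is a blob of organism material obeying two local constraints: a
MEMBRANE site must touch at least one OUTSIDE site, a CYTOPLASM site must
touch none.  The only dynamical move is a *bubble event*: a piece of the
outside is introduced at a stimulated membrane site and percolates through
the organism by swapping places with material, which over many events makes
the whole cell crawl, fuse with neighbors, or retract.

Two event modes exist.  *Conserving* events (exploration) first displace the
stimulus material outward into an adjacent free site, so the organism's area
never changes; this is the amoebic-motion mode.  *Eroding* events (used by
the shrinking phase) delete the stimulus material outright, shrinking the
organism by exactly one site per event.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt
from typing import Iterable, Literal

import numpy as np

from . import _kernels as K
from .lattice_topology import Lattice, SiteState

WalkPolicy = Literal["stable", "free", "cyto_only"]

_WALK_POLICIES = {
    "stable": K.WALK_STABLE,
    "free": K.WALK_FREE,
    "cyto_only": K.WALK_CYTO_ONLY,
}


class RunRNG:
    """Deterministic xorshift128+ stream shared by every random choice.

    One instance is created per run; the stimulus choice, the bubble entry
    neighbor and every walk step draw from it in a fixed documented order, so
    a run is reproducible bit-for-bit from its seed.
    """

    __slots__ = ("state", "seed")

    def __init__(self, seed: int) -> None:
        self.seed = int(seed)
        self.state = np.zeros(2, dtype=np.uint64)
        K.seed_rng(np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF), self.state)

    def random(self) -> float:
        return float(K.rand_unit(self.state))

    def below(self, n: int) -> int:
        if n <= 0:
            raise ValueError("empty choice set")
        return int(K.rand_below(self.state, n))


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the automaton.

    ``n_swaps`` is the maximum number of swaps a bubble may take and
    ``s_max`` the maximum number of OUTSIDE neighbors an eligible stimulus
    may have; the defaults (1000 and 3) are the standard operating point of
    the model.  ``iteration_cap`` bounds a whole run; ``no_change_threshold``
    is the number of iterations without an area change after which the
    shrinking phase declares the network final.

    ``walk_policy``, ``membrane_budget`` and ``walk_leak`` govern the
    bubble-walk reconstruction (see the methods note).  The default
    ``stable`` policy lets bubbles percolate through cytoplasm (crossing
    membrane at most ``membrane_budget`` times per walk, and with
    probability ``walk_leak`` even when cytoplasm is available) and come to
    rest only where the surrounding material stays locally contiguous; this
    retracts surfaces and prunes dead ends while never severing the thin
    network.
    """

    n_swaps: int = 1000
    s_max: int = 3
    iteration_cap: int = 10_000_000
    no_change_threshold: int = 1_000_000
    seed: int | None = None
    walk_policy: WalkPolicy = "stable"
    membrane_budget: int = 1000
    walk_leak: float = 0.15

    def __post_init__(self) -> None:
        if self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")
        if not (0 <= self.s_max <= 4):
            raise ValueError("s_max must lie in 0..4 for the von Neumann neighborhood")
        if self.iteration_cap < 0 or self.no_change_threshold <= 0:
            raise ValueError("iteration caps must be positive")
        if self.membrane_budget < 0:
            raise ValueError("membrane_budget must be >= 0")
        if not (0.0 <= self.walk_leak <= 1.0):
            raise ValueError("walk_leak must lie in [0, 1]")
        if self.walk_policy not in _WALK_POLICIES:
            raise ValueError(f"unknown walk_policy {self.walk_policy!r}")

    @property
    def walk_policy_code(self) -> int:
        return _WALK_POLICIES[self.walk_policy]


@dataclass(frozen=True)
class CellSpawnSpec:
    """How to seed the grid with cells.

    ``tile`` layout places footprints on a regular grid with period
    ``size + spacing`` starting at the origin, skipping any placement that
    leaves the grid or touches an obstacle.  ``count`` layout spreads
    ``count`` footprints on a centered ceil(sqrt(count))-square lattice over
    the free area.
    """

    shape: Literal["square", "diamond"] = "square"
    size: int = 9
    layout: Literal["tile", "count"] = "tile"
    spacing: int = 1
    count: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"cell size must be an odd positive integer, got {self.size}")
        if self.shape not in ("square", "diamond"):
            raise ValueError(f"unknown cell shape {self.shape!r}")
        if self.layout not in ("tile", "count"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")
        if self.layout == "count" and (self.count is None or self.count < 1):
            raise ValueError("count layout requires a positive count")

    def footprint(self) -> set[tuple[int, int]]:
        return cell_footprint(self.shape, self.size)


@dataclass
class Bubble:
    """A live piece of the outside percolating through an organism."""

    position: tuple[int, int]
    swaps_used: int = 0


def cell_footprint(shape: str, size: int) -> set[tuple[int, int]]:
    """Offsets of a cell footprint centered at (0, 0).

    ``square`` of side k covers max(|dx|,|dy|) <= (k-1)/2 (k**2 sites);
    ``diamond`` of width k covers |dx|+|dy| <= (k-1)/2, the L1 ball with
    (k**2+1)/2 sites.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"cell size must be an odd positive integer, got {size}")
    r = (size - 1) // 2
    if shape == "square":
        return {(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)}
    if shape == "diamond":
        return {
            (dx, dy)
            for dx in range(-r, r + 1)
            for dy in range(-(r - abs(dx)), r - abs(dx) + 1)
        }
    raise ValueError(f"unknown cell shape {shape!r}")


def _tile_anchors(M: int, size: int, spacing: int) -> list[tuple[int, int]]:
    period = size + spacing
    return [
        (ax, ay)
        for ay in range(0, M - size + 1, period)
        for ax in range(0, M - size + 1, period)
    ]


def _count_anchors(M: int, size: int, count: int) -> list[tuple[int, int]]:
    g = ceil(sqrt(count))
    anchors = []
    for row in range(g):
        for col in range(g):
            if len(anchors) >= count:
                break
            cx = (col + 0.5) * M / g - size / 2.0
            cy = (row + 0.5) * M / g - size / 2.0
            ax = min(max(int(round(cx)), 0), M - size)
            ay = min(max(int(round(cy)), 0), M - size)
            anchors.append((ax, ay))
    return anchors


def spawn_cells(lattice: Lattice, spec: CellSpawnSpec, rng: RunRNG | None = None) -> Lattice:
    """Place cells on an empty lattice, each with a fresh origin id.

    Placement is deterministic (the layouts are regular); placements that
    would leave the grid or overlap an obstacle are skipped in ``tile``
    layout and are an error in ``count`` layout.  States are repaired after
    placement, so the returned lattice satisfies both constraints.
    """
    if lattice.organism_mask().any():
        raise ValueError("spawn_cells requires a lattice with no organism sites")
    M = lattice.M
    fp = sorted(spec.footprint())
    r = (spec.size - 1) // 2
    if spec.layout == "tile":
        anchors = _tile_anchors(M, spec.size, spec.spacing)
    else:
        anchors = _count_anchors(M, spec.size, spec.count or 1)

    placed = 0
    taken = np.zeros((M, M), dtype=bool)
    for ax, ay in anchors:
        cx, cy = ax + r, ay + r
        sites = [(cx + dx, cy + dy) for dx, dy in fp]
        ok = all(
            0 <= x < M and 0 <= y < M and not lattice.obstacle[y, x] and not taken[y, x]
            for x, y in sites
        )
        if not ok:
            if spec.layout == "count":
                continue
            continue
        placed += 1
        for x, y in sites:
            taken[y, x] = True
            lattice.states[y, x] = SiteState.CYTOPLASM
            lattice.origin_id[y, x] = placed
    if spec.layout == "count" and placed < (spec.count or 0):
        raise ValueError(
            f"could only place {placed} of the requested {spec.count} cells "
            f"on the {M}x{M} grid"
        )
    if placed == 0:
        raise ValueError("spawn spec placed no cells on the grid")
    repair_states(lattice)
    return lattice


def repair_states(lattice: Lattice) -> Lattice:
    """Restore the two state constraints in one deterministic pass.

    Every organism site becomes MEMBRANE if any neighbor (off-grid and
    obstacle sites count as OUTSIDE) is OUTSIDE, else CYTOPLASM.  Idempotent
    and equal to the fixed point of iterating the naive rule.
    """
    flat = lattice.states.reshape(-1)
    K.repair_all(flat, lattice.topology.neighbor_table())
    return lattice


def eligible_stimuli(
    lattice: Lattice,
    region: Iterable[tuple[int, int]] | None = None,
    s_max: int = 3,
) -> set[tuple[int, int]]:
    """Sites where a bubble may be introduced.

    A stimulus must be MEMBRANE, have between 1 and ``s_max`` OUTSIDE
    neighbors (off-grid/obstacle included -- the cap excludes nearly
    detached protrusion tips), and at least one enterable OUTSIDE neighbor
    (in-grid, non-obstacle) so conserving introduction cannot fail.
    """
    M = lattice.M
    flat = lattice.states.reshape(-1)
    obst = lattice.obstacle.reshape(-1).astype(np.uint8)
    nbr = lattice.topology.neighbor_table()
    if region is None:
        out = np.empty(M * M, dtype=np.int64)
        cnt = K.collect_eligible(flat, obst, nbr, s_max, out)
    else:
        sites = np.array(sorted(y * M + x for (x, y) in region), dtype=np.int64)
        out = np.empty(max(len(sites), 1), dtype=np.int64)
        cnt = K.collect_eligible_subset(flat, obst, nbr, s_max, sites, out)
    return {(int(i) % M, int(i) // M) for i in out[:cnt]}


def introduce_bubble(
    lattice: Lattice,
    t: tuple[int, int],
    mode: Literal["conserving", "eroding"],
    rng: RunRNG,
    s_max: int = 3,
) -> tuple[Lattice, Bubble]:
    """Introduce a bubble at eligible stimulus ``t`` and repair states.

    Conserving mode displaces the stimulus material into a uniformly chosen
    enterable OUTSIDE neighbor first (area unchanged); eroding mode deletes
    it (area decreases by exactly 1).
    """
    if mode not in ("conserving", "eroding"):
        raise ValueError(f"unknown bubble mode {mode!r}")
    x, y = t
    M = lattice.M
    i = y * M + x
    flat = lattice.states.reshape(-1)
    obst = lattice.obstacle.reshape(-1).astype(np.uint8)
    nbr = lattice.topology.neighbor_table()
    if not K.is_eligible(flat, obst, nbr, i, s_max):
        raise ValueError(f"site {t} is not an eligible stimulus")
    touched = np.empty(8, dtype=np.int64)
    cnt = K.introduce(flat, lattice.origin_id.reshape(-1), obst, nbr, i,
                      mode == "conserving", rng.state, touched)
    K.repair_touched(flat, nbr, touched, cnt)
    return lattice, Bubble(position=t)


def propagate_bubble(
    lattice: Lattice,
    bubble: Bubble,
    n_swaps: int,
    rng: RunRNG,
    walk_policy: WalkPolicy = "stable",
    membrane_budget: int = 1000,
    walk_leak: float = 0.15,
) -> Lattice:
    """Percolate ``bubble`` by up to ``n_swaps`` material swaps, then repair.

    Each step swaps the bubble with a uniformly chosen CYTOPLASM neighbor;
    when none exists it may cross MEMBRANE (at most ``membrane_budget``
    times per walk).  Under the default ``stable`` policy the bubble rests
    only where the surrounding material remains locally contiguous,
    retreating along its trail if necessary.  Area is conserved (swaps
    only).
    """
    x, y = bubble.position
    M = lattice.M
    i = y * M + x
    flat = lattice.states.reshape(-1)
    if flat[i] != 0:
        raise ValueError(f"bubble position {bubble.position} is not OUTSIDE")
    nbr = lattice.topology.neighbor_table()
    touched = np.empty(4 * n_swaps + 2 * membrane_budget + 16, dtype=np.int64)
    protected = np.zeros(M * M, dtype=np.uint8)
    cnt, pos = K.walk(flat, lattice.origin_id.reshape(-1), nbr, i, n_swaps,
                      membrane_budget, _WALK_POLICIES[walk_policy], walk_leak,
                      rng.state, touched, 0, -1, protected)
    K.repair_touched(flat, nbr, touched, cnt)
    bubble.position = (int(pos) % M, int(pos) // M)
    bubble.swaps_used += cnt // 2
    return lattice
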