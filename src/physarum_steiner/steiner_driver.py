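"""The two-phase explore-and-fuse Steiner driver.

*Foraging* spawns many cells and lets conserving bubble events move and fuse
them.  The stimulus is drawn globally with probability

    p_random = (N - points_discovered + cells_effective - 1) / (N + cells_initial)

and otherwise from membrane inside already-discovered zones, which anchors
the swarm to terminals it has found.  When p_random reaches zero -- every
zone discovered and held by a single organism -- the run latches into
*shrinking*: stimuli now come only from the zones and erode material (area
-1 per effective event, the bubble percolating inward and retracting the
surface where it safely comes to rest), with a direct removal of interior
zone cytoplasm when no zone stimulus is eligible.  The run ends when the
area has not changed for ``no_change_threshold`` iterations (or at
``iteration_cap``); a finished network -- every leaf a terminal pad, no
safe resting place reachable -- is provably frozen, which is the normal way
the counter fires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

from . import _kernels as K
from .cell_dynamics import ModelParams, RunRNG, spawn_cells
from .lattice_topology import ActiveZone, Lattice, connected_components, count_area

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_io import Scenario

TRACE_COLUMNS = ("iteration", "area", "points_discovered", "cells_effective", "p_random", "phase")


def compute_p_random(
    N: int, points_discovered: int, cells_effective: int, cells_initial: int
) -> float:
    """Probability of the global (exploratory) stimulus option.

    Zero exactly when all N zones are discovered and one organism holds them
    all, which triggers the phase switch.  Clamped into [0, 1] (component
    splits can transiently push cells_effective past cells_initial).
    """
    if cells_effective < 1:
        raise ValueError("cells_effective must be >= 1; no organism holds any zone")
    p = (N - points_discovered + cells_effective - 1) / (N + cells_initial)
    return min(max(p, 0.0), 1.0)


def _zone_arrays(zones: Sequence[ActiveZone], M: int) -> tuple[np.ndarray, np.ndarray]:
    sites: list[int] = []
    zone_of: list[int] = []
    for z, zone in enumerate(zones):
        for i in zone.flat_sites(M):
            sites.append(i)
            zone_of.append(z)
    return np.asarray(sites, dtype=np.int64), np.asarray(zone_of, dtype=np.int64)


def points_discovered(lattice: Lattice, zones: Sequence[ActiveZone]) -> int:
    """Number of zones with at least one organism site (occupancy contact)."""
    flat = lattice.states.reshape(-1)
    return sum(1 for z in zones if any(flat[i] > 0 for i in z.flat_sites(lattice.M)))


def cells_effective(lattice: Lattice, zones: Sequence[ActiveZone]) -> int:
    """Number of disjoint organism components holding at least one zone site.

    A component counts once however many zones it touches; components
    touching no zone are excluded.
    """
    labels = connected_components(lattice).reshape(-1)
    flat = lattice.states.reshape(-1)
    seen: set[int] = set()
    for z in zones:
        for i in z.flat_sites(lattice.M):
            if flat[i] > 0:
                seen.add(int(labels[i]))
    return len(seen)


def has_loops(lattice: Lattice, zones: Sequence[ActiveZone]) -> bool:
    """Flood-fill loop check: does a solution component enclose an OUTSIDE
    pocket?

    On the bounded square a pocket is an OUTSIDE site unreachable from the
    border; on closed surfaces it is an OUTSIDE component other than the
    largest.  Only pockets bordered by a component that holds a zone site
    count -- stray blobs with holes are not part of the solution.
    """
    M = lattice.M
    n = M * M
    zone_sites, _ = _zone_arrays(zones, M)
    flat = lattice.states.reshape(-1)
    nbr = lattice.topology.neighbor_table()
    labels = np.zeros(n, dtype=np.int32)
    labels0 = np.zeros(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    visited = np.zeros(n, dtype=np.uint8)
    bounded = lattice.topology.kind == "bounded"
    return bool(
        K.pocket_loops(flat, nbr, M, bounded, zone_sites, labels, labels0, queue, visited)
    )


def solution_length(lattice: Lattice, zones: Sequence[ActiveZone]) -> int:
    """Organism sites in components holding at least one zone site.

    Stray cells disconnected from every zone are ignored.
    """
    labels = connected_components(lattice).reshape(-1)
    flat = lattice.states.reshape(-1)
    keep: set[int] = set()
    for z in zones:
        for i in z.flat_sites(lattice.M):
            if flat[i] > 0:
                keep.add(int(labels[i]))
    if not keep:
        return 0
    keep_arr = np.zeros(int(labels.max()) + 1, dtype=bool)
    for l in keep:
        keep_arr[l] = True
    return int(np.count_nonzero(keep_arr[labels] & (flat > 0)))


@dataclass
class PhaseTracker:
    """Live counters of a run."""

    N: int
    cells_initial: int
    points_discovered: int = 0
    cells_effective: int = 0
    p_random: float = 1.0
    phase: str = "foraging"
    iteration: int = 0
    true_iterations: float = 0.0
    no_change_counter: int = 0
    last_area: int = 0
    phase_switch_iteration: int | None = None


@dataclass
class RunResult:
    """Outcome of a run."""

    success: bool
    termination: str  # "no_change" | "iteration_cap" | "early_stop"
    iterations: int
    true_iterations: float
    phase_switch_iteration: int | None
    solution_length: int
    loops_present: bool | None
    final_lattice: Lattice
    area_trace: np.ndarray  # columns TRACE_COLUMNS
    points_discovered: int
    cells_effective: int
    initial_area: int
    cells_spawned: int
    constraint_violations: int | None = None
    foraging_area_changes: int = 0
    shrink_actions: int = 0
    shrink_decrements: int = 0
    shrink_rejected: int = 0

    def to_dict(self) -> dict:
        return {
            "success": self.success,
            "termination": self.termination,
            "iterations": self.iterations,
            "true_iterations": self.true_iterations,
            "phase_switch_iteration": self.phase_switch_iteration,
            "solution_length": self.solution_length,
            "loops_present": self.loops_present,
            "points_discovered": self.points_discovered,
            "cells_effective": self.cells_effective,
            "initial_area": self.initial_area,
            "cells_spawned": self.cells_spawned,
            "constraint_violations": self.constraint_violations,
            "foraging_area_changes": self.foraging_area_changes,
            "shrink_actions": self.shrink_actions,
            "shrink_decrements": self.shrink_decrements,
            "shrink_rejected": self.shrink_rejected,
        }

    def trace_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.area_trace, columns=list(TRACE_COLUMNS))


class _Engine:
    """Shared buffer set + kernel plumbing for stepping and full runs."""

    def __init__(
        self,
        lattice: Lattice,
        zones: Sequence[ActiveZone],
        params: ModelParams,
        cells_initial: int,
        rng: RunRNG,
        enforce_tree: bool = False,
        check_constraints: bool = False,
    ) -> None:
        M = lattice.M
        n = M * M
        self.lattice = lattice
        self.zones = list(zones)
        self.params = params
        self.rng = rng
        self.enforce_tree = enforce_tree
        self.check_constraints = check_constraints
        self.M = M
        self.flat = lattice.states.reshape(-1)
        self.origin = lattice.origin_id.reshape(-1)
        self.obstacle = np.ascontiguousarray(lattice.obstacle.reshape(-1).astype(np.uint8))
        self.nbr = lattice.topology.neighbor_table()
        self.zone_sites, self.zone_of = _zone_arrays(zones, M)
        self.labels = np.zeros(n, dtype=np.int32)
        self.labels0 = np.zeros(n, dtype=np.int32)
        self.queue = np.empty(n, dtype=np.int32)
        self.cand = np.empty(n, dtype=np.int64)
        # percolation + expulsion stages can each take up to n_swaps swaps
        self.touched = np.empty(4 * params.n_swaps + 2 * params.membrane_budget + 16, dtype=np.int64)
        self.lbl_stamp = np.zeros(n + 1, dtype=np.int64)
        self.visited = np.zeros(n, dtype=np.uint8)
        self.special = np.zeros(n, dtype=np.uint8)
        self.comp_cyto = np.zeros(n + 1, dtype=np.uint8)
        self.protected = np.zeros(n, dtype=np.uint8)
        self.protected[self.zone_sites] = 1
        self.ic = np.zeros(K.N_ICOUNTERS, dtype=np.int64)
        self.fc = np.zeros(K.N_FCOUNTERS, dtype=np.float64)
        self.ic[K.I_AREA] = count_area(lattice)
        self.ic[K.I_DIRTY] = 1
        self.ic[K.I_SWITCH] = -1
        self.bounded = lattice.topology.kind == "bounded"
        self.ic_cells_initial = cells_initial

    def advance(self, max_iters: int, trace: np.ndarray, trace_every: int,
                allow_fastforward: bool) -> int:
        p = self.params
        return K.run_chunk(
            self.flat, self.origin, self.obstacle, self.nbr,
            self.zone_sites, self.zone_of, len(self.zones), self.ic_cells_initial,
            p.n_swaps, p.membrane_budget, p.s_max, p.iteration_cap, p.no_change_threshold,
            self.enforce_tree, p.walk_policy_code, p.walk_leak,
            self.check_constraints, allow_fastforward, self.bounded, self.M,
            self.rng.state, self.ic, self.fc,
            self.labels, self.labels0, self.queue, self.cand, self.touched,
            self.lbl_stamp, self.visited, self.special, self.comp_cyto, self.protected,
            trace, trace_every, max_iters,
        )

    def tracker(self) -> PhaseTracker:
        ic, fc = self.ic, self.fc
        return PhaseTracker(
            N=len(self.zones),
            cells_initial=self.ic_cells_initial,
            points_discovered=int(ic[K.I_PD]),
            cells_effective=int(ic[K.I_CE]),
            p_random=float(fc[K.F_P_RANDOM]),
            phase="foraging" if ic[K.I_PHASE] == K.PHASE_FORAGING else "shrinking",
            iteration=int(ic[K.I_ITER]),
            true_iterations=float(fc[K.F_TRUE_ITERS]),
            no_change_counter=int(ic[K.I_QUIET]),
            last_area=int(ic[K.I_AREA]),
            phase_switch_iteration=None if ic[K.I_SWITCH] < 0 else int(ic[K.I_SWITCH]),
        )


def make_engine(
    lattice: Lattice,
    zones: Sequence[ActiveZone],
    params: ModelParams,
    cells_initial: int,
    rng: RunRNG,
    **kw,
) -> _Engine:
    """Build a stepping engine (used by the single-step operations)."""
    return _Engine(lattice, zones, params, cells_initial, rng, **kw)


def foraging_step(engine: _Engine) -> PhaseTracker:
    """Execute exactly one foraging iteration (phase may latch to shrinking)."""
    if engine.ic[K.I_PHASE] != K.PHASE_FORAGING:
        raise ValueError("engine is not in the foraging phase")
    _no_trace = np.empty((1, 6), dtype=np.float64)
    engine.advance(1, _no_trace, 0, False)
    return engine.tracker()


def shrinking_step(engine: _Engine) -> PhaseTracker:
    """Execute exactly one shrinking iteration."""
    if engine.ic[K.I_PHASE] != K.PHASE_SHRINKING:
        raise ValueError("engine is not in the shrinking phase")
    _no_trace = np.empty((1, 6), dtype=np.float64)
    engine.advance(1, _no_trace, 0, False)
    return engine.tracker()


def run(
    scenario: "Scenario",
    params: ModelParams | None = None,
    *,
    seed: int | None = None,
    enforce_tree: bool = False,
    early_stop: int | None = None,
    check_constraints: bool = False,
    trace_every: int = 1024,
    chunk: int = 65536,
    snapshot_every: int | None = None,
    snapshot_callback: Callable[[int, Lattice], None] | None = None,
) -> RunResult:
    """Run the full two-phase algorithm on ``scenario``.

    ``early_stop`` halts the run at a given iteration (redundant-network
    mode: the network may still contain loops).  ``enforce_tree`` keeps
    shrinking past the quiet threshold until the flood-fill loop check comes
    back clean.  Success means the no-change termination fired and a single
    component holds every zone.
    """
    params = params or scenario.params
    run_seed = seed if seed is not None else (params.seed if params.seed is not None else scenario.seed)
    rng = RunRNG(run_seed)
    lattice = scenario.build_lattice()
    spawn_cells(lattice, scenario.spawn, rng)
    cells_initial = int(lattice.origin_id.max())
    initial_area = count_area(lattice)

    eng = make_engine(
        lattice, scenario.zones, params, cells_initial, rng,
        enforce_tree=enforce_tree, check_constraints=check_constraints,
    )

    trace_rows: list[np.ndarray] = []
    limit = params.iteration_cap if early_stop is None else min(early_stop, params.iteration_cap)
    # the frozen-state fast forward can jump past an early-stop point, so it
    # is only enabled for full runs
    allow_ff = early_stop is None
    buf = np.empty((max(chunk // max(trace_every, 1) + 2, 4), 6), dtype=np.float64)
    while eng.ic[K.I_TERM] == K.TERM_RUNNING and eng.ic[K.I_ITER] < limit:
        step = min(chunk, limit - int(eng.ic[K.I_ITER]))
        if snapshot_every:
            step = min(step, snapshot_every - int(eng.ic[K.I_ITER]) % snapshot_every)
        nt = eng.advance(step, buf, trace_every, allow_ff)
        if nt:
            trace_rows.append(buf[:nt].copy())
        if snapshot_every and snapshot_callback and eng.ic[K.I_ITER] % snapshot_every == 0:
            snapshot_callback(int(eng.ic[K.I_ITER]), lattice)

    term_code = int(eng.ic[K.I_TERM])
    if term_code == K.TERM_NO_CHANGE:
        termination = "no_change"
    elif term_code == K.TERM_CAP or eng.ic[K.I_ITER] >= params.iteration_cap:
        termination = "iteration_cap"
    else:
        termination = "early_stop"

    # final metrics on the terminal lattice
    ncomp = K.label_components(eng.flat, eng.nbr, eng.labels, eng.queue)
    eng.ic[K.I_STAMP] += 1
    pd_, ce_ = K.zone_metrics(eng.flat, eng.labels, eng.zone_sites, eng.zone_of,
                              len(eng.zones), eng.lbl_stamp, eng.ic[K.I_STAMP])
    one_comp = bool(
        K.zones_in_one_component(eng.flat, eng.labels, eng.zone_sites, eng.zone_of, len(eng.zones))
    )
    loops = has_loops(lattice, scenario.zones)
    success = termination == "no_change" and pd_ == len(scenario.zones) and one_comp

    final_row = np.array(
        [[
            float(eng.ic[K.I_ITER]), float(eng.ic[K.I_AREA]), float(pd_),
            float(ce_), float(eng.fc[K.F_P_RANDOM]), float(eng.ic[K.I_PHASE]),
        ]],
        dtype=np.float64,
    )
    trace_rows.append(final_row)
    trace = np.concatenate(trace_rows, axis=0)

    return RunResult(
        success=success,
        termination=termination,
        iterations=int(eng.ic[K.I_ITER]),
        true_iterations=float(eng.fc[K.F_TRUE_ITERS]),
        phase_switch_iteration=None if eng.ic[K.I_SWITCH] < 0 else int(eng.ic[K.I_SWITCH]),
        solution_length=solution_length(lattice, scenario.zones),
        loops_present=loops,
        final_lattice=lattice,
        area_trace=trace,
        points_discovered=int(pd_),
        cells_effective=int(ce_),
        initial_area=initial_area,
        cells_spawned=cells_initial,
        constraint_violations=int(eng.ic[K.I_VIOL]) if check_constraints else None,
        foraging_area_changes=int(eng.ic[K.I_FORAGE_AREA_CHANGES]),
        shrink_actions=int(eng.ic[K.I_SHRINK_ACTIONS]),
        shrink_decrements=int(eng.ic[K.I_SHRINK_DECREMENTS]),
        shrink_rejected=int(eng.ic[K.I_SHRINK_REJECTED]),
    )
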