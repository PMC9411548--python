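"""Two-phase driver tests: the stimulus-mixing probability, zone metrics,
loop detection and full seeded runs."""

import numpy as np
import pytest

from physarum_steiner import (
    ActiveZone,
    Scenario,
    cells_effective,
    compute_p_random,
    connected_components,
    has_loops,
    points_discovered,
    run,
    solution_length,
)
from physarum_steiner.cell_dynamics import CellSpawnSpec, ModelParams
from physarum_steiner.lattice_topology import neighbors

from conftest import lattice_from_ascii, random_lattice

FAST = ModelParams(iteration_cap=50_000, no_change_threshold=10_000)


class TestPRandom:
    def test_fresh_swarm_is_nearly_all_exploration(self):
        assert compute_p_random(100, 0, 100, 100) == pytest.approx(199 / 200)

    def test_zero_at_full_discovery_by_one_organism(self):
        # the phase-switch condition: every zone found, one effective cell
        assert compute_p_random(100, 100, 1, 100) == 0.0

    def test_intermediate_value(self):
        assert compute_p_random(100, 50, 10, 100) == pytest.approx(59 / 200)

    def test_no_effective_cell_is_an_error(self):
        with pytest.raises(ValueError):
            compute_p_random(10, 0, 0, 10)

    def test_bounded_on_full_counter_lattice(self):
        # exhaustive over all valid counter states for N, cells_initial <= 30
        for N in range(1, 31):
            for ci in range(1, 31):
                for pd in range(0, N + 1):
                    for ce in range(1, ci + 1):
                        p = compute_p_random(N, pd, ce, ci)
                        assert 0.0 <= p <= 1.0


class TestZoneMetrics:
    def _scan_oracle(self, lat, zones):
        pd = sum(
            1 for z in zones if any(lat.states[y, x] > 0 for x, y in z.sites)
        )
        labels = connected_components(lat)
        eff = {
            int(labels[y, x])
            for z in zones
            for x, y in z.sites
            if lat.states[y, x] > 0
        }
        return pd, len(eff)

    def test_empty_lattice(self):
        lat = lattice_from_ascii(["." * 8] * 8)
        zones = [ActiveZone((0, 0)), ActiveZone((4, 4))]
        assert points_discovered(lat, zones) == 0
        assert cells_effective(lat, zones) == 0

    def test_fully_covered(self):
        lat = lattice_from_ascii(["o" * 8] * 8)
        zones = [ActiveZone((0, 0)), ActiveZone((4, 4))]
        assert points_discovered(lat, zones) == 2
        assert cells_effective(lat, zones) == 1

    def test_component_counts_once_over_many_zones(self):
        rows = ["oooooooo"] + ["........"] * 7
        lat = lattice_from_ascii(rows)
        zones = [ActiveZone((0, 0)), ActiveZone((4, 0))]
        assert cells_effective(lat, zones) == 1

    def test_cell_on_no_zone_not_counted(self):
        rows = ["oo..oo..",
                "oo..oo..",
                "........",
                "......oo",
                "......oo"] + ["........"] * 3
        lat = lattice_from_ascii(rows)
        zones = [ActiveZone((0, 0)), ActiveZone((4, 0))]
        assert cells_effective(lat, zones) == 2  # the (6,3) blob touches no zone

    def test_matches_scan_oracle_on_random_lattices(self, np_rng):
        zones = [ActiveZone((0, 0)), ActiveZone((3, 3)), ActiveZone((5, 0))]
        for _ in range(60):
            lat = random_lattice(np_rng, M=8)
            pd, ce = self._scan_oracle(lat, zones)
            assert points_discovered(lat, zones) == pd
            assert cells_effective(lat, zones) == ce


def _loops_oracle(lat, zones):
    """DFS flood fill of the OUTSIDE region from the grid border; any
    unreached OUTSIDE site enclosed by a zone-holding component is a loop."""
    M = lat.M
    seen = np.zeros((M, M), dtype=bool)
    stack = [
        (x, y)
        for x in range(M)
        for y in (0, M - 1)
        if lat.states[y, x] == 0
    ] + [
        (x, y)
        for y in range(M)
        for x in (0, M - 1)
        if lat.states[y, x] == 0
    ]
    for x, y in stack:
        seen[y, x] = True
    while stack:
        p = stack.pop()
        for qx, qy in neighbors(p, lat.topology):
            if lat.states[qy, qx] == 0 and not seen[qy, qx]:
                seen[qy, qx] = True
                stack.append((qx, qy))
    labels = connected_components(lat)
    sol = {
        int(labels[y, x])
        for z in zones
        for x, y in z.sites
        if lat.states[y, x] > 0
    }
    for y in range(M):
        for x in range(M):
            if lat.states[y, x] == 0 and not seen[y, x]:
                for qx, qy in neighbors((x, y), lat.topology):
                    if lat.states[qy, qx] > 0 and int(labels[qy, qx]) in sol:
                        return True
    return False


class TestHasLoops:
    def test_straight_path_has_none(self):
        rows = ["........", ".######.", "........"] + ["........"] * 5
        lat = lattice_from_ascii(rows)
        assert not has_loops(lat, [ActiveZone((1, 1))])

    def test_closed_ring_encloses_a_pocket(self):
        rows = ["........",
                ".#####..",
                ".#...#..",
                ".#...#..",
                ".#####..",
                "........",
                "........",
                "........"]
        lat = lattice_from_ascii(rows)
        assert has_loops(lat, [ActiveZone((1, 1))])

    def test_stray_blob_pocket_not_a_solution_loop(self):
        rows = ["........",
                ".###....",
                ".#.#....",
                ".###....",
                "........",
                "......oo",
                "......oo",
                "........"]
        lat = lattice_from_ascii(rows)
        # the ring belongs to no zone-holding component
        assert not has_loops(lat, [ActiveZone((6, 5))])

    def test_matches_flood_fill_oracle(self, np_rng):
        zones = [ActiveZone((2, 2)), ActiveZone((5, 5))]
        for _ in range(80):
            lat = random_lattice(np_rng, M=8, p_fill=0.55)
            assert has_loops(lat, zones) == _loops_oracle(lat, zones)


class TestSolutionLength:
    def test_single_component_no_strays(self):
        rows = ["........", ".######.", "........"] + ["........"] * 5
        lat = lattice_from_ascii(rows)
        assert solution_length(lat, [ActiveZone((1, 0))]) == 6

    def test_stray_blob_excluded(self):
        rows = ["........",
                ".####...",
                "........",
                "........",
                ".....ooo",
                ".....ooo",
                "........",
                "........"]
        lat = lattice_from_ascii(rows)
        # stray 6-site blob touches no zone: only the 4-path counts
        assert solution_length(lat, [ActiveZone((1, 0))]) == 4

    def test_matches_component_filter_oracle(self, np_rng):
        zones = [ActiveZone((1, 1)), ActiveZone((5, 5))]
        for _ in range(40):
            lat = random_lattice(np_rng, M=8)
            labels = connected_components(lat)
            sol = {
                int(labels[y, x])
                for z in zones
                for x, y in z.sites
                if lat.states[y, x] > 0
            }
            expected = sum(
                1
                for y in range(8)
                for x in range(8)
                if lat.states[y, x] > 0 and int(labels[y, x]) in sol
            )
            assert solution_length(lat, zones) == expected


class TestStepping:
    def _engine(self, seed=9):
        from physarum_steiner import make_engine
        from physarum_steiner.cell_dynamics import RunRNG, spawn_cells

        sc = Scenario(
            M=24,
            zones=[ActiveZone((3, 11)), ActiveZone((18, 11))],
            spawn=CellSpawnSpec("square", 7, "tile", 1),
            params=FAST,
            seed=seed,
        )
        rng = RunRNG(seed)
        lat = sc.build_lattice()
        spawn_cells(lat, sc.spawn, rng)
        eng = make_engine(lat, sc.zones, FAST, int(lat.origin_id.max()), rng)
        return sc, lat, eng

    def test_foraging_step_conserves_area_and_counts(self):
        from physarum_steiner import count_area, foraging_step

        sc, lat, eng = self._engine()
        area0 = count_area(lat)
        tracker = foraging_step(eng)
        assert tracker.iteration == 1
        assert count_area(lat) == area0
        assert 0.0 <= tracker.p_random <= 1.0

    def test_phase_latches_and_steps_enforce_it(self):
        from physarum_steiner import foraging_step, shrinking_step

        sc, lat, eng = self._engine()
        with pytest.raises(ValueError, match="not in the shrinking phase"):
            shrinking_step(eng)
        tracker = foraging_step(eng)
        while tracker.phase == "foraging" and tracker.iteration < 20_000:
            tracker = foraging_step(eng)
        assert tracker.phase == "shrinking"
        assert tracker.p_random == 0.0
        with pytest.raises(ValueError, match="not in the foraging phase"):
            foraging_step(eng)

    def test_fusion_preserves_origin_ids_and_merges_effective_cells(self):
        from physarum_steiner import cells_effective, foraging_step

        sc, lat, eng = self._engine()
        founders = set(np.unique(lat.origin_id)) - {0}
        assert cells_effective(lat, sc.zones) == 2  # one cell per zone at spawn
        tracker = foraging_step(eng)
        while tracker.phase == "foraging" and tracker.iteration < 20_000:
            tracker = foraging_step(eng)
        # both zones now held by a single organism; material still traceable
        assert cells_effective(lat, sc.zones) == 1
        assert (set(np.unique(lat.origin_id)) - {0}) <= founders

    def test_shrinking_steps_never_increase_area(self):
        from physarum_steiner import count_area, foraging_step, shrinking_step

        sc, lat, eng = self._engine(seed=11)
        tracker = foraging_step(eng)
        while tracker.phase == "foraging" and tracker.iteration < 20_000:
            tracker = foraging_step(eng)
        area = count_area(lat)
        for _ in range(300):
            tracker = shrinking_step(eng)
            new_area = count_area(lat)
            assert new_area in (area, area - 1)
            area = new_area


class TestRun:
    def test_single_covered_zone_switches_immediately(self):
        # one zone fully inside one spawned cell: p_random = 0 at iteration 0
        sc = Scenario(
            M=12,
            zones=[ActiveZone((5, 5))],
            spawn=CellSpawnSpec("square", 9, "count", count=1),
            params=FAST,
            seed=1,
        )
        res = run(sc, FAST, seed=1)
        assert res.phase_switch_iteration == 0

    def test_zero_cap_fails_immediately(self):
        params = ModelParams(iteration_cap=0, no_change_threshold=1000)
        sc = Scenario(
            M=12,
            zones=[ActiveZone((5, 5))],
            spawn=CellSpawnSpec("square", 9, "count", count=1),
            params=params,
            seed=1,
        )
        res = run(sc, params)
        assert not res.success and res.termination == "iteration_cap"
        assert res.iterations == 0

    def test_seeded_two_zone_run_connects(self):
        params = ModelParams(iteration_cap=500_000, no_change_threshold=50_000)
        sc = Scenario(
            M=30,
            zones=[ActiveZone((4, 14)), ActiveZone((24, 14))],
            spawn=CellSpawnSpec("square", 9, "tile", 1),
            params=params,
            seed=3,
        )
        res = run(sc, params, seed=3)
        assert res.success
        labels = connected_components(res.final_lattice)
        zl = {
            int(labels[y, x])
            for z in sc.zones
            for x, y in z.sites
            if res.final_lattice.states[y, x] > 0
        }
        assert len(zl) == 1  # both zones in one component

    def test_run_is_deterministic_per_seed(self):
        params = ModelParams(iteration_cap=200_000, no_change_threshold=20_000)
        sc = Scenario(
            M=24,
            zones=[ActiveZone((3, 11)), ActiveZone((18, 11))],
            spawn=CellSpawnSpec("square", 7, "tile", 1),
            params=params,
            seed=5,
        )
        r1 = run(sc, params, seed=5)
        r2 = run(sc, params, seed=5)
        assert r1.iterations == r2.iterations
        assert np.array_equal(r1.final_lattice.states, r2.final_lattice.states)
        assert r1.true_iterations == r2.true_iterations
        r3 = run(sc, params, seed=6)
        assert not np.array_equal(r1.final_lattice.states, r3.final_lattice.states)

    def test_true_iterations_bounded_by_iterations(self):
        params = ModelParams(iteration_cap=100_000, no_change_threshold=20_000)
        sc = Scenario(
            M=24,
            zones=[ActiveZone((3, 11)), ActiveZone((18, 11))],
            spawn=CellSpawnSpec("square", 7, "tile", 1),
            params=params,
            seed=2,
        )
        res = run(sc, params, seed=2)
        assert 0 < res.true_iterations <= res.iterations

    def test_early_stop_reports_early_termination(self):
        params = ModelParams(iteration_cap=500_000, no_change_threshold=100_000)
        sc = Scenario(
            M=24,
            zones=[ActiveZone((3, 11)), ActiveZone((18, 11))],
            spawn=CellSpawnSpec("square", 7, "tile", 1),
            params=params,
            seed=2,
        )
        res = run(sc, params, seed=2, early_stop=500)
        assert res.termination == "early_stop"
        assert res.iterations == 500 and not res.success

    def test_area_constant_during_foraging_trace(self):
        params = ModelParams(iteration_cap=100_000, no_change_threshold=20_000)
        sc = Scenario(
            M=24,
            zones=[ActiveZone((3, 11)), ActiveZone((18, 11))],
            spawn=CellSpawnSpec("square", 7, "tile", 1),
            params=params,
            seed=4,
        )
        res = run(sc, params, seed=4, trace_every=16)
        tr = res.area_trace
        foraging = tr[tr[:, 5] == 0]
        if len(foraging):
            assert np.all(foraging[:, 1] == res.initial_area)
        shrink = tr[tr[:, 5] == 1]
        assert np.all(np.diff(shrink[:, 1]) <= 0)
        assert res.foraging_area_changes == 0
        # every effective shrink event removed exactly one site; the rest
        # were rejected bubbles that undid themselves
        assert res.shrink_actions == res.shrink_decrements + res.shrink_rejected
        assert res.initial_area - res.final_lattice.states.astype(bool).sum() == res.shrink_decrements
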