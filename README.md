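# physarum-steiner

A slime-mold-inspired *explore-and-fuse* heuristic for approximate Steiner
trees on grids, with obstacle avoidance and identification-space topologies
(torus, Klein bottle, RP², sphere).

The package is for people who want approximate rectilinear Steiner networks
— VLSI-style routing, road/cable network sketches, terminals on unusual
surfaces — and for anyone studying biologically inspired computation with a
fully deterministic, testable cellular automaton.

## The algorithm

Terminals are 2×2 *active zones* on an `M×M` grid.  Many virtual *Physarum*
cells are spawned; each cell is a blob of sites labeled cytoplasm (state 1,
interior: may not touch the outside) or membrane (state 2, boundary: must
touch the outside).  The only move is a **bubble event**: a piece of the
outside enters at a stimulated membrane site and percolates through the
organism by swapping with material, which makes cells crawl, fuse, and
retract.

Two phases:

* **Foraging** — the stimulus is global with probability

  ```
  p_random = (N − points_discovered + cells_effective − 1) / (N + cells_initial)
  ```

  and otherwise drawn inside already-discovered zones.  Cells explore in
  parallel, fuse on contact, and anchor to the terminals they find.  When
  `p_random` hits zero (every zone found, one organism holding all of
  them), the run latches into
* **Shrinking** — stimuli come only from the zones and erode material one
  site per effective event; the organism drains onto a thin network
  connecting the terminals.  The run ends when the area has not changed
  for `no_change_threshold` iterations (default 10⁶).

Success means a single connected component holds every zone at normal
termination.  A flood-fill loop check identifies redundant cycles
(enclosed outside pockets); with `--enforce-tree` the shrinkage continues
until the network is loop-free.  See `docs/methods.md` for the full model,
the bubble-walk reconstruction and its safety guarantees.

## Worked example

```python
from physarum_steiner import ActiveZone, Scenario, run
from physarum_steiner.cell_dynamics import CellSpawnSpec, ModelParams

params = ModelParams(iteration_cap=2_000_000, no_change_threshold=1_000_000)
scenario = Scenario(
    M=30,
    zones=[ActiveZone((4, 14)), ActiveZone((24, 14))],  # two terminals, 20 apart
    spawn=CellSpawnSpec("square", 9, "tile", 1),        # size-9 squares spaced 1
    params=params,
    seed=0,
)
result = run(scenario, params, seed=0, enforce_tree=True)
print(result.success, result.solution_length, result.loops_present)
print(result.phase_switch_iteration, result.iterations)
```

prints

```
True 32 False
8 1000622
```

Nine spawned squares fused within 8 iterations (`phase_switch_iteration`),
the shrinking phase eroded the fused organism down to a loop-free, 32-site
network containing both 2×2 terminal pads (a straight 20-site path plus the
pads and a little residual width), and the run terminated after the area
had been stable for one million iterations.

The same from the shell:

```bash
physarum gen --n 10 --m 40 --seed 1 --out scenario.json
physarum run --scenario scenario.json --enforce-tree --out outdir
```

`outdir/` then holds `result.json`, the area/metric trace as CSV and a
final-state PGM snapshot (outside white, cytoplasm mid-gray, membrane dark,
obstacles black, unoccupied zone sites outlined).  Exit code 0 on success,
2 when the run hit its iteration cap.  `physarum experiment` drives full
sweeps (values × grids × trials) with CSV/PNG/JSON summaries.

`examples/` contains ready-made scenarios: a 40-terminal road-network
instance built from a plain-text city coordinate list via
`map_coordinates`, and an obstacle-avoidance instance (a lake and a park
carved out of the search area as an ASCII mask).

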