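# Methods

## The model

`physarum_steiner` approximates rectilinear Steiner trees with a cellular
automaton modeled on the foraging behavior of the slime mold *Physarum
polycephalum*.  A virtual cell is a set of occupied sites on an `M x M`
grid, each labeled **cytoplasm** (state 1) or **membrane/cytoskeleton**
(state 2); empty sites are **outside** (state 0).  Two local rules define
well-formedness: a cytoplasm site may touch no outside site, a membrane site
must touch at least one (von Neumann 4-neighborhood; off-grid and obstacle
sites count as outside).  After any material movement a *repair* pass
re-derives the labels — an organism site becomes membrane exactly when it
has an outside neighbor — which is a single deterministic, idempotent sweep
because the label of a site depends only on the occupancy of its neighbors.

The only dynamical move is a **bubble event**.  A membrane site is chosen as
a *stimulus*; eligibility requires 1 to `s_max` outside neighbors (the cap
excludes nearly detached tips) and at least one enterable outside neighbor.
A piece of the outside (the bubble) is introduced there and percolates
through the organism by swapping places with material, up to `n_swaps`
times.  Conserving events (used while exploring) first displace the
stimulus material outward — into the adjacent free site with the most
organism support, so crevices fill before protrusions sprout — and the
organism's area never changes.  Eroding events (used while shrinking)
delete the stimulus material, so area falls by exactly one per effective
event.

Terminals are 2x2 **active zones**.  The driver runs two latched phases:

* **Foraging.**  Many cells are spawned and stimulated; with probability
  `p_random = (N - points_discovered + cells_effective - 1) / (N + cells_initial)`
  the stimulus is drawn uniformly from all eligible membrane, otherwise from
  eligible membrane inside already-discovered zones (with a global fallback
  when that set is empty).  Cells crawl, meet and fuse; contact makes two
  cells one organism, and per-site origin identifiers track the founders
  through every swap.  When `p_random` reaches zero — all `N` zones
  discovered and held by a single organism — the run switches to shrinking
  and never switches back.
* **Shrinking.**  Stimuli come only from zone sites and erode.  When no
  zone site is a viable stimulus but a zone still holds interior cytoplasm,
  one such piece is removed outright, creating fresh stimulus points.  The
  run terminates when the area has not changed for `no_change_threshold`
  iterations, or gives up at `iteration_cap`.

A run is a *success* when the no-change termination fired and one connected
component holds at least one site of every zone.  `solution_length` counts
the organism sites of zone-holding components (stray blobs are ignored);
`true_iterations` accrues `1/(number of disjoint organism components)` per
iteration, modeling the parallelism of a real swarm as a running harmonic
sum.

## The bubble-walk reconstruction

The percolation mechanics are stated only loosely in the sources this model
descends from, so the walk is this package's own reconstruction; it was the
main open design problem, and the choices below were made so that the
automaton provably cannot destroy what it has built.

* **Interior transport.**  Each swap picks a uniform cytoplasm neighbor;
  membrane may be crossed when no cytoplasm is adjacent, and additionally
  with a small *leak* probability (`walk_leak`, default 0.15) even when
  cytoplasm is available, which lets bubbles pass between cytoplasm pockets
  separated by one-site walls.  At most `membrane_budget` membrane swaps are
  allowed per walk — the cytoskeleton resists transport — which bounds
  travel along thin all-membrane structures.
* **Stable resting (the `stable` policy, default).**  After percolating,
  the bubble is expelled through the membrane: it keeps moving until it
  reaches a position where settling is *safe*, and if it finds none it
  retreats along its trail, undoing swaps, to the last safe position — or
  undoes the whole event.  Safety is a crossing-number (simple-point) test
  on the 8-ring around the position: the occupied arcs containing a
  cardinal neighbor must number at most one, and interior positions (no
  outside cardinal) are never rests, so bubbles cannot leave voids.  Ring
  neighbors in one arc are pairwise 4-adjacent, so a safe removal can never
  disconnect the organism: surfaces retract, dead-end tips prune, width-2
  material thins, and thin paths are immortal.  Zone sites are additionally
  *protected* — a bubble may pass through a terminal pad but never rests on
  one — because long-range walks from one terminal would otherwise prune
  away another terminal's anchor.
* **Frozen-state termination.**  A shrinking event can change the lattice
  only if a safe, unprotected resting place is reachable through organism
  material from a zone.  When none exists and no zone cytoplasm can be
  removed without splitting the organism (checked by trial relabeling), the
  run is provably frozen and is fast-forwarded arithmetically to its
  termination point.  The natural frozen state is a network in which every
  leaf is a terminal pad — exactly the desired result.  (The analysis treats
  the drainability of the current occupancy; a walk could in principle
  manufacture a safe rest by rearranging material mid-flight, which the
  static test does not see.  Runs that would exploit this are terminated as
  frozen; the no-change counter would have ended them anyway unless such
  events occurred more often than once per million iterations.)
* **Loop enforcement.**  Redundant cycles are detected by flood fill:
  a loop is an enclosed outside pocket bordered by a zone-holding component
  (on closed surfaces, an outside component other than the largest).  With
  `enforce_tree`, a frozen run with loops keeps shrinking by removing one
  pocket-border site at a time, accepting only cuts that leave the
  component count unchanged — a closed ring loses a site without anything
  being severed — until the flood fill comes back clean.  If no such cut
  exists the run honestly exhausts its iteration budget.

Alternative policies are available for experimentation: `free` rests
wherever the walk stops (the unguarded rule; it fragments thin networks and
is kept as a comparison baseline), and `cyto_only` never crosses membrane.

## Parameters

| parameter             | default    | meaning                                                        |
|-----------------------|------------|----------------------------------------------------------------|
| `n_swaps`             | 1000       | maximum swaps per bubble walk                                  |
| `s_max`               | 3          | maximum outside neighbors of an eligible stimulus              |
| `iteration_cap`       | 10,000,000 | hard bound on a run                                            |
| `no_change_threshold` | 1,000,000  | quiet iterations before the network is declared final          |
| `walk_policy`         | `stable`   | resting rule of the bubble walk (see above)                    |
| `membrane_budget`     | 1000       | membrane crossings allowed per walk                            |
| `walk_leak`           | 0.15       | probability of crossing membrane when cytoplasm is available   |

`n_swaps`, `s_max` and the two iteration thresholds are the standard
operating point of the model; `membrane_budget` and `walk_leak` belong to
the walk reconstruction.  The leak value is the smallest round probability
at which bubbles reliably migrate between pockets of the fused organism in
desk-scale trials; the budget equal to `n_swaps` makes the cytoskeleton a
soft rather than hard barrier.  Determinism: one xorshift128+ stream drives
every choice in a fixed documented order, so any run is bit-for-bit
reproducible from its seed on any platform.

## Topologies, obstacles, instances

All dynamics run unchanged on five surfaces, realized purely through the
neighbor table of the square's edge identifications: the bounded square,
torus, Klein bottle, real projective plane and sphere (north edge glued to
west, south to east, by transposition).  The identifications are the
standard square identification polygons.  On rp2 the four corners keep
three distinct neighbors — their two glued directions reach the same site —
which is a property of the surface, not an implementation artifact.
Obstacle sites are permanently outside: never a stimulus, never entered,
never a displacement target.

Random instances place `N` disjoint 2x2 zones uniformly; the generator is
deterministic per seed.  `map_coordinates` converts longitude/latitude
point lists to zones by equirectangular bounding-box scaling (collisions
nudge to the nearest free anchor), which is how road-network style demos
are built.  Spawn layouts are the regular `tile` grid (footprints separated
by `spacing`, the classic "size 9 squares spaced one apart") and the
centered `count` lattice.

## What the synthetic instances do and do not show

The generator produces uniformly scattered terminals on empty or
obstacle-masked grids.  This matches the instance model used for the
empirical studies the package reproduces, but real routing problems have
structure the generator lacks: clustered terminals, correlated obstacle
geometry, non-uniform congestion costs.  Passing tests demonstrate the
automaton's invariants (constraint preservation, area accounting,
connectivity retention, termination) and its qualitative behavior at desk
scale; they do not certify approximation quality on structured real-world
instances, and the algorithm is a heuristic with no approximation
guarantee.

## Numerical and procedural choices

* Coordinates are `(x, y)`, 0-based, x eastward, y southward; arrays are
  row-major.  All uniform choices order candidates row-major (or in the
  fixed N, E, S, W direction order) before sampling, for cross-platform
  determinism.
* The no-change counter is armed only in the shrinking phase; foraging
  conserves area by construction, and the global cap bounds stalled
  exploration (a foraging state with no eligible stimulus anywhere is
  likewise provably frozen and fast-forwarded to the cap).
* "In contact with" a zone means occupying one of its four sites;
  adjacency does not count.
* The fallback when the zone-restricted stimulus set is empty during
  foraging is a global draw; a failed draw is a counted no-op iteration.
* Phase transition is latched; disconnection after the switch shows up as
  failure at evaluation, never as a return to foraging.
* Stray components are never garbage-collected; they are merely excluded
  from `solution_length`.
* Desk-scale studies in the test-suite and the acceptance script use
  `iteration_cap = 2x10^6` with the standard `10^6` quiet threshold; the
  problem sizes (`M` 30-60, `N` 2-20) were chosen as the smallest instances
  on which every phase of the algorithm is exercised end to end.

## Known limitations

* Solution quality depends on how much material forages near the final
  tree; tightly packed square spawns fuse instantly and leave distant
  material that freezes into the solution component, inflating
  `solution_length` well above the optimum on large grids.
* Sparse spawns (few small cells, diamonds) can fail to discover all zones
  within the cap: exploration is diffusive and slows sharply once one zone
  anchors most of the stimulus probability.
* The crossing-number safety rule makes width-1 paths immortal during
  walks; only the zone-cytoplasm removal and the loop-enforcement cuts can
  delete unsafely-placed material, so a small amount of redundant width can
  persist.
* On closed surfaces the "main" outside region is taken to be the largest
  outside component, which misclassifies exotic states where a pocket
  outgrows the exterior.
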