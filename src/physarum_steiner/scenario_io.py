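"""Scenario descriptions: generation, JSON round-trip, mapping, rendering.

A scenario is a complete problem instance: grid side ``M``, the terminal
zones (2x2 blocks), the surface topology, an optional obstacle mask, the
cell spawn specification, model parameters and the RNG seed.  Scenarios are
stored as JSON; obstacle masks are referenced by a relative path to an ASCII
('#'/'.') or PGM file.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .cell_dynamics import CellSpawnSpec, ModelParams, RunRNG
from .lattice_topology import (
    ActiveZone,
    Lattice,
    SiteState,
    Topology,
    load_obstacle_mask,
    validate_zones,
)


@dataclass
class Scenario:
    """A full problem instance."""

    M: int
    zones: list[ActiveZone]
    topology: str = "bounded"
    obstacle_path: str | None = None
    obstacle_mask: np.ndarray | None = None
    spawn: CellSpawnSpec = field(default_factory=CellSpawnSpec)
    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        Topology(self.topology, self.M)  # validates kind and M >= 3
        if self.obstacle_mask is not None:
            self.obstacle_mask = np.asarray(self.obstacle_mask, dtype=bool)
            if self.obstacle_mask.shape != (self.M, self.M):
                raise ValueError(
                    f"obstacle mask shape {self.obstacle_mask.shape} does not match M={self.M}"
                )
        validate_zones(self.zones, self.M, self.obstacle_mask)

    @property
    def N(self) -> int:
        return len(self.zones)

    def build_lattice(self) -> Lattice:
        return Lattice(
            Topology(self.topology, self.M),
            obstacle=None if self.obstacle_mask is None else self.obstacle_mask.copy(),
        )

    def search_area(self) -> int:
        """Number of non-obstacle grid sites."""
        if self.obstacle_mask is None:
            return self.M * self.M
        return int(self.M * self.M - np.count_nonzero(self.obstacle_mask))


def generate_random_scenario(
    N: int,
    M: int,
    seed: int,
    topology: str = "bounded",
    spawn: CellSpawnSpec | None = None,
    obstacle_mask: np.ndarray | None = None,
    params: ModelParams | None = None,
    max_rejections: int = 100_000,
) -> Scenario:
    """Uniformly place ``N`` disjoint, obstacle-free 2x2 zones.

    Anchors are drawn uniformly from all in-grid anchor positions and
    rejected on overlap; deterministic per seed.  Raises if ``N`` zones
    cannot be placed within ``max_rejections`` rejected draws.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M < 4:
        raise ValueError("M must be >= 4 to host a 2x2 zone")
    rng = RunRNG(seed)
    taken = np.zeros((M, M), dtype=bool)
    zones: list[ActiveZone] = []
    rejections = 0
    side = M - 1  # anchors lie in [0, M-2]^2
    while len(zones) < N:
        a = rng.below(side * side)
        ax, ay = a % side, a // side
        sites = [(ax, ay), (ax + 1, ay), (ax, ay + 1), (ax + 1, ay + 1)]
        ok = all(
            not taken[y, x] and (obstacle_mask is None or not obstacle_mask[y, x])
            for x, y in sites
        )
        if ok:
            zones.append(ActiveZone((ax, ay)))
            for x, y in sites:
                taken[y, x] = True
        else:
            rejections += 1
            if rejections > max_rejections:
                raise ValueError(
                    f"could not place {N} disjoint zones on a {M}x{M} grid "
                    f"(placed {len(zones)}; {rejections} rejected draws)"
                )
    return Scenario(
        M=M,
        zones=zones,
        topology=topology,
        obstacle_mask=obstacle_mask,
        spawn=spawn or CellSpawnSpec(),
        params=params or ModelParams(),
        seed=seed,
    )


_SCENARIO_FIELDS = {"M", "zones", "topology", "obstacle", "spawn", "params", "seed"}
_SPAWN_FIELDS = {"shape", "size", "layout", "spacing", "count"}
_PARAM_FIELDS = {
    "n_swaps", "s_max", "iteration_cap", "no_change_threshold", "seed",
    "walk_policy", "membrane_budget", "walk_leak",
}


def write_scenario(scenario: Scenario, path: str) -> None:
    doc = {
        "M": scenario.M,
        "zones": [list(z.anchor) for z in scenario.zones],
        "topology": scenario.topology,
        "spawn": {k: v for k, v in asdict(scenario.spawn).items() if v is not None},
        "params": asdict(scenario.params),
        "seed": scenario.seed,
    }
    if scenario.obstacle_path is not None:
        doc["obstacle"] = scenario.obstacle_path
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_scenario(path: str) -> Scenario:
    """Read a scenario JSON file; unknown fields are rejected.

    Only ``M`` and ``zones`` are mandatory; everything else defaults
    (bounded topology, standard parameters, size-9 squares tiled one apart).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError("scenario file must contain a JSON object")
    unknown = set(doc) - _SCENARIO_FIELDS
    if unknown:
        raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
    for key in ("M", "zones"):
        if key not in doc:
            raise ValueError(f"scenario file is missing required field {key!r}")
    M = int(doc["M"])
    zones = []
    for k, anchor in enumerate(doc["zones"]):
        if not (isinstance(anchor, (list, tuple)) and len(anchor) == 2):
            raise ValueError(f"zone {k} must be a 2-element [x, y] anchor, got {anchor!r}")
        z = ActiveZone((int(anchor[0]), int(anchor[1])))
        try:
            z.validate(M)
        except ValueError as exc:
            raise ValueError(f"zone {k}: {exc}") from exc
        zones.append(z)
    spawn_doc = doc.get("spawn", {})
    unknown = set(spawn_doc) - _SPAWN_FIELDS
    if unknown:
        raise ValueError(f"unknown spawn fields: {sorted(unknown)}")
    params_doc = doc.get("params", {})
    unknown = set(params_doc) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown params fields: {sorted(unknown)}")
    obstacle_path = doc.get("obstacle")
    mask = None
    if obstacle_path is not None:
        full = os.path.join(os.path.dirname(os.path.abspath(path)), obstacle_path)
        mask = load_obstacle_mask(full, M)
    return Scenario(
        M=M,
        zones=zones,
        topology=doc.get("topology", "bounded"),
        obstacle_path=obstacle_path,
        obstacle_mask=mask,
        spawn=CellSpawnSpec(**spawn_doc),
        params=ModelParams(**params_doc),
        seed=int(doc.get("seed", 0)),
    )


def map_coordinates(
    points: Sequence[tuple[float, float]],
    M: int,
    margin: int = 1,
    strict: bool = False,
) -> list[ActiveZone]:
    """Map (longitude, latitude) points onto zone anchors.

    Equirectangular scaling of the bounding box onto
    ``[margin, M - 2 - margin]^2``; latitude grows northward, rows grow
    southward, so latitude is flipped.  Anchor collisions are resolved by
    nudging to the nearest free anchor in row-major search order (an error
    instead if ``strict``).
    """
    if not points:
        raise ValueError("need at least one point")
    lo = min(M - 2 - margin, margin)
    hi = M - 2 - margin
    if hi < margin:
        raise ValueError(f"M={M} too small for margin {margin}")
    lons = [p[0] for p in points]
    lats = [p[1] for p in points]
    lon0, lon1 = min(lons), max(lons)
    lat0, lat1 = min(lats), max(lats)
    span = hi - margin

    def scale(v: float, v0: float, v1: float) -> float:
        if v1 == v0:
            return margin + span / 2.0
        return margin + (v - v0) / (v1 - v0) * span

    taken: set[tuple[int, int]] = set()
    zones: list[ActiveZone] = []
    for lon, lat in points:
        ax = int(round(scale(lon, lon0, lon1)))
        ay = int(round(scale(lat0 + lat1 - lat, lat0, lat1)))  # flip latitude
        anchor = _nearest_free_anchor((ax, ay), taken, M)
        if anchor is None or (strict and anchor != (ax, ay)):
            raise ValueError(f"cannot place a disjoint zone for point {(lon, lat)} on M={M}")
        # mark the 2x2 block and its overlapping anchors as taken
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                taken.add((anchor[0] + dx, anchor[1] + dy))
        zones.append(ActiveZone(anchor))
    return zones


def _nearest_free_anchor(
    want: tuple[int, int], taken: set[tuple[int, int]], M: int
) -> tuple[int, int] | None:
    wx, wy = want
    best = None
    best_d = None
    for ay in range(M - 1):
        for ax in range(M - 1):
            if (ax, ay) in taken:
                continue
            d = (ax - wx) ** 2 + (ay - wy) ** 2
            if best_d is None or d < best_d:
                best, best_d = (ax, ay), d
    return best


# rendering --------------------------------------------------------------

PALETTE = {
    "outside": 255,
    "cytoplasm": 160,
    "membrane": 64,
    "obstacle": 0,
    "zone_outline": 208,
}


def render_array(lattice: Lattice, zones: Sequence[ActiveZone] = (), scale: int = 1) -> np.ndarray:
    """Grayscale raster of the lattice with the fixed palette.

    OUTSIDE white, CYTOPLASM mid-gray, MEMBRANE dark, obstacles black;
    unoccupied zone sites are outlined in light gray.
    """
    img = np.full((lattice.M, lattice.M), PALETTE["outside"], dtype=np.uint8)
    img[lattice.states == SiteState.CYTOPLASM] = PALETTE["cytoplasm"]
    img[lattice.states == SiteState.MEMBRANE] = PALETTE["membrane"]
    for z in zones:
        for x, y in z.sites:
            if lattice.states[y, x] == SiteState.OUTSIDE:
                img[y, x] = PALETTE["zone_outline"]
    img[lattice.obstacle] = PALETTE["obstacle"]
    if scale > 1:
        img = np.kron(img, np.ones((scale, scale), dtype=np.uint8))
    return img


def render_raster(
    lattice: Lattice, zones: Sequence[ActiveZone], path: str, scale: int = 1
) -> None:
    """Write a snapshot image; ``.pgm`` gets ASCII (P2) PGM, otherwise PIL
    infers the format from the extension."""
    img = render_array(lattice, zones, scale)
    if path.endswith(".pgm"):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n255\n")
            for row in img:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
    else:
        from PIL import Image

        Image.fromarray(img, mode="L").save(path)
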