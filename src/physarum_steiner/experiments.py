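"""Empirical studies: N-sweeps, M-sweeps, normalized sweeps, cell studies.

Each sweep value gets ``grids_per_value`` randomly generated instances and
``trials_per_grid`` independent runs per instance; every trial is recorded
(failures flagged, never dropped -- excluding them is a reporting option of
:func:`summarize`).  All seeds derive deterministically from the base seed,
so whole sweeps are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .cell_dynamics import CellSpawnSpec, ModelParams
from .scenario_io import Scenario, generate_random_scenario
from .steiner_driver import run

SweepKind = Literal["N_sweep", "M_sweep", "normalized", "cells"]

TRIAL_COLUMNS = [
    "sweep_value", "grid_index", "trial_index", "variant", "success",
    "termination", "iterations", "true_iterations", "solution_length",
    "initial_cytoplasm", "search_area", "cytoplasm_percentage",
]


def normalized_M(N: int, rounding: str = "half_up") -> int:
    """Grid side that keeps N at two percent of the search area M*M.

    ``M = round(sqrt(N / 0.02))`` with round-half-up by default (``floor``
    and ``ceil`` are exposed for sensitivity checks).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    v = float(np.sqrt(N / 0.02))
    if rounding == "half_up":
        return int(np.floor(v + 0.5))
    if rounding == "floor":
        return int(np.floor(v))
    if rounding == "ceil":
        return int(np.ceil(v))
    raise ValueError(f"unknown rounding {rounding!r}")


def cytoplasm_percentage(search_area: int, initial_cytoplasm: int) -> float:
    """Search area expressed as a percentage of the spawned cytoplasm."""
    if initial_cytoplasm <= 0:
        raise ValueError("initial cytoplasm must be positive")
    return 100.0 * search_area / initial_cytoplasm


@dataclass(frozen=True)
class ExperimentConfig:
    """A sweep description.

    ``values`` is the sweep grid (N values, M values, or cell counts
    depending on ``kind``).  For ``cells`` sweeps, ``spawn_variants`` maps a
    variant name to a spawn spec; every variant runs on the same instances.
    """

    kind: SweepKind
    values: tuple[int, ...]
    grids_per_value: int = 10
    trials_per_grid: int = 10
    N: int = 100  # fixed N for M_sweep / cells sweeps
    M: int = 100  # fixed M for N_sweep / cells sweeps
    params: ModelParams = field(default_factory=ModelParams)
    spawn: CellSpawnSpec = field(default_factory=CellSpawnSpec)
    spawn_variants: tuple[tuple[str, CellSpawnSpec], ...] = ()
    topology: str = "bounded"
    base_seed: int = 0

    @property
    def total_trials(self) -> int:
        nv = max(len(self.spawn_variants), 1)
        return len(self.values) * self.grids_per_value * self.trials_per_grid * nv


def scale_config(config: ExperimentConfig, scale: float) -> ExperimentConfig:
    """Desk-scale variant: shrink values, fixed sizes and caps proportionally."""
    if scale <= 0 or scale > 1:
        raise ValueError("scale must lie in (0, 1]")
    if scale == 1.0:
        return config
    shrink = lambda v: max(int(round(v * scale)), 4)
    params = replace(
        config.params,
        iteration_cap=max(int(config.params.iteration_cap * scale), 1),
        no_change_threshold=max(int(config.params.no_change_threshold * scale), 1),
    )
    return replace(
        config,
        values=tuple(max(int(round(v * scale)), 1) for v in config.values),
        N=max(int(round(config.N * scale)), 1),
        M=shrink(config.M),
        params=params,
    )


def _trial_seed(base_seed: int, value_idx: int, grid_idx: int, trial_idx: int, variant_idx: int) -> int:
    # distinct, deterministic, and well below 2**31
    return (
        (base_seed * 1_000_003 + value_idx * 10_007 + grid_idx * 101
         + trial_idx * 13 + variant_idx * 7) % 2_000_000_011
    )


def _scenario_for(config: ExperimentConfig, value: int, value_idx: int, grid_idx: int) -> Scenario:
    gen_seed = _trial_seed(config.base_seed, value_idx, grid_idx, 0, 0) + 1
    if config.kind == "N_sweep":
        N, M = value, config.M
    elif config.kind == "M_sweep":
        N, M = config.N, value
    elif config.kind == "normalized":
        N, M = value, normalized_M(value)
    else:  # cells: value is the cell count; instance size fixed
        N, M = config.N, config.M
    return generate_random_scenario(
        N, M, seed=gen_seed, topology=config.topology,
        spawn=config.spawn, params=config.params,
    )


def run_sweep(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Execute the sweep; one row per trial, failures flagged not dropped."""
    rows = []
    variants = list(config.spawn_variants) or [("default", config.spawn)]
    for vi, value in enumerate(config.values):
        for gi in range(config.grids_per_value):
            scenario = _scenario_for(config, value, vi, gi)
            for name_idx, (vname, vspawn) in enumerate(variants):
                if config.kind == "cells":
                    vspawn = replace(vspawn, layout="count", count=value)
                scen = Scenario(
                    M=scenario.M, zones=list(scenario.zones), topology=scenario.topology,
                    obstacle_mask=scenario.obstacle_mask, spawn=vspawn,
                    params=config.params, seed=scenario.seed,
                )
                for ti in range(config.trials_per_grid):
                    seed = _trial_seed(config.base_seed, vi, gi, ti + 1, name_idx)
                    try:
                        res = run(scen, config.params, seed=seed)
                        row = dict(
                            sweep_value=value, grid_index=gi, trial_index=ti,
                            variant=vname, success=res.success,
                            termination=res.termination,
                            iterations=res.iterations,
                            true_iterations=res.true_iterations,
                            solution_length=res.solution_length,
                            initial_cytoplasm=res.initial_area,
                            search_area=scen.search_area(),
                            cytoplasm_percentage=cytoplasm_percentage(
                                scen.search_area(), res.initial_area),
                        )
                    except Exception as exc:  # recorded as failure, never aborts the sweep
                        row = dict(
                            sweep_value=value, grid_index=gi, trial_index=ti,
                            variant=vname, success=False, termination=f"error: {exc}",
                            iterations=0, true_iterations=0.0, solution_length=0,
                            initial_cytoplasm=0, search_area=scen.search_area(),
                            cytoplasm_percentage=float("nan"),
                        )
                    rows.append(row)
                    if progress:
                        print(f"value={value} grid={gi} trial={ti} variant={vname}: {row['termination']}")
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def summarize(table: pd.DataFrame, exclude_failures: bool = True) -> pd.DataFrame:
    """Per-(value, variant) aggregates.

    Success is always reported as a proportion over all trials; iteration
    and length statistics exclude failed trials by default, mirroring how
    the sweep figures are usually drawn.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    out = []
    for (value, variant), g in table.groupby(["sweep_value", "variant"], sort=True):
        ok = g[g["success"]] if exclude_failures else g
        stat = lambda col, f: float(f(ok[col])) if len(ok) else float("nan")
        out.append({
            "sweep_value": value,
            "variant": variant,
            "n_trials": len(g),
            "success_proportion": float(g["success"].mean()),
            "mean_iterations": stat("iterations", np.mean),
            "std_iterations": stat("iterations", lambda s: np.std(s, ddof=0)),
            "mean_true_iterations": stat("true_iterations", np.mean),
            "mean_solution_length": stat("solution_length", np.mean),
            "std_solution_length": stat("solution_length", lambda s: np.std(s, ddof=0)),
            "mean_cytoplasm_percentage": float(g["cytoplasm_percentage"].mean()),
        })
    return pd.DataFrame(out)


def plot_summary(summary: pd.DataFrame, metric: str, path: str, ylabel: str | None = None) -> None:
    """Bar chart of a summary metric per sweep value with std error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for variant, g in summary.groupby("variant"):
        err_col = metric.replace("mean_", "std_")
        err = g[err_col] if err_col in g.columns else None
        ax.bar(
            [str(v) for v in g["sweep_value"]], g[metric],
            yerr=None if err is None else err, capsize=3, label=str(variant), alpha=0.7,
        )
    ax.set_xlabel("sweep value")
    ax.set_ylabel(ylabel or metric)
    if summary["variant"].nunique() > 1:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
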