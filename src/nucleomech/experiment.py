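"""Monte-Carlo sweep over the substrate-stiffness grid.

One replicate = one random filament-network realisation solved on one
substrate stiffness; each replicate is a statistical data point.  The sweep
runs `replicates` networks per stiffness on the grid (default 0.1, 0.7, 5,
14 and 40 kPa), collects the nuclear readouts in a tidy table and summarises
them per stiffness.

The default per-stiffness fiber statistics are synthetic placeholders that
encode the measured qualitative behaviour — filament count and alignment
increase with substrate stiffness — by linear interpolation from
(10, 5, 15) fibers / S = 0.2 at 0.1 kPa to (40, 20, 60) fibers / S = 0.8 at
40 kPa.  Override them (configuration file or code) when measured per-class
counts and alignment are available.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import NucleoMechError
from .fem import assemble, solve_static
from .fibers import FiberClass, FiberClassSpec, generate_network
from .geometry import CellGeometry, Mesh, build_cell_mesh
from .materials import MaterialParams
from .readouts import nuclear_metrics
from .substrate import SubstrateParams, effective_stiffness

logger = logging.getLogger(__name__)

DEFAULT_STIFFNESS_GRID_KPA = (0.1, 0.7, 5.0, 14.0, 40.0)

_CLASS_COLUMNS = {
    FiberClass.NUCLEUS_MEMBRANE_BASAL: "nucleus_membrane",
    FiberClass.OVER_NUCLEUS_BASAL: "over_nucleus",
    FiberClass.VENTRAL_NETWORK: "ventral",
}


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for the per-replicate solve."""

    resolution: float = 2.2  # coarse target edge length, µm
    regularization: float = 1e-3  # basal-rim spring factor, × k_eff
    tie_tolerance: float | None = None  # defaults to resolution
    force_mode: str = "sum_magnitudes"  # or "vector_sum"


def default_fiber_table(
    grid_kpa=DEFAULT_STIFFNESS_GRID_KPA,
    soft_counts=(10, 5, 15),
    stiff_counts=(40, 20, 60),
    soft_S: float = 0.2,
    stiff_S: float = 0.8,
    length_scale: float = 3.0,
) -> dict[float, list[FiberClassSpec]]:
    """Per-stiffness fiber specs, linear in stiffness between the endpoints."""
    lo, hi = min(grid_kpa), max(grid_kpa)
    table = {}
    for E in grid_kpa:
        frac = (E - lo) / (hi - lo) if hi > lo else 0.0
        counts = [round(a + frac * (b - a)) for a, b in zip(soft_counts, stiff_counts)]
        S = soft_S + frac * (stiff_S - soft_S)
        table[float(E)] = [
            FiberClassSpec(fc, counts[i], S, length_scale) for i, fc in enumerate(FiberClass)
        ]
    return table


@dataclass
class SweepConfig:
    """Complete description of one in-silico experiment."""

    stiffness_grid_kpa: tuple = DEFAULT_STIFFNESS_GRID_KPA
    replicates: int = 20
    base_seed: int = 0
    geometry: CellGeometry = field(default_factory=CellGeometry)
    materials: MaterialParams = field(default_factory=MaterialParams)
    substrate: SubstrateParams = field(default_factory=SubstrateParams)  # E_s set per point
    fiber_table: dict[float, list[FiberClassSpec]] | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        grid = tuple(float(g) for g in self.stiffness_grid_kpa)
        if any(g <= 0 for g in grid) or any(np.diff(grid) <= 0):
            raise ValueError("stiffness grid must be positive and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "stiffness_grid_kpa", grid)
        if self.fiber_table is None:
            self.fiber_table = default_fiber_table(grid)

    def specs_for(self, stiffness_kpa: float) -> list[FiberClassSpec]:
        key = float(stiffness_kpa)
        if key not in self.fiber_table:
            raise KeyError(f"no fiber statistics for stiffness {stiffness_kpa} kPa")
        return self.fiber_table[key]

    def substrate_for(self, stiffness_kpa: float) -> SubstrateParams:
        return replace(self.substrate, E_s=1000.0 * float(stiffness_kpa))


@dataclass
class SweepResult:
    """Tidy per-replicate table plus per-stiffness summary statistics."""

    rows: pd.DataFrame
    config: SweepConfig

    @property
    def summary(self) -> pd.DataFrame:
        ok = self.rows[self.rows["status"] == "ok"]
        metric_cols = [
            "k_eff", "total_force", "strain_x", "strain_y", "strain_z",
            "stress_x", "stress_y", "stress_z", "projected_area", "area_change",
        ]
        return ok.groupby("stiffness_kpa")[metric_cols].agg(["mean", "std"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _mesh_for(config: SweepConfig, cache: dict | None) -> Mesh:
    if cache is None:
        cache = {}
    key = (config.geometry, config.solver.resolution)
    if key not in cache:
        cache[key] = build_cell_mesh(config.geometry, config.solver.resolution)
    return cache[key]


def replicate_seed(base_seed: int, replicate_index: int) -> int:
    """Per-replicate network seed: base_seed + replicate index."""
    return int(base_seed) + int(replicate_index)


def run_replicate(
    config: SweepConfig,
    stiffness_kpa: float,
    replicate_index: int,
    _mesh_cache: dict | None = None,
) -> dict:
    """One Monte-Carlo replicate; returns a flat result row.

    Deterministic for a fixed (config, stiffness, index).  Solver failures
    are captured in the row (status/error) rather than raised, so a sweep
    never aborts on one bad replicate.
    """
    seed = replicate_seed(config.base_seed, replicate_index)
    specs = config.specs_for(stiffness_kpa)
    k_eff = effective_stiffness(config.substrate_for(stiffness_kpa))
    row = {
        "stiffness_kpa": float(stiffness_kpa),
        "replicate": int(replicate_index),
        "seed": seed,
        "k_eff": k_eff,
        "status": "ok",
        "error": "",
    }
    for s in specs:
        row[f"count_{_CLASS_COLUMNS[s.fiber_class]}"] = s.count
        row[f"target_S_{_CLASS_COLUMNS[s.fiber_class]}"] = s.target_S
    try:
        mesh = _mesh_for(config, _mesh_cache)
        network = generate_network(config.geometry, specs, config.materials.fiber, seed)
        for fc, col in _CLASS_COLUMNS.items():
            row[f"realized_S_{col}"] = network.realized_order(fc)
        system = assemble(
            mesh,
            config.materials,
            network,
            k_eff,
            regularization=config.solver.regularization,
            tie_tolerance=config.solver.tie_tolerance,
        )
        solution = solve_static(system)
        metrics = nuclear_metrics(solution, force_mode=config.solver.force_mode)
        row.update(metrics.as_dict())
        row["n_slack"] = solution.n_slack
        row["residual"] = solution.residual
    except (NucleoMechError, np.linalg.LinAlgError) as exc:
        logger.warning("replicate failed (E=%s kPa, idx=%d): %s", stiffness_kpa, replicate_index, exc)
        row["status"] = "failed"
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


def run_sweep(config: SweepConfig) -> SweepResult:
    """Run the full stiffness × replicate grid and collect the tidy table."""
    cache: dict = {}
    rows = []
    for stiffness in config.stiffness_grid_kpa:
        for idx in range(config.replicates):
            t0 = time.perf_counter()
            row = run_replicate(config, stiffness, idx, _mesh_cache=cache)
            rows.append(row)
            logger.info(
                "E=%.3g kPa replicate %d: %s (%.2fs)",
                stiffness, idx, row["status"], time.perf_counter() - t0,
            )
    return SweepResult(rows=pd.DataFrame(rows), config=config)
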