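"""YAML run-configuration loading/saving.

A configuration file has up to six blocks — ``geometry``, ``materials``,
``substrate``, ``fibers``, ``solver``, ``sweep`` — all optional; omitted
fields fall back to the package defaults.  Example::

    geometry: {spread_area: 1200, aspect_ratio: 1.5, height: 13,
               nucleus_radius: 5.5, basal_gap: 0.5}
    substrate: {k_a: 1.0e5, nu_s: 0.3, d: 2.0}
    solver:    {resolution: 2.2, regularization: 1.0e-3}
    sweep:     {stiffness_grid_kpa: [0.1, 0.7, 5, 14, 40], replicates: 20,
                base_seed: 0}
    fibers:
      endpoints:   # linear interpolation across the grid
        soft_counts: [10, 5, 15]
        stiff_counts: [40, 20, 60]
        soft_S: 0.2
        stiff_S: 0.8
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment import SolverSettings, SweepConfig, default_fiber_table
from .fibers import FiberClass, FiberClassSpec
from .geometry import CellGeometry
from .materials import ElasticMaterial, FiberMaterial, MaterialParams, MembraneMaterial
from .substrate import SubstrateParams


def load_config(path: str | Path) -> SweepConfig:
    """Build a :class:`SweepConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def _numeric(block: dict) -> dict:
    """Coerce scalar values to float (YAML 1.1 reads '2.0e5' as a string)."""
    out = {}
    for key, value in block.items():
        if isinstance(value, str):
            try:
                value = float(value)
            except ValueError:
                pass
        out[key] = value
    return out


def config_from_dict(raw: dict) -> SweepConfig:
    geometry = CellGeometry(**_numeric(raw.get("geometry", {})))
    materials = _materials_from_dict(raw.get("materials", {}))
    sub = _numeric(raw.get("substrate", {}))
    sub.pop("stiffness_grid_kpa", None)
    substrate = SubstrateParams(**({"E_s": 1.0} | sub))
    solver = SolverSettings(**_numeric(raw.get("solver", {})))
    sweep = raw.get("sweep", {})
    grid = tuple(sweep.get("stiffness_grid_kpa", (0.1, 0.7, 5.0, 14.0, 40.0)))
    fiber_table = _fiber_table_from_dict(raw.get("fibers", {}), grid)
    return SweepConfig(
        stiffness_grid_kpa=grid,
        replicates=int(sweep.get("replicates", 20)),
        base_seed=int(sweep.get("base_seed", 0)),
        geometry=geometry,
        materials=materials,
        substrate=substrate,
        fiber_table=fiber_table,
        solver=solver,
    )


def _materials_from_dict(raw: dict) -> MaterialParams:
    kw = {}
    if "membrane" in raw:
        kw["membrane"] = MembraneMaterial(**_numeric(raw["membrane"]))
    if "cytoplasm" in raw:
        kw["cytoplasm"] = ElasticMaterial(**_numeric(raw["cytoplasm"]))
    if "nucleus" in raw:
        kw["nucleus"] = ElasticMaterial(**_numeric(raw["nucleus"]))
    if "fiber" in raw:
        kw["fiber"] = FiberMaterial(**_numeric(raw["fiber"]))
    return MaterialParams(**kw)


def _fiber_table_from_dict(raw: dict, grid) -> dict | None:
    if not raw:
        return None
    if "table" in raw:
        table = {}
        for stiffness, classes in raw["table"].items():
            table[float(stiffness)] = [
                FiberClassSpec(
                    fiber_class=FiberClass(entry["fiber_class"]),
                    count=int(entry["count"]),
                    target_S=float(entry["target_S"]),
                    length_scale=float(entry.get("length_scale", 3.0)),
                )
                for entry in classes
            ]
        return table
    if "endpoints" in raw:
        ep = raw["endpoints"]
        return default_fiber_table(
            grid,
            soft_counts=tuple(ep.get("soft_counts", (10, 5, 15))),
            stiff_counts=tuple(ep.get("stiff_counts", (40, 20, 60))),
            soft_S=float(ep.get("soft_S", 0.2)),
            stiff_S=float(ep.get("stiff_S", 0.8)),
            length_scale=float(ep.get("length_scale", 3.0)),
        )
    raise ValueError("fibers block must contain 'table' or 'endpoints'")
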