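"""Nuclear deformation readouts from a solved cell model.

Computes, for one static solution: the total force the filament network
exerts on the nucleus (pN), volume-averaged nuclear normal strains and
stresses along x/y/z, and the projected (basal-plane) nuclear area used as
the deformation indicator.

The "total force" is the sum of the magnitudes of the per-attachment forces
(a near-symmetric filament arrangement would make the plain vector sum
cancel to ~0 and be uninformative); the vector-sum convention remains
available via ``mode="vector_sum"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .fem import Solution
from .geometry import NUCLEUS, Mesh


@dataclass(frozen=True)
class NuclearMetrics:
    """Scalar deformation readouts for one solved replicate."""

    total_force: float  # pN
    strain_x: float
    strain_y: float
    strain_z: float
    stress_x: float  # Pa
    stress_y: float
    stress_z: float
    projected_area: float  # µm²
    area_change: float  # µm² (deformed - undeformed)

    def as_dict(self) -> dict:
        return asdict(self)


def total_nuclear_force(solution: Solution, mode: str = "sum_magnitudes") -> float:
    """Total force transmitted by fibers to nucleus-surface nodes, pN.

    For each fiber vertex tied to a nucleus-surface node the force the fiber
    exerts there is the sum of the adjacent segment tensions along their
    (undeformed) axes.  ``mode`` selects the reduction: sum of per-attachment
    magnitudes (default) or magnitude of the vector sum.
    """
    if mode not in ("sum_magnitudes", "vector_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    system = solution.system
    seg = system.segments
    nuc_nodes = set(system.mesh.nucleus_surface_nodes.tolist())
    if len(seg) == 0 or not nuc_nodes:
        warnings.warn("network has no nucleus-tied vertices; total force is 0")
        return 0.0
    # per-node force accumulation: tension pulls the node toward the far end
    forces: dict[int, np.ndarray] = {}
    for s in range(len(seg)):
        i, j = int(seg.node_i[s]), int(seg.node_j[s])
        fvec = solution.segment_tension[s] * seg.direction[s]
        if i in nuc_nodes:
            forces.setdefault(i, np.zeros(3))
            forces[i] += fvec  # pulled toward j
        if j in nuc_nodes:
            forces.setdefault(j, np.zeros(3))
            forces[j] -= fvec  # pulled toward i
    if not forces:
        warnings.warn("network has no nucleus-tied vertices; total force is 0")
        return 0.0
    vectors = np.array(list(forces.values()))
    if mode == "vector_sum":
        return float(np.linalg.norm(vectors.sum(axis=0)))
    return float(np.linalg.norm(vectors, axis=1).sum())


def mean_nuclear_strain_stress(
    solution: Solution, mesh: Mesh | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted mean normal strain and stress over nucleus elements.

    Returns ``(strain_xyz, stress_xyz)``; constant-strain element values are
    averaged with element-volume weights, no nodal smoothing.
    """
    mesh = mesh or solution.system.mesh
    m = mesh.tet_part == NUCLEUS
    if not m.any():
        raise ValueError("mesh contains no nucleus elements")
    w = mesh.tet_volumes[m]
    w = w / w.sum()
    strain = (solution.tet_strain[m, :3] * w[:, None]).sum(axis=0)
    stress = (solution.tet_stress[m, :3] * w[:, None]).sum(axis=0)
    return strain, stress


def projected_nuclear_area(solution: Solution | None, mesh: Mesh) -> float:
    """Area of the deformed nucleus surface projected on the basal plane, µm².

    Convex hull of the (displaced) nucleus-surface nodes in (x, y); pass
    ``solution=None`` for the undeformed area.
    """
    idx = mesh.nucleus_surface_nodes
    if len(idx) == 0:
        raise ValueError("mesh has no nucleus surface nodes")
    pts = mesh.nodes[idx, :2].copy()
    if solution is not None:
        pts += solution.displacements[idx, :2]
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) nucleus projection") from exc
    return float(hull.volume)  # 2D hull "volume" is the area


def nuclear_metrics(solution: Solution, force_mode: str = "sum_magnitudes") -> NuclearMetrics:
    """All nuclear deformation readouts for one solution."""
    mesh = solution.system.mesh
    strain, stress = mean_nuclear_strain_stress(solution, mesh)
    area = projected_nuclear_area(solution, mesh)
    area0 = projected_nuclear_area(None, mesh)
    return NuclearMetrics(
        total_force=total_nuclear_force(solution, mode=force_mode),
        strain_x=float(strain[0]),
        strain_y=float(strain[1]),
        strain_z=float(strain[2]),
        stress_x=float(stress[0]),
        stress_y=float(stress[1]),
        stress_z=float(stress[2]),
        projected_area=area,
        area_change=area - area0,
    )
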