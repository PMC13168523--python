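"""Stochastic actin-filament network generation and nematic order statistics.

Filaments are grouped into three classes:

``nucleus_membrane_basal``
    straight trusses from the nucleus equatorial band to focal-adhesion
    anchors near the basal cell perimeter;
``over_nucleus_basal``
    polyline trusses running anchor-to-anchor across the cell whose interior
    vertices lie on the apical nucleus surface (the "actin cap" — their
    tension presses the nucleus down);
``ventral_network``
    a planar random fiber network on the basal plane beneath the nucleus.

In-plane orientations follow a nematic (doubled-angle von Mises)
distribution about the cell's major axis (y), calibrated so that the
expected nematic order parameter S matches a prescribed target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull, Delaunay
from scipy.special import i0e, i1e

from .errors import RoutingError
from .geometry import CellGeometry
from .materials import FiberMaterial

#: mean orientation of every nematic distribution: the major (y) axis
MAJOR_AXIS_ANGLE = np.pi / 2


class FiberClass(str, Enum):
    NUCLEUS_MEMBRANE_BASAL = "nucleus_membrane_basal"
    OVER_NUCLEUS_BASAL = "over_nucleus_basal"
    VENTRAL_NETWORK = "ventral_network"


@dataclass(frozen=True)
class FiberClassSpec:
    """Target statistics for one filament class.

    ``count`` filaments are generated with orientations whose expected
    nematic order is ``target_S``.  ``length_scale`` (µm) sets the node
    density of the ventral network and is ignored for the other classes.
    """

    fiber_class: FiberClass
    count: int
    target_S: float
    length_scale: float = 3.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not 0.0 <= self.target_S <= 1.0:
            raise ValueError("target_S must be in [0, 1]")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be > 0")


@dataclass
class Fiber:
    """One filament: a polyline with class label, section and pre-strain."""

    vertices: np.ndarray  # (k, 3) µm
    fiber_class: FiberClass
    cross_section_radius: float
    pre_strain: float
    anchored: tuple[bool, bool]  # (first vertex, last vertex) substrate-anchored

    @property
    def azimuth(self) -> float:
        """In-plane end-to-end orientation, radians in [0, π)."""
        d = self.vertices[-1] - self.vertices[0]
        return float(np.arctan2(d[1], d[0]) % np.pi)


@dataclass
class FiberNetwork:
    """A generated filament network plus its provenance."""

    fibers: list[Fiber]
    seed: int | None = None
    specs: list[FiberClassSpec] = field(default_factory=list)

    def by_class(self, fiber_class: FiberClass) -> list[Fiber]:
        return [f for f in self.fibers if f.fiber_class == fiber_class]

    def class_counts(self) -> dict[str, int]:
        return {fc.value: len(self.by_class(fc)) for fc in FiberClass}

    def class_azimuths(self, fiber_class: FiberClass) -> np.ndarray:
        return np.array([f.azimuth for f in self.by_class(fiber_class)])

    def realized_order(self, fiber_class: FiberClass) -> float:
        az = self.class_azimuths(fiber_class)
        return nematic_order(az) if len(az) else float("nan")

    @property
    def anchor_points(self) -> np.ndarray:
        """Coordinates of all substrate-anchored fiber endpoints, (n, 3)."""
        pts = []
        for f in self.fibers:
            if f.anchored[0]:
                pts.append(f.vertices[0])
            if f.anchored[1]:
                pts.append(f.vertices[-1])
        return np.array(pts) if pts else np.empty((0, 3))

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "fibers": [
                {
                    "class": f.fiber_class.value,
                    "vertices": f.vertices.tolist(),
                    "cross_section_radius": f.cross_section_radius,
                    "pre_strain": f.pre_strain,
                    "anchored": list(f.anchored),
                }
                for f in self.fibers
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FiberNetwork":
        text = str(text_or_path)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:  # raw JSON text, not a path
            pass
        payload = json.loads(text)
        fibers = [
            Fiber(
                vertices=np.asarray(d["vertices"], dtype=float),
                fiber_class=FiberClass(d["class"]),
                cross_section_radius=d["cross_section_radius"],
                pre_strain=d["pre_strain"],
                anchored=tuple(bool(a) for a in d["anchored"]),
            )
            for d in payload["fibers"]
        ]
        return cls(fibers=fibers, seed=payload.get("seed"))


# ---------------------------------------------------------------------------
# nematic order statistics
# ---------------------------------------------------------------------------


def nematic_order(angles, weights=None) -> float:
    """Nematic order parameter S of a set of (axial) orientations.

    S = |Σ w·exp(2iθ)| / Σ w, in [0, 1]: 0 for disordered, 1 for perfectly
    aligned orientations.  Invariant under θ → θ + π and global rotations.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("nematic_order requires at least one angle")
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one angle must have positive weight")
    resultant = np.sum(weights * np.exp(2j * angles)) / total
    return float(np.abs(resultant))


def expected_order(concentration: float) -> float:
    """Expected S when doubled angles follow a von Mises(κ): I₁(κ)/I₀(κ)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return float(i1e(concentration) / i0e(concentration))


def calibrate_concentration(target_S: float) -> float:
    """Von Mises concentration κ whose expected nematic order is ``target_S``.

    Solves I₁(κ)/I₀(κ) = S.  S = 0 maps to κ = 0 (uniform orientations);
    S = 1 has no finite κ and raises (use deterministic identical angles).
    """
    if not 0.0 <= target_S < 1.0:
        if target_S == 1.0:
            raise ValueError(
                "target_S = 1 is degenerate: use deterministic identical angles"
            )
        raise ValueError(f"target_S must be in [0, 1), got {target_S}")
    if target_S == 0.0:
        return 0.0
    hi = 1.0
    while expected_order(hi) < target_S:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for S < 1
            raise RuntimeError("calibration did not bracket")
    return float(brentq(lambda k: expected_order(k) - target_S, 0.0, hi, xtol=1e-12))


def sample_orientations(
    n: int, concentration: float, seed, mean: float = MAJOR_AXIS_ANGLE
) -> np.ndarray:
    """Sample ``n`` axial orientations θ ∈ [0, π) with nematic concentration κ.

    Doubled angles 2θ are von Mises distributed about 2·mean; κ = 0 gives
    uniform orientations.  ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if concentration == 0.0:
        doubled = rng.uniform(-np.pi, np.pi, size=n)
    else:
        doubled = rng.vonmises(0.0, concentration, size=n)
    return (mean + doubled / 2.0) % np.pi


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def generate_network(
    geometry: CellGeometry,
    specs: list[FiberClassSpec],
    material: FiberMaterial | None = None,
    seed: int = 0,
) -> FiberNetwork:
    """Generate one random filament network realisation.

    Per-class fiber counts are met exactly; in-plane azimuths are drawn from
    the class's calibrated nematic distribution about the major (y) axis.
    Deterministic for a fixed (geometry, specs, seed).
    """
    if material is None:
        material = FiberMaterial()
    spec_map = {s.fiber_class: s for s in specs}
    rngs = {
        fc: np.random.default_rng(np.random.SeedSequence([int(seed), 7, i]))
        for i, fc in enumerate(FiberClass)
    }
    fibers: list[Fiber] = []
    builders = {
        FiberClass.NUCLEUS_MEMBRANE_BASAL: _build_nucleus_membrane,
        FiberClass.OVER_NUCLEUS_BASAL: _build_over_nucleus,
        FiberClass.VENTRAL_NETWORK: _build_ventral_network,
    }
    for fc in FiberClass:
        spec = spec_map.get(fc)
        if spec is None or spec.count == 0:
            continue
        fibers.extend(builders[fc](geometry, spec, material, rngs[fc]))
    network = FiberNetwork(fibers=fibers, seed=int(seed), specs=list(specs))
    _check_containment(geometry, network)
    return network


def _class_angles(spec: FiberClassSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.target_S >= 1.0:
        return np.full(n, MAJOR_AXIS_ANGLE)
    kappa = calibrate_concentration(spec.target_S)
    return sample_orientations(n, kappa, rng)


def _build_nucleus_membrane(
    geometry: CellGeometry, spec: FiberClassSpec, material: FiberMaterial, rng
) -> list[Fiber]:
    R = geometry.nucleus_radius
    c = geometry.nucleus_center
    theta = _class_angles(spec, spec.count, rng)
    # orientation is axial: pick a direction along the axis at random
    az = np.where(rng.random(spec.count) < 0.5, theta, theta + np.pi)
    rho_rim = geometry.boundary_radius(az)
    # the whole anchor annulus (outer 20% of the footprint) must clear the nucleus
    if np.any(0.8 * rho_rim <= R + 0.2):
        raise RoutingError("nucleus_membrane_basal: basal footprint too small for nucleus")
    z = c[2] + rng.uniform(-R / 3.0, R / 3.0, spec.count)  # equatorial band
    r_band = np.sqrt(R**2 - (z - c[2]) ** 2)
    start = np.column_stack([r_band * np.cos(az), r_band * np.sin(az), z])
    rho = rho_rim * (0.8 + 0.2 * rng.random(spec.count))  # outer 20% annulus
    end = np.column_stack([rho * np.cos(az), rho * np.sin(az), np.zeros(spec.count)])
    return [
        Fiber(
            vertices=np.vstack([start[i], end[i]]),
            fiber_class=FiberClass.NUCLEUS_MEMBRANE_BASAL,
            cross_section_radius=material.cross_section_radius,
            pre_strain=material.pre_strain,
            anchored=(False, True),
        )
        for i in range(spec.count)
    ]


def _build_over_nucleus(
    geometry: CellGeometry, spec: FiberClassSpec, material: FiberMaterial, rng
) -> list[Fiber]:
    R = geometry.nucleus_radius
    c = geometry.nucleus_center
    a_x, a_y = geometry.semi_axes
    theta = _class_angles(spec, spec.count, rng)
    fibers = []
    for i in range(spec.count):
        e = np.array([np.cos(theta[i]), np.sin(theta[i]), 0.0])
        perp = np.array([-e[1], e[0], 0.0])
        t = rng.uniform(-R / 2.0, R / 2.0)  # lateral offset from the centre plane
        R_t = np.sqrt(R**2 - t**2)
        # basal anchors: intersections of the offset line with the rim ellipse
        A = (e[0] / a_x) ** 2 + (e[1] / a_y) ** 2
        B = 2.0 * (perp[0] * t * e[0] / a_x**2 + perp[1] * t * e[1] / a_y**2)
        C = (perp[0] * t / a_x) ** 2 + (perp[1] * t / a_y) ** 2 - 1.0
        disc = B**2 - 4.0 * A * C
        if disc <= 0:
            raise RoutingError("over_nucleus_basal: offset line misses the basal footprint")
        s_hi = (-B + np.sqrt(disc)) / (2.0 * A)
        s_lo = (-B - np.sqrt(disc)) / (2.0 * A)
        if 0.8 * s_hi < R_t + 0.2 or 0.8 * (-s_lo) < R_t + 0.2:
            raise RoutingError("over_nucleus_basal: cell too small to route over the nucleus")
        u0, u1 = rng.random(2)
        anchor_a = (s_lo * (0.8 + 0.2 * u0)) * e + t * perp
        anchor_b = (s_hi * (0.8 + 0.2 * u1)) * e + t * perp
        # interior vertices on the apical nucleus surface along a great arc
        n_int = int(rng.integers(3, 8))
        arc = np.linspace(5.0 * np.pi / 6.0, np.pi / 6.0, n_int)
        interior = (
            c
            + t * perp
            + R_t * (np.cos(arc)[:, None] * e[None, :])
            + R_t * np.sin(arc)[:, None] * np.array([0.0, 0.0, 1.0])[None, :]
        )
        verts = np.vstack([anchor_a, interior, anchor_b])
        fibers.append(
            Fiber(
                vertices=verts,
                fiber_class=FiberClass.OVER_NUCLEUS_BASAL,
                cross_section_radius=material.cross_section_radius,
                pre_strain=material.pre_strain,
                anchored=(True, True),
            )
        )
    return fibers


def _build_ventral_network(
    geometry: CellGeometry, spec: FiberClassSpec, material: FiberMaterial, rng
) -> list[Fiber]:
    """Poisson nodes under the nucleus footprint joined by Delaunay edges.

    Exactly ``count`` edges are kept, drawn without replacement with
    probability proportional to the doubled-angle von Mises density at the
    edge azimuth, which biases the realised orientations toward target_S.
    """
    R = geometry.nucleus_radius
    n_nodes = max(4, int(round(np.pi * R**2 / spec.length_scale**2)))
    kappa = calibrate_concentration(min(spec.target_S, 1.0 - 1e-9))
    for _ in range(12):
        r = R * np.sqrt(rng.random(n_nodes))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_nodes)
        nodes = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        tri = Delaunay(nodes)
        edges = set()
        for simplex in tri.simplices:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
        edges = np.array(sorted(edges))
        if len(edges) >= spec.count:
            break
        n_nodes *= 2
    else:  # pragma: no cover
        raise RoutingError("ventral_network: could not generate enough edges")
    d = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    az = np.arctan2(d[:, 1], d[:, 0]) % np.pi
    logw = kappa * np.cos(2.0 * (az - MAJOR_AXIS_ANGLE))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    chosen = rng.choice(len(edges), size=spec.count, replace=False, p=w)
    hull_nodes = set(ConvexHull(nodes).vertices.tolist())
    fibers = []
    for i, j in edges[np.sort(chosen)]:
        verts = np.array([[*nodes[i], 0.0], [*nodes[j], 0.0]])
        fibers.append(
            Fiber(
                vertices=verts,
                fiber_class=FiberClass.VENTRAL_NETWORK,
                cross_section_radius=material.cross_section_radius,
                pre_strain=material.pre_strain,
                anchored=(i in hull_nodes, j in hull_nodes),
            )
        )
    return fibers


def _check_containment(geometry: CellGeometry, network: FiberNetwork) -> None:
    for f in network.fibers:
        v = f.vertices
        if np.any(v[:, 2] < -1e-9) or np.any(geometry.ellipsoid_value(v) > 1.0 + 1e-9):
            raise RoutingError(
                f"{f.fiber_class.value}: fiber vertex escapes the cell body"
            )
        for idx in ([0] if f.anchored[0] else []) + ([-1] if f.anchored[1] else []):
            if abs(v[idx, 2]) > 1e-6:
                raise RoutingError(
                    f"{f.fiber_class.value}: anchored endpoint off the basal plane"
                )
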