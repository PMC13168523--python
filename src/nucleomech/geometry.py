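"""Cell and nucleus geometry and conforming tetrahedral meshing.

The cell body is a semi-ellipsoid resting on the basal plane z = 0 with a
spherical nucleus inside.  Conventions used throughout the package:

* right-handed coordinates, z up, basal plane at z = 0;
* y is the cell's major basal axis (aspect_ratio = a_y / a_x >= 1);
* all lengths in micrometres (µm).

Meshing strategy: the nucleus surface is an icosphere whose vertices are
shared verbatim by the nucleus and cytoplasm tetrahedralisations, so the
interface is conforming by construction.  Interior and surface point clouds
are laid out deterministically and tetrahedralised with a single Delaunay
pass; elements are then classified by centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import InvalidGeometryError, MeshingError

#: part labels for solid elements
CYTOPLASM = 0
NUCLEUS = 1
PART_NAMES = ("cytoplasm", "nucleus")

#: default target edge length (µm) used when no resolution is given
DEFAULT_RESOLUTION = 1.5

_BASAL_TOL = 1e-9


def semi_axes_from_spread(spread_area: float, aspect_ratio: float) -> tuple[float, float]:
    """Basal semi-axes (a_x, a_y) of a cell with the given footprint.

    The basal footprint is an ellipse of area ``pi * a_x * a_y`` with the
    major axis along y, so ``a_y / a_x = aspect_ratio >= 1``.

    Parameters
    ----------
    spread_area
        Basal footprint area in µm².
    aspect_ratio
        Major/minor axis ratio (dimensionless, >= 1).
    """
    if spread_area <= 0:
        raise InvalidGeometryError(f"spread_area must be > 0, got {spread_area}")
    if aspect_ratio < 1:
        raise InvalidGeometryError(f"aspect_ratio must be >= 1, got {aspect_ratio}")
    a_x = math.sqrt(spread_area / (math.pi * aspect_ratio))
    return a_x, aspect_ratio * a_x


@dataclass(frozen=True)
class CellGeometry:
    """Semi-ellipsoidal cell body with an interior spherical nucleus.

    Attributes
    ----------
    spread_area : float
        Basal footprint area, µm².
    aspect_ratio : float
        Major/minor basal axis ratio (>= 1); major axis along y.
    height : float
        Apex height of the semi-ellipsoid, µm.
    nucleus_radius : float
        Radius of the (undeformed, spherical) nucleus, µm.
    basal_gap : float
        Clearance between the nucleus bottom and the basal plane, µm.
    """

    spread_area: float = 1200.0
    aspect_ratio: float = 1.5
    height: float = 13.0
    nucleus_radius: float = 5.5
    basal_gap: float = 0.5

    def __post_init__(self) -> None:
        for name in ("spread_area", "height", "nucleus_radius", "basal_gap"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.aspect_ratio < 1:
            raise InvalidGeometryError(f"aspect_ratio must be >= 1, got {self.aspect_ratio}")
        # nucleus sphere strictly inside the semi-ellipsoid
        verts = _icosphere(2)[0] * self.nucleus_radius + self.nucleus_center
        if np.any(self.ellipsoid_value(verts) >= 1.0) or np.any(verts[:, 2] <= 0):
            raise InvalidGeometryError(
                "nucleus sphere is not strictly inside the semi-ellipsoidal cell body"
            )

    @property
    def semi_axes(self) -> tuple[float, float]:
        """Basal semi-axes (a_x, a_y), µm."""
        return semi_axes_from_spread(self.spread_area, self.aspect_ratio)

    @property
    def nucleus_center(self) -> np.ndarray:
        """Nucleus centre (0, 0, R + basal_gap), µm."""
        return np.array([0.0, 0.0, self.nucleus_radius + self.basal_gap])

    @property
    def cell_volume(self) -> float:
        """Analytic semi-ellipsoid volume (2/3)·π·a_x·a_y·h, µm³."""
        a_x, a_y = self.semi_axes
        return 2.0 / 3.0 * math.pi * a_x * a_y * self.height

    @property
    def nucleus_volume(self) -> float:
        """Analytic nucleus volume (4/3)·π·R³, µm³."""
        return 4.0 / 3.0 * math.pi * self.nucleus_radius**3

    def ellipsoid_value(self, points: np.ndarray) -> np.ndarray:
        """(x/a_x)² + (y/a_y)² + (z/h)² — < 1 inside the cell body."""
        a_x, a_y = self.semi_axes
        p = np.atleast_2d(points)
        return (p[:, 0] / a_x) ** 2 + (p[:, 1] / a_y) ** 2 + (p[:, 2] / self.height) ** 2

    def boundary_radius(self, azimuth: np.ndarray) -> np.ndarray:
        """Radial distance from the z-axis to the basal rim at given azimuth(s)."""
        a_x, a_y = self.semi_axes
        az = np.asarray(azimuth, dtype=float)
        return 1.0 / np.sqrt((np.cos(az) / a_x) ** 2 + (np.sin(az) / a_y) ** 2)


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------


def _icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere (vertices, triangular faces) at the given subdivision level."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.intp,
    )
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        vlist = list(verts)
        new_faces = []

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(vlist)
                vlist.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.intp)
    return verts, faces


def icosphere_level_for(radius: float, resolution: float) -> int:
    """Smallest subdivision level whose edge length is <= resolution."""
    # icosahedron edge for a unit circumscribed sphere is ~1.0515; halves per level
    return max(1, math.ceil(math.log2(1.0515 * radius / resolution)))


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Conforming tetrahedral + membrane-triangle mesh of the cell.

    ``tets`` index into ``nodes``; ``tet_part`` maps each tetrahedron to
    CYTOPLASM or NUCLEUS.  ``shell_tris`` tile the exterior (lateral and
    apical) cell surface.  Caches used by the FE solver are attached lazily.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_part: np.ndarray
    shell_tris: np.ndarray
    shell_thickness: float = 0.2
    geometry: CellGeometry | None = None
    resolution: float = DEFAULT_RESOLUTION
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @cached_property
    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    @cached_property
    def basal_nodes(self) -> np.ndarray:
        """Indices of nodes on the basal plane z = 0."""
        return np.flatnonzero(np.abs(self.nodes[:, 2]) < 1e-6)

    @cached_property
    def nucleus_surface_nodes(self) -> np.ndarray:
        """Nodes shared by nucleus and cytoplasm tetrahedra (the interface).

        For a mesh whose only part is the nucleus (e.g. a lone verification
        sphere) this is the exterior boundary instead.
        """
        nuc = np.unique(self.tets[self.tet_part == NUCLEUS])
        cyt = np.unique(self.tets[self.tet_part == CYTOPLASM])
        if len(cyt) == 0:
            return np.unique(self.shell_tris)
        return np.intersect1d(nuc, cyt)

    @cached_property
    def basal_rim_nodes(self) -> np.ndarray:
        """Basal nodes on (or very near) the footprint rim."""
        if self.geometry is None:
            return self.basal_nodes
        b = self.basal_nodes
        p = self.nodes[b]
        a_x, a_y = self.geometry.semi_axes
        rho = (p[:, 0] / a_x) ** 2 + (p[:, 1] / a_y) ** 2
        return b[rho > 0.95]

    def part_volume(self, part: int) -> float:
        return float(self.tet_volumes[self.tet_part == part].sum())

    @cached_property
    def node_tree(self) -> cKDTree:
        return cKDTree(self.nodes)


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    e = p[:, 1:] - p[:, :1]
    return np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0


def _tet_quality(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Radius ratio quality 3·r_in/r_circ, 1 for a regular tetrahedron."""
    p = nodes[tets]
    vol = np.abs(tet_volumes(nodes, tets))
    # face areas
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    area_sum = np.zeros(len(tets))
    for i, j, k in faces:
        area_sum += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1
        )
    r_in = 3.0 * vol / area_sum
    # circumradius from the Cayley-Menger-free formula |a||b||c| style
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    la, lb, lc = (np.einsum("ij,ij->i", v, v) for v in (a, b, c))
    num = la[:, None] * np.cross(b, c) + lb[:, None] * np.cross(c, a) + lc[:, None] * np.cross(a, b)
    r_circ = np.linalg.norm(num, axis=1) / (12.0 * vol)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 3.0 * r_in / r_circ
    return np.nan_to_num(q, nan=0.0, posinf=0.0)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------


def _grid_points(lo: np.ndarray, hi: np.ndarray, spacing: float) -> np.ndarray:
    """Regular grid covering [lo, hi]; axes spanning 0 are symmetric about 0."""
    out_axes = []
    for l, h in zip(lo, hi):
        if l < 0 < h:
            pos = np.arange(0.0, h + spacing / 2, spacing)
            neg = np.arange(-spacing, l - spacing / 2, -spacing)[::-1]
            out_axes.append(np.concatenate([neg, pos]))
        else:
            out_axes.append(np.arange(l, h + spacing / 2, spacing))
    g = np.meshgrid(*out_axes, indexing="ij")
    return np.stack([x.ravel() for x in g], axis=1)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, roughly uniform points on the upper unit hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n  # (0, 1)
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _thin_points(points: np.ndarray, min_dist: float) -> np.ndarray:
    """Greedy deterministic thinning so no two kept points are closer than min_dist."""
    if len(points) == 0:
        return points
    tree = cKDTree(points)
    keep = np.ones(len(points), dtype=bool)
    for i in range(len(points)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(points[i], min_dist):
            if j > i:
                keep[j] = False
    return points[keep]


def _ellipse_rim_points(a_x: float, a_y: float, spacing: float) -> np.ndarray:
    """Points along the basal rim ellipse with ~uniform arc spacing."""
    t = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
    xy = np.stack([a_x * np.cos(t), a_y * np.sin(t)], axis=1)
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    total = arc[-1] + seg[-1]
    n = max(8, int(round(total / spacing)))
    targets = np.arange(n) * total / n
    idx = np.searchsorted(arc, targets)
    idx = np.clip(idx, 0, len(t) - 1)
    pts = xy[np.unique(idx)]
    return np.column_stack([pts, np.zeros(len(pts))])


def _cell_point_cloud(
    geometry: CellGeometry, resolution: float
) -> tuple[np.ndarray, dict[str, slice]]:
    """All mesh points plus named index slices; the nucleus icosphere comes first."""
    a_x, a_y = geometry.semi_axes
    h = geometry.height
    R = geometry.nucleus_radius
    c = geometry.nucleus_center
    res = resolution

    # the nucleus interface is the readout surface (projected area, interface
    # conformity); resolve it at half the bulk edge length
    level = icosphere_level_for(R, res / 2.0)
    sph_v, _ = _icosphere(level)
    nuc_surf = c + R * sph_v

    # nucleus interior: grid + centre, kept clear of the surface
    # deterministic jiggle breaks the co-planar/co-spherical degeneracy of
    # regular grids under Delaunay (exact surface points are never jiggled)
    jig = np.random.default_rng(20260922)

    g = _grid_points(np.array([-R, -R, c[2] - R]), np.array([R, R, c[2] + R]), res)
    g = g + jig.uniform(-0.03 * res, 0.03 * res, g.shape)
    rad = np.linalg.norm(g - c, axis=1)
    nuc_in = g[rad < R - 0.55 * res]
    nuc_in = np.vstack([nuc_in, c])

    # exterior ellipsoid surface (z above a basal margin); Thomsen area estimate
    area_half = 2.0 * math.pi * (
        ((a_x * a_y) ** 1.6 + (a_x * h) ** 1.6 + (a_y * h) ** 1.6) / 3.0
    ) ** (1 / 1.6)
    n_surf = max(64, int(2.2 * area_half / res**2))
    hemi = _fibonacci_hemisphere(n_surf) * np.array([a_x, a_y, h])
    hemi = hemi[hemi[:, 2] > 0.45 * res]
    hemi = _thin_points(hemi, 0.55 * res)

    rim = _ellipse_rim_points(a_x, a_y, res)

    # basal disk grid, clear of the rim
    bg = _grid_points(np.array([-a_x, -a_y, 0.0]), np.array([a_x, a_y, 0.0]), res)
    bg[:, :2] += jig.uniform(-0.03 * res, 0.03 * res, (len(bg), 2))  # stay on z = 0
    bg = bg[(bg[:, 0] / a_x) ** 2 + (bg[:, 1] / a_y) ** 2 < (1.0 - 0.5 * res / min(a_x, a_y)) ** 2]

    # cytoplasm interior grid
    gi = _grid_points(np.array([-a_x, -a_y, 0.0]), np.array([a_x, a_y, h]), res)
    gi = gi + jig.uniform(-0.03 * res, 0.03 * res, gi.shape)
    gi = gi[gi[:, 2] >= 0.8 * res]
    margin = 0.5 * res / min(a_x, a_y, h)
    inside = geometry.ellipsoid_value(gi) < (1.0 - margin) ** 2
    outside_nucleus = np.linalg.norm(gi - c, axis=1) > R + 0.55 * res
    gi = gi[inside & outside_nucleus]

    blocks = [nuc_surf, nuc_in, hemi, rim, bg, gi]
    names = ["nucleus_surface", "nucleus_interior", "apical", "rim", "basal", "cytoplasm"]
    slices, start = {}, 0
    for name, blk in zip(names, blocks):
        slices[name] = slice(start, start + len(blk))
        start += len(blk)
    return np.vstack(blocks), slices


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def build_cell_mesh(geometry: CellGeometry, resolution: float = DEFAULT_RESOLUTION) -> Mesh:
    """Mesh the cell into conforming cytoplasm/nucleus tetrahedra + surface shell.

    Parameters
    ----------
    geometry
        Validated cell geometry.
    resolution
        Target edge length in µm; must be <= nucleus_radius / 2.

    Returns
    -------
    Mesh
        Deterministic for fixed inputs.
    """
    if resolution > geometry.nucleus_radius / 2:
        raise InvalidGeometryError(
            f"resolution {resolution} exceeds nucleus_radius/2 = {geometry.nucleus_radius / 2}"
        )
    points, sl = _cell_point_cloud(geometry, resolution)
    n_sph = sl["nucleus_surface"].stop
    n_nuc = sl["nucleus_interior"].stop

    # Nucleus and cytoplasm are tetrahedralised separately but share the
    # icosphere vertices verbatim, so the interface conforms exactly: the
    # cytoplasm triangulation sees the nucleus polyhedron as an empty hole
    # tiled only by all-icosphere tets, which are removed.
    nuc_tets = Delaunay(points[:n_nuc]).simplices.astype(np.intp)

    cyto_idx = np.concatenate([np.arange(n_sph), np.arange(n_nuc, len(points))])
    cyto_local = Delaunay(points[cyto_idx]).simplices.astype(np.intp)
    cyto_tets = cyto_idx[cyto_local]
    cyto_tets = cyto_tets[~np.all(cyto_tets < n_sph, axis=1)]  # drop the nucleus hole

    tets = np.vstack([nuc_tets, cyto_tets])
    part = np.concatenate(
        [np.full(len(nuc_tets), NUCLEUS, np.int8), np.full(len(cyto_tets), CYTOPLASM, np.int8)]
    )

    vols = tet_volumes(points, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]  # orient positively
    keep = np.abs(vols) > 1e-9 * resolution**3
    # degenerate "cap" slivers spanned purely by exterior-surface points add
    # nothing but ill-conditioning; dropping them moves the shell to the
    # neighbouring faces, a sub-resolution geometric change
    on_ext_surface = np.zeros(len(points), dtype=bool)
    for name in ("apical", "rim", "basal"):
        on_ext_surface[sl[name]] = True
    q = _tet_quality(points, tets)
    keep &= ~((q < 1e-3) & np.all(on_ext_surface[tets], axis=1))
    tets, part = tets[keep], part[keep]
    if len(tets) == 0:
        raise MeshingError("meshing produced no usable tetrahedra")

    shell = _boundary_shell(points, tets)

    # drop nodes not referenced by any element
    used = np.unique(np.concatenate([tets.ravel(), shell.ravel()]))
    remap = -np.ones(len(points), dtype=np.intp)
    remap[used] = np.arange(len(used))
    mesh = Mesh(
        nodes=points[used],
        tets=remap[tets],
        tet_part=part,
        shell_tris=remap[shell],
        geometry=geometry,
        resolution=resolution,
    )
    if _tet_quality(mesh.nodes, mesh.tets).min() <= 0:
        raise MeshingError("degenerate element in mesh")
    return mesh


def _boundary_shell(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Boundary faces that are not on the basal plane (lateral + apical shell)."""
    faces = np.vstack(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    z = points[boundary][:, :, 2]
    return boundary[~np.all(z < 1e-6, axis=1)]


def mesh_quality_report(mesh: Mesh) -> dict:
    """Diagnostic summary: per-part volume, element quality, counts."""
    if len(mesh.tets) == 0:
        raise MeshingError("no elements")
    q = _tet_quality(mesh.nodes, mesh.tets)
    report = {
        "n_nodes": int(len(mesh.nodes)),
        "n_tets": int(len(mesh.tets)),
        "n_shell_tris": int(len(mesh.shell_tris)),
        "min_quality": float(q.min()),
        "median_quality": float(np.median(q)),
        "part_volumes": {
            PART_NAMES[p]: mesh.part_volume(p) for p in (CYTOPLASM, NUCLEUS)
        },
    }
    if mesh.geometry is not None:
        geo = mesh.geometry
        report["analytic_volumes"] = {
            "cytoplasm": geo.cell_volume - geo.nucleus_volume,
            "nucleus": geo.nucleus_volume,
        }
    return report


def mesh_sphere(radius: float, resolution: float, center: np.ndarray | None = None) -> Mesh:
    """Tetrahedral mesh of a lone sphere (used by solver verification cases)."""
    if center is None:
        center = np.zeros(3)
    level = icosphere_level_for(radius, resolution)
    sph_v, _ = _icosphere(level)
    surf = center + radius * sph_v
    g = center + _grid_points(np.array([-radius] * 3), np.array([radius] * 3), resolution)
    g = g + np.random.default_rng(20260922).uniform(-0.03 * resolution, 0.03 * resolution, g.shape)
    rad = np.linalg.norm(g - center, axis=1)
    interior = g[rad < radius - 0.55 * resolution]
    pts = np.vstack([surf, interior, center[None, :]])
    tri = Delaunay(pts)
    tets = tri.simplices.astype(np.intp)
    vols = tet_volumes(pts, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    keep = np.abs(vols) > 1e-9 * resolution**3
    tets = tets[keep]
    part = np.full(len(tets), NUCLEUS, dtype=np.int8)
    faces = np.vstack(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    return Mesh(
        nodes=pts,
        tets=tets,
        tet_part=part,
        shell_tris=boundary,
        geometry=None,
        resolution=resolution,
    )
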