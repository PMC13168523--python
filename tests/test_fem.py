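import numpy as np
import pytest

from nucleomech import (
    FiberMaterial,
    MaterialParams,
    assemble,
    generate_network,
    global_equilibrium_residual,
    solve_static,
    total_nuclear_force,
    verify_analytic,
)
from nucleomech.errors import SingularSystemError, TieError
from nucleomech.fem import Constraints, _solid_membrane_stiffness  # noqa: F401
from nucleomech.fibers import Fiber, FiberClass, FiberClassSpec, FiberNetwork

K_EFF = 1.0e4  # pN/µm, mid-grid anchor stiffness


def _specs(counts=(15, 8, 20), S=0.6):
    return [FiberClassSpec(fc, counts[i], S) for i, fc in enumerate(FiberClass)]


def _materials(pre_strain=0.2):
    return MaterialParams(fiber=FiberMaterial(pre_strain=pre_strain))


class TestAssembly:
    def test_zero_pre_strain_gives_zero_load(self, default_geometry, coarse_mesh):
        mats = _materials(pre_strain=0.0)
        net = generate_network(default_geometry, _specs(), mats.fiber, seed=21)
        system = assemble(coarse_mesh, mats, net, K_EFF)
        assert np.all(system.f == 0.0)

    def test_pre_strain_end_force_magnitude(self, default_geometry, coarse_mesh, materials):
        # E_f·A·ε₀ = 2.5e5 Pa · π·0.25² µm² · 0.2 ≈ 9817 pN (≈ 9.8 nN)
        assert materials.fiber.axial_rigidity * 0.2 == pytest.approx(9817.477, rel=1e-6)
        net = generate_network(default_geometry, _specs((1, 0, 0)), materials.fiber, seed=22)
        system = assemble(coarse_mesh, materials, net, K_EFF)
        seg = system.segments
        node_force = np.linalg.norm(system.f.reshape(-1, 3)[seg.node_i[0]])
        assert node_force == pytest.approx(9817.477, rel=1e-6)

    def test_operator_symmetry(self, default_geometry, coarse_mesh, materials):
        net = generate_network(default_geometry, _specs(), materials.fiber, seed=23)
        K = assemble(coarse_mesh, materials, net, K_EFF).K
        asym = abs(K - K.T).max()
        assert asym < 1e-10 * abs(K).max()

    def test_untied_fiber_vertex_raises(self, coarse_mesh, materials):
        stray = Fiber(
            vertices=np.array([[0.0, 0.0, 50.0], [0.0, 0.0, 60.0]]),
            fiber_class=FiberClass.NUCLEUS_MEMBRANE_BASAL,
            cross_section_radius=0.25,
            pre_strain=0.2,
            anchored=(False, False),
        )
        with pytest.raises(TieError):
            assemble(coarse_mesh, materials, FiberNetwork(fibers=[stray]), K_EFF)


class TestSolve:
    def test_zero_load_zero_displacement(self, coarse_mesh, materials):
        system = assemble(coarse_mesh, materials, None, K_EFF)
        sol = solve_static(system)
        assert np.all(sol.displacements == 0.0)
        assert np.all(sol.tet_stress == 0.0)

    def test_global_equilibrium(self, default_geometry, coarse_mesh, materials):
        net = generate_network(default_geometry, _specs(), materials.fiber, seed=24)
        sol = solve_static(assemble(coarse_mesh, materials, net, K_EFF))
        assert sol.residual < 1e-8
        assert global_equilibrium_residual(sol) < 1e-6

    def test_linearity_in_pre_strain(self, default_geometry, coarse_mesh):
        sols = []
        for eps in (0.1, 0.2):
            mats = _materials(pre_strain=eps)
            net = generate_network(default_geometry, _specs(), mats.fiber, seed=25)
            sols.append(solve_static(assemble(coarse_mesh, mats, net, K_EFF)))
        u1, u2 = sols[0].displacements, sols[1].displacements
        assert np.allclose(2.0 * u1, u2, rtol=1e-6, atol=1e-12)
        f1 = total_nuclear_force(sols[0])
        f2 = total_nuclear_force(sols[1])
        assert f2 == pytest.approx(2.0 * f1, rel=1e-6)

    def test_substrate_softening_single_fiber(self, default_geometry, coarse_mesh, materials):
        """A stiffer anchor spring lets a lone fiber keep more of its tension."""
        geo = default_geometry
        start = geo.nucleus_center + np.array([geo.nucleus_radius, 0.0, 0.0])
        fiber = Fiber(
            vertices=np.array([start, [0.9 * geo.semi_axes[0], 0.0, 0.0]]),
            fiber_class=FiberClass.NUCLEUS_MEMBRANE_BASAL,
            cross_section_radius=0.25,
            pre_strain=0.2,
            anchored=(False, True),
        )
        net = FiberNetwork(fibers=[fiber])
        tensions = [
            solve_static(assemble(coarse_mesh, materials, net, k_eff)).segment_tension[0]
            for k_eff in (2e2, 2e3, 2e4, 2e5)
        ]
        assert np.all(np.diff(tensions) > 0)

    def test_substrate_softening_total_force(self, default_geometry, coarse_mesh, materials):
        """For a fixed network, total transmitted nuclear force grows with k_eff."""
        net = generate_network(default_geometry, _specs(), materials.fiber, seed=26)
        forces = [
            total_nuclear_force(solve_static(assemble(coarse_mesh, materials, net, k_eff)))
            for k_eff in (2e2, 2e3, 2e4, 2e5)
        ]
        assert np.all(np.diff(forces) > 0)

    def test_exactly_singular_system_raises(self):
        """A free-floating truss (rigid modes unconstrained) is rejected."""
        from nucleomech.fem import AssembledSystem, _build_segments, truss_stiffness
        import scipy.sparse as sp
        from nucleomech.geometry import Mesh, NUCLEUS

        mesh = Mesh(
            nodes=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
            tets=np.empty((0, 4), dtype=np.intp),
            tet_part=np.empty(0, dtype=np.int8),
            shell_tris=np.empty((0, 3), dtype=np.intp),
            resolution=1.0,
        )
        K = sp.csr_matrix(truss_stiffness(np.array([1.0, 0.0, 0.0]), 4908.7))
        f = np.array([9817.0, 0, 0, -9817.0, 0, 0])
        system = AssembledSystem(
            K=K,
            f=f,
            constraints=Constraints(dofs=np.empty(0, dtype=int), values=np.empty(0)),
            mesh=mesh,
            segments=_build_segments(mesh, FiberNetwork(fibers=[]), [], MaterialParams().fiber),
            spring_nodes=np.empty(0, dtype=np.intp),
            spring_stiffness=np.empty(0),
            materials=MaterialParams(),
        )
        with pytest.raises(SingularSystemError):
            solve_static(system)

    def test_dense_oracle_equivalence(self):
        """Sparse constrained solve matches a brute-force dense solve."""
        from nucleomech.fem import AssembledSystem, _build_segments
        from nucleomech.geometry import Mesh, NUCLEUS, tet_volumes
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(0)
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
            dtype=float,
        )
        pts[1:] += rng.uniform(-0.05, 0.05, (7, 3))
        tets = Delaunay(pts).simplices.astype(np.intp)
        vols = tet_volumes(pts, tets)
        tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
        tets = tets[np.abs(vols) > 1e-12]
        mesh = Mesh(
            nodes=pts,
            tets=tets,
            tet_part=np.full(len(tets), NUCLEUS, np.int8),
            shell_tris=np.empty((0, 3), dtype=np.intp),
            resolution=1.0,
        )
        mats = MaterialParams()
        K = _solid_membrane_stiffness(mesh, mats)
        fixed = np.arange(9)  # clamp nodes 0-2 completely
        f = rng.normal(0.0, 10.0, K.shape[0])
        f[fixed] = 0.0
        system = AssembledSystem(
            K=K,
            f=f,
            constraints=Constraints(dofs=fixed, values=np.zeros(len(fixed))),
            mesh=mesh,
            segments=_build_segments(mesh, FiberNetwork(fibers=[]), [], mats.fiber),
            spring_nodes=np.empty(0, dtype=np.intp),
            spring_stiffness=np.empty(0),
            materials=mats,
        )
        sol = solve_static(system)
        free = np.setdiff1d(np.arange(K.shape[0]), fixed)
        dense = np.zeros(K.shape[0])
        dense[free] = np.linalg.solve(K.toarray()[np.ix_(free, free)], f[free])
        assert np.allclose(sol.displacements.ravel(), dense, atol=1e-10)


class TestAnalyticCases:
    def test_bar_spring_series_closed_form(self):
        report = verify_analytic("bar_spring_series")
        assert report["passed"]
        assert report["expected"] == pytest.approx(1.0)  # ε₀·L/2 = 1 µm
        assert report["rel_error"] < 1e-8

    def test_unknown_case_raises(self):
        with pytest.raises(ValueError):
            verify_analytic("not_a_case")
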