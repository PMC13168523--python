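import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleomech import (
    FiberClass,
    FiberClassSpec,
    FiberNetwork,
    calibrate_concentration,
    expected_order,
    generate_network,
    nematic_order,
    sample_orientations,
)
from nucleomech.errors import RoutingError
from nucleomech.fibers import MAJOR_AXIS_ANGLE

angle_lists = st.lists(
    st.floats(min_value=-10.0, max_value=10.0, allow_nan=False), min_size=1, max_size=30
)


class TestNematicOrder:
    @pytest.mark.parametrize(
        "angles,expected",
        [
            ([0.3, 0.3, 0.3], 1.0),
            ([0.0, np.pi / 2], 0.0),
            ([0.0, np.pi / 4], np.sqrt(2) / 2),  # |(1 + i)/2|
        ],
    )
    def test_examples(self, angles, expected):
        assert nematic_order(angles) == pytest.approx(expected, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            nematic_order([])

    def test_zero_weights_raise(self):
        with pytest.raises(ValueError):
            nematic_order([0.1, 0.2], weights=[0.0, 0.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(angles=angle_lists, shift=st.floats(-3.0, 3.0, allow_nan=False))
    def test_axial_and_rotation_invariance(self, angles, shift):
        base = nematic_order(angles)
        assert 0.0 <= base <= 1.0 + 1e-12
        flipped = [a + np.pi for a in angles]
        assert nematic_order(flipped) == pytest.approx(base, abs=1e-9)
        rotated = [a + shift for a in angles]
        assert nematic_order(rotated) == pytest.approx(base, abs=1e-9)


class TestCalibration:
    def test_zero_maps_to_uniform(self):
        assert calibrate_concentration(0.0) == 0.0

    def test_monotone(self):
        k = [calibrate_concentration(s) for s in (0.3, 0.6, 0.9)]
        assert k[0] < k[1] < k[2]

    def test_round_trip_at_large_n(self):
        kappa = calibrate_concentration(0.7)
        S_hat = nematic_order(sample_orientations(10**5, kappa, seed=7))
        assert S_hat == pytest.approx(0.7, abs=0.01)

    def test_perfect_alignment_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_concentration(1.0)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            calibrate_concentration(bad)


class TestSampling:
    def test_deterministic(self):
        a = sample_orientations(500, 2.0, seed=11)
        b = sample_orientations(500, 2.0, seed=11)
        assert np.array_equal(a, b)

    def test_uniform_order_is_small(self):
        assert nematic_order(sample_orientations(10**4, 0.0, seed=3)) < 0.05

    def test_high_concentration_order(self):
        assert nematic_order(sample_orientations(10**3, 50.0, seed=5)) > 0.95
        assert expected_order(50.0) > 0.98

    def test_mean_is_major_axis(self):
        theta = sample_orientations(10**4, 5.0, seed=9)
        mean_axis = 0.5 * np.angle(np.mean(np.exp(2j * theta)))
        assert mean_axis % np.pi == pytest.approx(MAJOR_AXIS_ANGLE, abs=0.05)

    @pytest.mark.parametrize("n", [100, 1000, 10000])
    def test_convergence_bound(self, n):
        kappa = calibrate_concentration(0.5)
        S_hat = nematic_order(sample_orientations(n, kappa, seed=100 + n))
        assert abs(S_hat - 0.5) < 3.0 / np.sqrt(n)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_orientations(0, 1.0, seed=0)
        with pytest.raises(ValueError):
            sample_orientations(10, -1.0, seed=0)


def _specs(counts=(20, 10, 30), S=0.5):
    return [FiberClassSpec(fc, counts[i], S) for i, fc in enumerate(FiberClass)]


class TestNetworkGeneration:
    def test_exact_class_counts(self, default_geometry):
        net = generate_network(default_geometry, _specs((20, 10, 30)), seed=1)
        assert net.class_counts() == {
            "nucleus_membrane_basal": 20,
            "over_nucleus_basal": 10,
            "ventral_network": 30,
        }

    def test_realized_order_near_target(self, default_geometry):
        net = generate_network(default_geometry, _specs((200, 120, 30), S=0.8), seed=2)
        for fc in (FiberClass.NUCLEUS_MEMBRANE_BASAL, FiberClass.OVER_NUCLEUS_BASAL):
            assert net.realized_order(fc) == pytest.approx(0.8, abs=0.05)

    def test_seed_reproducibility_bitwise(self, default_geometry):
        a = generate_network(default_geometry, _specs(), seed=33)
        b = generate_network(default_geometry, _specs(), seed=33)
        assert all(np.array_equal(x.vertices, y.vertices) for x, y in zip(a.fibers, b.fibers))

    def test_empty_specs_give_empty_network(self, default_geometry):
        net = generate_network(default_geometry, _specs((0, 0, 0)), seed=4)
        assert net.fibers == []

    def test_anchors_on_basal_plane(self, default_geometry):
        net = generate_network(default_geometry, _specs(), seed=5)
        anchors = net.anchor_points
        assert len(anchors) > 0
        assert np.abs(anchors[:, 2]).max() < 1e-6

    def test_over_nucleus_interior_vertices_on_sphere(self, default_geometry):
        net = generate_network(default_geometry, _specs(), seed=6)
        c = default_geometry.nucleus_center
        R = default_geometry.nucleus_radius
        for f in net.by_class(FiberClass.OVER_NUCLEUS_BASAL):
            assert len(f.vertices) >= 5  # two anchors + at least 3 interior
            radii = np.linalg.norm(f.vertices[1:-1] - c, axis=1)
            assert np.abs(radii - R).max() < 1e-6

    def test_geometric_containment(self, default_geometry):
        net = generate_network(default_geometry, _specs((50, 30, 40)), seed=7)
        for f in net.fibers:
            assert np.all(f.vertices[:, 2] >= -1e-9)
            assert np.all(default_geometry.ellipsoid_value(f.vertices) <= 1.0 + 1e-9)

    def test_too_small_cell_raises_routing_error(self):
        from nucleomech import CellGeometry

        tiny = CellGeometry(spread_area=133.0, aspect_ratio=1.0, height=13.0)
        with pytest.raises(RoutingError, match="nucleus_membrane_basal"):
            generate_network(tiny, _specs(), seed=8)

    def test_json_round_trip(self, default_geometry):
        net = generate_network(default_geometry, _specs((5, 3, 4)), seed=9)
        back = FiberNetwork.from_json(net.to_json())
        assert len(back.fibers) == len(net.fibers)
        for a, b in zip(net.fibers, back.fibers):
            assert a.fiber_class == b.fiber_class
            assert np.allclose(a.vertices, b.vertices)
            assert a.anchored == b.anchored
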