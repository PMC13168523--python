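import numpy as np
import pytest

from nucleomech import (
    calibrate_concentration,
    image_alignment_S,
    render_filament_image,
    sample_filament_segments,
    structure_tensor_field,
)
from nucleomech.imaging import FilamentImage, load_image, save_image


def _stripes(shape=(128, 128), period=8.0, vertical=True, amplitude=1.0):
    rows, cols = shape
    coord = np.arange(cols) if vertical else np.arange(rows)[:, None]
    img = amplitude * (1.0 + np.sin(2 * np.pi * coord / period)) / 2.0
    return np.broadcast_to(img, shape).astype(float)


class TestRendering:
    def test_single_horizontal_segment_peaks_on_its_row(self):
        img = render_filament_image(
            [((20, 64), (108, 64))], shape=(128, 128), noise_sd=0.0
        )
        peak_rows = np.argmax(img.intensity[:, 30:100], axis=0)
        assert np.all(peak_rows == 64)

    def test_deterministic_for_fixed_seed(self):
        segs = [((10, 10), (100, 90)), ((30, 80), (90, 20))]
        a = render_filament_image(segs, shape=(128, 128), seed=7)
        b = render_filament_image(segs, shape=(128, 128), seed=7)
        assert np.array_equal(a.intensity, b.intensity)

    def test_empty_segment_list_warns_blank(self):
        with pytest.warns(UserWarning, match="empty"):
            img = render_filament_image([], shape=(64, 64), noise_sd=0.0)
        assert np.all(img.intensity == 0.0)

    def test_sampled_segments_hit_target_order(self):
        kappa = calibrate_concentration(0.8)
        segs = sample_filament_segments(200, kappa, seed=13)
        img = render_filament_image(segs, noise_sd=0.0, seed=0)
        assert img.ground_truth_order == pytest.approx(0.8, abs=0.05)


class TestStructureTensor:
    def test_vertical_stripes_orientation_and_coherency(self):
        field = structure_tensor_field(_stripes(vertical=True))
        hot = field.energy > 0.2 * field.energy.max()
        theta_deg = np.degrees(field.theta[hot])
        assert np.all(np.minimum(np.abs(theta_deg - 90), np.abs(theta_deg - 270)) < 2)
        assert field.coherency[hot].mean() > 0.95
        assert image_alignment_S(field) > 0.95

    def test_orthogonal_stripe_families_cancel(self):
        left = _stripes((128, 64), vertical=True)
        right = _stripes((128, 64), vertical=False)
        img = np.concatenate([left, right], axis=1)
        field = structure_tensor_field(img)
        # exclude the seam between the two families
        mask = np.ones_like(img, dtype=bool)
        mask[:, 54:74] = False
        assert image_alignment_S(field, mask=mask) < 0.05

    def test_rotation_equivariance(self):
        from skimage.transform import rotate

        kappa = calibrate_concentration(0.9)
        segs = sample_filament_segments(60, kappa, shape=(256, 256), length_px=50, seed=3)
        img = render_filament_image(segs, shape=(256, 256), noise_sd=0.0)
        phi = 30.0

        def mean_axis(arr):
            f = structure_tensor_field(arr)
            w = f.energy * f.coherency
            return np.degrees(0.5 * np.angle(np.sum(w * np.exp(2j * f.theta)))) % 180

        a0 = mean_axis(img.intensity)
        a1 = mean_axis(rotate(img.intensity, phi, preserve_range=True))
        # positive skimage angle is counter-clockwise on screen, i.e. -phi in
        # the row-down image frame used for theta
        delta = (a0 - a1) % 180
        assert min(delta, 180 - delta) == pytest.approx(phi, abs=2.0)

    def test_white_noise_less_coherent_than_stripes(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(1.0, 0.3, (128, 128))
        f_noise = structure_tensor_field(noise)
        f_stripe = structure_tensor_field(_stripes())
        assert f_noise.coherency.mean() < f_stripe.coherency.mean()

    def test_constant_image_zero_energy(self):
        field = structure_tensor_field(np.full((64, 64), 3.0))
        assert np.all(field.energy == 0.0)
        assert np.all(field.coherency == 0.0)
        with pytest.raises(ValueError, match="zero total weight"):
            image_alignment_S(field)

    def test_intensity_invariance(self):
        img = _stripes()
        f1 = structure_tensor_field(img)
        f2 = structure_tensor_field(4.2 * img)
        hot = f1.energy > 0.1 * f1.energy.max()
        assert np.allclose(f1.theta[hot], f2.theta[hot])
        assert np.allclose(f1.coherency, f2.coherency, atol=1e-10)
        assert image_alignment_S(f1) == pytest.approx(image_alignment_S(f2), abs=1e-9)

    def test_invalid_scales_raise(self):
        with pytest.raises(ValueError):
            structure_tensor_field(_stripes(), sigma_g=0.0)
        with pytest.raises(ValueError):
            structure_tensor_field(np.zeros((8, 8)), sigma_w=4.0)


class TestEndToEndRecovery:
    def test_measured_S_tracks_ground_truth(self):
        targets = (0.0, 0.3, 0.6, 0.9)
        measured, truth = [], []
        for i, S in enumerate(targets):
            kappa = calibrate_concentration(S)
            segs = sample_filament_segments(200, kappa, seed=40 + i)
            img = render_filament_image(segs, seed=50 + i)
            truth.append(img.ground_truth_order)
            measured.append(image_alignment_S(structure_tensor_field(img)))
        assert np.all(np.diff(measured) > 0)  # monotone in the target order
        assert np.abs(np.array(measured) - np.array(truth)).max() < 0.1


class TestImageIO:
    def test_tiff_round_trip(self, tmp_path):
        img = render_filament_image([((5, 20), (58, 44))], shape=(64, 64), seed=1)
        path = save_image(tmp_path / "fil.tif", img)
        back = load_image(path)
        assert back.intensity.shape == img.intensity.shape
        corr = np.corrcoef(back.intensity.ravel(), img.intensity.ravel())[0, 1]
        assert corr > 0.999

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            FilamentImage(intensity=np.array([[-1.0, 0.0]]))
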