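"""Synthetic filament micrographs and structure-tensor orientation analysis.

``render_filament_image`` draws Gaussian-profile ridges for a set of 2D
segments (a stand-in for phalloidin-stained filament images with known
ground truth).  ``structure_tensor_field`` computes the gradient structure
tensor (gradient scale σ_g, window scale σ_w) whose eigen-decomposition
yields per-pixel orientation, coherency and energy, and
``image_alignment_S`` reduces the field to the scalar alignment parameter
S ∈ [0, 1] — the same nematic order statistic used for fiber azimuths, with
energy × coherency weights.

Angle convention: θ ∈ [0, π) measured from the image x-axis (columns), so a
horizontal filament has θ = 0 and a vertical one θ = π/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.feature import structure_tensor
from scipy.ndimage import gaussian_filter

from .fibers import nematic_order, sample_orientations


@dataclass
class FilamentImage:
    """Grayscale image with optional per-segment ground truth."""

    intensity: np.ndarray  # (rows, cols), float, >= 0
    pixel_size: float = 0.1  # µm per pixel
    ground_truth: list[dict] | None = None  # segment endpoints + orientation

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def ground_truth_order(self) -> float:
        """Length-weighted nematic order of the ground-truth segments."""
        if not self.ground_truth:
            raise ValueError("image carries no ground truth")
        ang = np.array([g["orientation"] for g in self.ground_truth])
        w = np.array([g["length"] for g in self.ground_truth])
        return nematic_order(ang, w)


@dataclass
class OrientationField:
    """Per-pixel structure-tensor orientation, coherency and energy."""

    theta: np.ndarray  # [0, π), filament direction (minor eigenvector)
    coherency: np.ndarray  # (λ1 − λ2)/(λ1 + λ2) ∈ [0, 1]
    energy: np.ndarray  # λ1 + λ2 >= 0
    sigma_g: float
    sigma_w: float


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_filament_image(
    segments,
    shape: tuple[int, int] = (640, 640),
    width_px: float = 2.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    pixel_size: float = 0.1,
) -> FilamentImage:
    """Render Gaussian-profile ridges plus additive Gaussian noise.

    ``segments`` is a sequence of ((x0, y0), (x1, y1)) pixel coordinates.
    Negative intensities after noise are clipped at zero.  Deterministic for
    a fixed seed; ground truth (endpoints, orientation, length) is carried
    on the returned image.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rows, cols = shape
    img = np.zeros(shape, dtype=float)
    truth = []
    if len(segments) == 0:
        import warnings

        warnings.warn("empty segment list: rendering a blank image")
    yy, xx = np.mgrid[0:rows, 0:cols]
    for (x0, y0), (x1, y1) in segments:
        p0 = np.array([x0, y0], dtype=float)
        p1 = np.array([x1, y1], dtype=float)
        d = p1 - p0
        length = float(np.hypot(*d))
        theta = float(np.arctan2(d[1], d[0]) % np.pi)
        truth.append({"p0": p0.tolist(), "p1": p1.tolist(), "orientation": theta, "length": length})
        pad = int(np.ceil(4 * width_px)) + 2
        lo_x = max(0, int(min(x0, x1)) - pad)
        hi_x = min(cols, int(max(x0, x1)) + pad + 1)
        lo_y = max(0, int(min(y0, y1)) - pad)
        hi_y = min(rows, int(max(y0, y1)) + pad + 1)
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        X = xx[lo_y:hi_y, lo_x:hi_x]
        Y = yy[lo_y:hi_y, lo_x:hi_x]
        if length < 1e-12:
            dist2 = (X - p0[0]) ** 2 + (Y - p0[1]) ** 2
        else:
            t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / length**2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (X - (p0[0] + t * d[0])) ** 2 + (Y - (p0[1] + t * d[1])) ** 2
        img[lo_y:hi_y, lo_x:hi_x] += amplitude * np.exp(-dist2 / (2.0 * (width_px / 2.0) ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd * amplitude, size=shape)
    return FilamentImage(
        intensity=np.clip(img, 0.0, None), pixel_size=pixel_size, ground_truth=truth
    )


def sample_filament_segments(
    n: int,
    concentration: float,
    shape: tuple[int, int] = (640, 640),
    length_px: float = 60.0,
    seed: int = 0,
):
    """Random segments with nematic-distributed orientations, clipped to frame."""
    rng = np.random.default_rng(seed)
    theta = sample_orientations(n, concentration, rng)
    rows, cols = shape
    cx = rng.uniform(0, cols, n)
    cy = rng.uniform(0, rows, n)
    half = length_px / 2.0
    segs = []
    for i in range(n):
        dx, dy = np.cos(theta[i]) * half, np.sin(theta[i]) * half
        x0, y0 = np.clip(cx[i] - dx, 0, cols - 1), np.clip(cy[i] - dy, 0, rows - 1)
        x1, y1 = np.clip(cx[i] + dx, 0, cols - 1), np.clip(cy[i] + dy, 0, rows - 1)
        segs.append(((x0, y0), (x1, y1)))
    return segs


# ---------------------------------------------------------------------------
# structure tensor
# ---------------------------------------------------------------------------


def structure_tensor_field(
    image: FilamentImage | np.ndarray, sigma_g: float = 1.0, sigma_w: float = 4.0
) -> OrientationField:
    """Gradient structure tensor: orientation, coherency and energy per pixel.

    The image is smoothed at the gradient scale σ_g, the outer products of
    its gradients are windowed with a Gaussian of scale σ_w, and the tensor
    is eigen-decomposed.  The filament direction θ is the minor-eigenvector
    direction (gradients are perpendicular to ridges).  A constant image has
    zero energy everywhere and coherency defined as 0.
    """
    arr = image.intensity if isinstance(image, FilamentImage) else np.asarray(image, float)
    if sigma_g <= 0 or sigma_w <= 0:
        raise ValueError("sigma_g and sigma_w must be > 0")
    if min(arr.shape) < 4 * sigma_w:
        raise ValueError("image smaller than 4·sigma_w")
    smooth = gaussian_filter(arr, sigma_g)
    # nearest-edge padding: a constant image then has exactly zero gradients
    # (the default zero-padding manufactures spurious border energy)
    Arr, Arc, Acc = structure_tensor(smooth, sigma=sigma_w, mode="nearest", order="rc")
    # rows are y, cols are x: J_xx = Acc, J_xy = Arc, J_yy = Arr
    Jxx, Jxy, Jyy = Acc, Arc, Arr
    energy = Jxx + Jyy
    root = np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(energy > 0, root / np.where(energy > 0, energy, 1.0), 0.0)
    # major (gradient) eigenvector angle, then rotate by π/2 for the ridge
    major = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy)
    theta = (major + np.pi / 2.0) % np.pi
    return OrientationField(
        theta=theta,
        coherency=np.clip(coherency, 0.0, 1.0),
        energy=energy,
        sigma_g=sigma_g,
        sigma_w=sigma_w,
    )


def image_alignment_S(fieldv: OrientationField, mask: np.ndarray | None = None) -> float:
    """Alignment parameter S: energy × coherency-weighted nematic order.

    S = |Σ w·exp(2iθ)| / Σ w with w = energy · coherency over the mask;
    0 = disordered, 1 = perfectly aligned.
    """
    w = fieldv.energy * fieldv.coherency
    theta = fieldv.theta
    if mask is not None:
        mask = np.asarray(mask, bool)
        w = w[mask]
        theta = theta[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight (no oriented signal under the mask)")
    return float(np.abs(np.sum(w * np.exp(2j * theta))) / total)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_image(path: str | Path, pixel_size: float = 0.1) -> FilamentImage:
    """Read a 16-bit TIFF or 8-bit PNG as a float image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
    else:
        arr = np.asarray(Image.open(path).convert("I")).astype(float)
    return FilamentImage(intensity=arr, pixel_size=pixel_size)


def save_image(path: str | Path, image: FilamentImage) -> Path:
    """Write as 16-bit TIFF (intensity scaled to the full uint16 range)."""
    path = Path(path)
    arr = image.intensity
    peak = arr.max()
    scaled = (arr / peak * 65535.0).astype(np.uint16) if peak > 0 else arr.astype(np.uint16)
    tifffile.imwrite(path, scaled)
    return path


def save_orientation_field(path: str | Path, fieldv: OrientationField) -> Path:
    """Export θ/coherency/energy as a 3-channel float TIFF."""
    stack = np.stack([fieldv.theta, fieldv.coherency, fieldv.energy]).astype(np.float32)
    tifffile.imwrite(Path(path), stack)
    return Path(path)
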