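"""Structure-tensor orientation estimation and tissue masking.

The fiber direction at a pixel is the direction of *minimal* intensity
variation, i.e. the eigenvector of the smaller eigenvalue of the gradient
structure tensor.  Angles follow the package-wide convention: degrees in
[0, 180), measured from the +x (column) axis, counterclockwise with y
pointing *up* (toward decreasing row index).  Because fibers are unsigned
directors, θ and θ+180° are identified and all downstream statistics use
2θ trigonometry only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes


@dataclass
class Image2D:
    """A 2D grayscale intensity image with physical pixel size."""

    intensity: np.ndarray  # (rows, cols), nonnegative
    pixel_size_um: float  # μm per pixel

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D (rows, cols)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class StructureTensor:
    """Gaussian-windowed structure tensor components.

    Jxx = ⟨gx²⟩, Jxy = ⟨gx·gy⟩, Jyy = ⟨gy²⟩ where gx, gy are
    Gaussian-derivative gradients along columns and rows, and ⟨·⟩ is a
    Gaussian window average.  ``is_flat`` flags a constant input image
    (zero tensor everywhere).
    """

    Jxx: np.ndarray
    Jxy: np.ndarray
    Jyy: np.ndarray
    sigma_window_px: float
    pixel_size_um: float
    is_flat: bool = False


@dataclass
class OrientationField:
    """Per-pixel director angle, coherency and energy.

    theta_deg ∈ [0, 180); coherency ∈ [0, 1] ((λmax−λmin)/(λmax+λmin),
    0 where the tensor is isotropic or zero); energy = λmax+λmin ≥ 0.
    ``reliable`` is False where the tensor was exactly degenerate so the
    reported angle is arbitrary.
    """

    theta_deg: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    pixel_size_um: float
    sigma_window_px: float = 0.0
    reliable: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_deg.shape


@dataclass
class Mask:
    """Boolean tissue mask with its equivalent-circle diameter."""

    inside: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.inside.sum())

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * self.pixel_size_um * np.sqrt(self.area_px / np.pi)

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size_um: float) -> "Mask":
        return cls(np.ones(shape, dtype=bool), pixel_size_um)


def structure_tensor(
    image: Image2D,
    sigma_grad_um: float | None = None,
    sigma_window_um: float | None = None,
) -> StructureTensor:
    """Compute the Gaussian structure tensor of an intensity image.

    Parameters default to 1 px (gradient scale) and 4 px (window scale)
    expressed in μm via the image's pixel size.  A constant image yields
    a zero tensor flagged via ``is_flat`` rather than an error.
    """
    px = image.pixel_size_um
    sigma_grad_px = 1.0 if sigma_grad_um is None else sigma_grad_um / px
    sigma_window_px = 4.0 if sigma_window_um is None else sigma_window_um / px
    if sigma_grad_px <= 0 or sigma_window_px <= 0:
        raise ValueError("sigma values must be positive")

    I = image.intensity
    # gx: derivative along columns (+x), gy: derivative along rows (down)
    gx = ndimage.gaussian_filter(I, sigma_grad_px, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(I, sigma_grad_px, order=(1, 0), mode="nearest")

    Jxx = ndimage.gaussian_filter(gx * gx, sigma_window_px, mode="nearest")
    Jxy = ndimage.gaussian_filter(gx * gy, sigma_window_px, mode="nearest")
    Jyy = ndimage.gaussian_filter(gy * gy, sigma_window_px, mode="nearest")

    is_flat = bool(np.ptp(I) == 0)
    if is_flat:
        Jxx = np.zeros_like(I)
        Jxy = np.zeros_like(I)
        Jyy = np.zeros_like(I)
    return StructureTensor(Jxx, Jxy, Jyy, sigma_window_px, px, is_flat)


def orientation_from_tensor(tensor: StructureTensor) -> OrientationField:
    """Extract the director angle, coherency and energy from a tensor.

    The dominant eigenvector of J points along the intensity gradient
    (normal to fibers); the fiber angle is perpendicular to it, mapped
    into [0, 180) in the y-up convention.
    """
    Jxx, Jxy, Jyy = tensor.Jxx, tensor.Jxy, tensor.Jyy
    trace = Jxx + Jyy
    disc = np.sqrt(((Jxx - Jyy) * 0.5) ** 2 + Jxy**2)
    lam_max = trace * 0.5 + disc
    lam_min = trace * 0.5 - disc
    # Dominant (gradient) direction in row-down image coordinates.
    phi_grad = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy)
    # Fiber = perpendicular; flip sign to convert row-down to y-up.
    theta = np.mod(90.0 - np.degrees(phi_grad), 180.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(trace > 0, (lam_max - lam_min) / trace, 0.0)
    coherency = np.clip(coherency, 0.0, 1.0)
    reliable = disc > 0
    return OrientationField(
        theta_deg=theta,
        coherency=coherency,
        energy=np.maximum(trace, 0.0),
        pixel_size_um=tensor.pixel_size_um,
        sigma_window_px=tensor.sigma_window_px,
        reliable=reliable,
    )


def estimate_orientation(
    image: Image2D,
    sigma_grad_um: float | None = None,
    sigma_window_um: float | None = None,
) -> OrientationField:
    """Convenience: structure tensor + eigen-analysis in one call."""
    return orientation_from_tensor(
        structure_tensor(image, sigma_grad_um, sigma_window_um)
    )


def tissue_mask(
    image: Image2D,
    threshold_method: str = "otsu",
    min_hole_area_px: int = 64,
    smooth_sigma_px: float = 2.0,
) -> Mask:
    """Segment the aggregate from the background.

    Otsu threshold on a Gaussian-smoothed image, holes below
    ``min_hole_area_px`` filled, largest 8-connected component kept.
    Raises ValueError when nothing lies above the threshold.
    """
    smoothed = ndimage.gaussian_filter(image.intensity, smooth_sigma_px)
    if threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            raise ValueError("empty mask: image is constant")
        thr = threshold_otsu(smoothed)
    else:
        raise ValueError(f"unknown threshold method: {threshold_method}")
    binary = smoothed > thr
    if not binary.any():
        raise ValueError("empty mask: nothing above threshold")
    if min_hole_area_px > 0:
        binary = remove_small_holes(binary, max_size=min_hole_area_px)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty mask: no connected component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return Mask(labels == keep, image.pixel_size_um)


def analysis_mask(mask: Mask, orient: OrientationField, border_factor: float = 3.0) -> np.ndarray:
    """Valid-pixel mask for downstream averages.

    Erodes the tissue mask and trims the image frame by
    ``border_factor · sigma_window`` pixels: the tensor's Gaussian window
    is truncated there, so angles are biased.
    """
    r = int(np.ceil(border_factor * max(orient.sigma_window_px, 1.0)))
    valid = mask.inside.copy()
    if r > 0:
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        disk = (xx**2 + yy**2) <= r**2
        valid = ndimage.binary_erosion(valid, structure=disk)
        valid[:r, :] = False
        valid[-r:, :] = False
        valid[:, :r] = False
        valid[:, -r:] = False
    if orient.reliable is not None:
        valid &= orient.reliable
    return valid
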