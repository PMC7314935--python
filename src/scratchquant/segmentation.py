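"""Cell/media binarization via gradient-magnitude quantification.

Phase-contrast monolayers are textured (cell interiors and bright cell
rims) while the culture medium is optically flat.  The per-pixel gradient
magnitude of the Gaussian-smoothed intensity field is therefore high at
cell edges and within cells and near zero in cell-free medium.  The mask is
obtained by thresholding that gradient map — which by construction codes
edge pixels as cell — and then consolidating cell interiors with
morphological closing, hole filling, and small-object removal.

Convention: in a :class:`BinaryMask`, ``True`` = white = cell (positive
space) and ``False`` = black = media (negative space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from .io import GreyImage, ValidationError

__all__ = [
    "BinaryMask",
    "SegmentationParams",
    "gradient_magnitude",
    "threshold_gradient",
    "clean_mask",
    "binarize",
]


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel cell/media labelling (white=True=cell, black=False=media)."""

    pixels: np.ndarray
    condition: str = ""
    replicate: int = 1
    hour: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(f"mask must be non-empty 2D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def white_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def black_count(self) -> int:
        return int(self.pixels.size - self.pixels.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the binarization pipeline.

    smoothing_sigma
        Gaussian pre-smoothing scale in pixels (0 disables smoothing).
    threshold_method
        ``"otsu"`` (parameter-free, on the gradient-magnitude histogram) or
        ``"fixed"`` (uses ``fixed_threshold``, for reproducibility pinning).
    fixed_threshold
        Gradient-magnitude cut in [0, 1]-intensity units per pixel.
    closing_radius
        Disk radius (px) of the morphological closing that consolidates
        cell interiors.
    min_object_area
        White connected components smaller than this (px^2) are removed.
    fill_holes
        Whether enclosed black regions inside white objects become white.
    """

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.1
    closing_radius: int = 5
    min_object_area: int = 64
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValidationError("smoothing_sigma must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError(
                f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}"
            )
        if self.closing_radius < 0 or self.min_object_area < 0:
            raise ValidationError("closing_radius and min_object_area must be >= 0")

    def replace(self, **kwargs) -> "SegmentationParams":
        return replace(self, **kwargs)


def gradient_magnitude(image: GreyImage | np.ndarray, smoothing_sigma: float = 1.0) -> np.ndarray:
    """Euclidean magnitude of the smoothed intensity gradient.

    The image is Gaussian-smoothed at ``smoothing_sigma`` (skipped when 0),
    then differentiated with central differences (one-sided at the borders);
    the returned raster has the input's shape and is everywhere >= 0.
    """
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image, dtype=float)
    if smoothing_sigma < 0:
        raise ValidationError("smoothing_sigma must be >= 0")
    if smoothing_sigma > 0:
        px = ndimage.gaussian_filter(px, sigma=smoothing_sigma)
    gy, gx = np.gradient(px)
    return np.hypot(gy, gx)


def threshold_gradient(grad: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Raw (pre-cleanup) white mask from a gradient-magnitude raster.

    With Otsu, a single-valued magnitude histogram (blank image) degenerates;
    the mask falls back to all-black with a warning since media-only fields
    are legitimate inputs.
    """
    if params.threshold_method == "fixed":
        return grad > params.fixed_threshold
    if np.ptp(grad) == 0:
        warnings.warn(
            "gradient magnitude is single-valued (blank image); "
            "returning an all-black mask",
            stacklevel=2,
        )
        return np.zeros_like(grad, dtype=bool)
    return grad > threshold_otsu(grad)


def clean_mask(raw: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Morphological cleanup: closing -> hole fill -> small-object removal.

    Closing first bridges the narrow dark seams between adjacent cells, hole
    filling then turns enclosed intracellular flat zones white, and the area
    filter finally discards isolated specks.  The composite is idempotent.
    """
    mask = np.asarray(raw, dtype=bool)
    if params.closing_radius > 0:
        mask = closing(mask, disk(params.closing_radius)).astype(bool)
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if params.min_object_area > 0:
        # drop white components with area strictly below min_object_area
        mask = remove_small_objects(mask, max_size=params.min_object_area - 1)
    return mask


def binarize(image: GreyImage, params: SegmentationParams | None = None) -> BinaryMask:
    """Segment a GreyImage into a cell (white) / media (black) BinaryMask.

    Pipeline: gradient magnitude -> threshold (Otsu or fixed) -> closing ->
    optional hole filling -> small-object removal.  High-gradient (edge)
    pixels end up white; textureless media ends up black.
    """
    if params is None:
        params = SegmentationParams()
    if image.height < 2 or image.width < 2:
        raise ValidationError(
            f"image too small to segment: {image.height}x{image.width}"
        )
    grad = gradient_magnitude(image, params.smoothing_sigma)
    raw = threshold_gradient(grad, params)
    mask = clean_mask(raw, params)
    return BinaryMask(
        mask, condition=image.condition, replicate=image.replicate, hour=image.hour
    )
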