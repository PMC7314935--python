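"""Fluorescence readouts: spot counting in an ROI and area-fraction morphometry.

``count_spots`` is an automated replacement for manual counting of
fluorescently labelled cells (e.g. GFP-tagged neutrophils recruited to a
wound): multi-scale Laplacian-of-Gaussian blob detection restricted to a
user-supplied rectangular region of interest, with distance-based
non-maximum suppression.  The ROI must be supplied by the user (for
example a band of fixed width proximal to the wound edge) — what counts as
"at the wound" is an experimental, not algorithmic, choice.

``area_fraction`` is threshold morphometry for immunofluorescence stains:
the fraction of pixels above an intensity threshold, and that signal area
normalized per counterstained nucleus so that conditions with different
cell numbers can be compared as fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log

from .io import GreyImage, ValidationError

__all__ = [
    "RectROI",
    "SpotParams",
    "count_spots",
    "area_fraction",
]


@dataclass(frozen=True)
class RectROI:
    """Half-open rectangle [top, bottom) x [left, right) in pixel indices."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0 or self.top >= self.bottom or self.left >= self.right:
            raise ValidationError(
                f"invalid ROI [{self.top},{self.bottom}) x [{self.left},{self.right})"
            )

    def validate_within(self, image: GreyImage) -> None:
        if self.bottom > image.height or self.right > image.width:
            raise ValidationError(
                f"ROI [{self.top},{self.bottom}) x [{self.left},{self.right}) "
                f"outside {image.height}x{image.width} image"
            )

    def contains(self, row: float, col: float) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right


@dataclass(frozen=True)
class SpotParams:
    """Blob-detector settings, sized for ~5-15 px diameter somata.

    min_sigma/max_sigma bound the Laplacian-of-Gaussian scale search (px);
    detect_threshold is the minimum scale-normalized response on [0, 1]
    intensities; detections closer than min_separation (px) are merged,
    keeping the stronger.
    """

    min_sigma: float = 2.0
    max_sigma: float = 8.0
    detect_threshold: float = 0.05
    min_separation: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.min_sigma <= self.max_sigma:
            raise ValidationError("need 0 < min_sigma <= max_sigma")
        if self.detect_threshold <= 0:
            raise ValidationError("detect_threshold must be > 0")


def _log_response(pixels: np.ndarray, rows: np.ndarray, cols: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scale-normalized -LoG response at given points (peak strength proxy)."""
    resp = np.empty(rows.shape[0])
    for s in np.unique(sigmas):
        filtered = -(s**2) * ndimage.gaussian_laplace(pixels, sigma=s)
        sel = sigmas == s
        resp[sel] = filtered[rows[sel], cols[sel]]
    return resp


def count_spots(
    image: GreyImage, roi: RectROI, params: SpotParams | None = None
) -> tuple[int, np.ndarray]:
    """Count bright spots inside an ROI.

    Returns ``(count, spots)`` where ``spots`` is an ``(n, 3)`` array of
    ``(row, col, sigma)`` in whole-image coordinates.  Detection is
    multi-scale LoG blob detection on the ROI crop; maxima weaker than
    ``detect_threshold`` are discarded and maxima closer than
    ``min_separation`` are merged keeping the stronger response.
    """
    if params is None:
        params = SpotParams()
    roi.validate_within(image)
    crop = image.pixels[roi.top : roi.bottom, roi.left : roi.right]
    blobs = blob_log(
        crop,
        min_sigma=params.min_sigma,
        max_sigma=params.max_sigma,
        num_sigma=10,
        threshold=params.detect_threshold,
        overlap=1.0,  # suppression handled below, by distance
    )
    if blobs.shape[0] == 0:
        return 0, np.empty((0, 3))
    rows = blobs[:, 0].astype(int)
    cols = blobs[:, 1].astype(int)
    sigmas = blobs[:, 2]
    strength = _log_response(crop, rows, cols, sigmas)

    # distance-based non-maximum suppression, strongest first
    order = np.argsort(strength)[::-1]
    kept: list[int] = []
    for i in order:
        pi = np.array([rows[i], cols[i]])
        if all(
            np.hypot(*(pi - np.array([rows[j], cols[j]]))) >= params.min_separation
            for j in kept
        ):
            kept.append(i)
    kept_arr = np.array(sorted(kept))
    spots = np.column_stack(
        [rows[kept_arr] + roi.top, cols[kept_arr] + roi.left, sigmas[kept_arr]]
    ).astype(float)
    return spots.shape[0], spots


def area_fraction(
    image: GreyImage, signal_threshold: float, nuclei_count: int
) -> tuple[float, float]:
    """Above-threshold area fraction and per-nucleus signal area.

    Returns ``(fraction, per_nucleus)`` with ``fraction`` = pixels above
    ``signal_threshold`` / total pixels and ``per_nucleus`` = above-threshold
    pixel count / ``nuclei_count``.  Fold change between two conditions is
    the ratio of their per-nucleus values.
    """
    if not 0 < signal_threshold < 1:
        raise ValidationError(f"signal_threshold must be in (0, 1), got {signal_threshold}")
    if nuclei_count < 1:
        raise ValidationError(f"nuclei_count must be >= 1, got {nuclei_count}")
    above = int(np.count_nonzero(image.pixels > signal_threshold))
    return above / image.pixels.size, above / nuclei_count
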