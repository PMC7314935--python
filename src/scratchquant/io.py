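"""Raster image and experiment-manifest input/output.

All images are normalized on load into :class:`GreyImage` records: 2D
float64 intensity rasters on ``[0, 1]``, regardless of source bit depth,
with acquisition metadata (condition label, replicate id, hour post-scratch)
attached.  RGB inputs are collapsed to grey with Rec. 709 luminance weights.

A batch of images is described by a :class:`Manifest`, a CSV with columns
``path, condition, replicate, hour``.  Every replicate series must include
an hour-0 entry because the disruption center used for profile alignment is
defined at hour 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GreyImage",
    "Manifest",
    "ManifestEntry",
    "ValidationError",
    "load_image",
    "save_image",
    "load_manifest",
    "write_manifest",
]

#: Rec. 709 luminance weights used for RGB -> grey conversion.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

MANIFEST_COLUMNS = ("path", "condition", "replicate", "hour")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GreyImage:
    """A single-channel intensity image with acquisition metadata.

    Attributes
    ----------
    pixels
        2D float array, shape ``(height, width)``, intensities in ``[0, 1]``.
        Coordinates are 0-based ``(row, column)``; columns increase rightward.
    condition
        Free-text experimental condition label.
    replicate
        Positive integer replicate id.
    hour
        Non-negative time post-scratch, in hours.
    """

    pixels: np.ndarray
    condition: str = ""
    replicate: int = 1
    hour: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(
                f"image must be a non-empty 2D raster, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValidationError("image intensities must be finite and >= 0")
        if self.replicate < 1:
            raise ValidationError(f"replicate id must be >= 1, got {self.replicate}")
        if self.hour < 0:
            raise ValidationError(f"hour must be >= 0, got {self.hour}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_meta(self, **kwargs) -> "GreyImage":
        """Return a copy with updated metadata fields."""
        return replace(self, **kwargs)


def _to_grey(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) array to 2D grey via Rec. 709 luminance."""
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3].astype(float)
        return rgb @ LUMA_WEIGHTS
    raise ValidationError(f"unsupported image shape {arr.shape}")


def _rescale(arr: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Map integer rasters onto [0, 1] by their dtype range; clip floats."""
    if np.issubdtype(dtype, np.integer):
        return arr / float(np.iinfo(dtype).max)
    return np.clip(arr, 0.0, 1.0)


def load_image(
    path: str | os.PathLike,
    condition: str = "",
    replicate: int = 1,
    hour: float = 0.0,
) -> GreyImage:
    """Load a TIFF or PNG image as a normalized :class:`GreyImage`.

    RGB(A) inputs are converted to grey with Rec. 709 luminance weights
    (0.2126 R + 0.7152 G + 0.0722 B); integer intensities are rescaled to
    ``[0, 1]`` by the dtype maximum.  Dimensions are preserved.

    Raises
    ------
    IOError
        If the file cannot be read; the message names the path.
    ValidationError
        If the decoded raster is zero-sized or has an unsupported layout.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    grey = _rescale(_to_grey(raw), raw.dtype)
    return GreyImage(grey, condition=condition, replicate=replicate, hour=hour)


def save_image(image: GreyImage, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a GreyImage to TIFF or PNG (by extension) at 8 or 16 bits.

    Quantization to the stored bit depth is round-to-nearest; reloading the
    written file reproduces the stored integers bit-exactly.
    """
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    vmax = np.iinfo(dtype).max
    quant = np.rint(np.clip(image.pixels, 0.0, 1.0) * vmax).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    else:
        iio.imwrite(path, quant)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    condition: str
    replicate: int
    hour: float


@dataclass
class Manifest:
    """Validated list of image records, sorted by (condition, replicate, hour)."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (e.condition, e.replicate, e.hour)
        )
        seen: set[tuple] = set()
        for e in self.entries:
            key = (e.condition, e.replicate, e.hour)
            if key in seen:
                raise ValidationError(
                    f"duplicate manifest entry for condition={e.condition!r} "
                    f"replicate={e.replicate} hour={e.hour}"
                )
            seen.add(key)
        missing = [
            f"{cond!r}/replicate {rep}"
            for (cond, rep), hours in self._series().items()
            if 0.0 not in hours
        ]
        if missing:
            raise ValidationError(
                "replicate series missing the required hour-0 entry: "
                + ", ".join(missing)
            )

    def _series(self) -> dict[tuple[str, int], set[float]]:
        series: dict[tuple[str, int], set[float]] = {}
        for e in self.entries:
            series.setdefault((e.condition, e.replicate), set()).add(e.hour)
        return series

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def conditions(self) -> list[str]:
        return sorted({e.condition for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.path, e.condition, e.replicate, e.hour) for e in self.entries],
            columns=list(MANIFEST_COLUMNS),
        )


def load_manifest(path: str | os.PathLike) -> Manifest:
    """Read and validate a CSV manifest (columns path, condition, replicate, hour)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty manifest file: {path}") from exc
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"manifest {path} missing required columns: {missing_cols}"
        )
    if len(df) == 0:
        raise ValidationError(f"manifest {path} contains no entries")
    entries = [
        ManifestEntry(
            path=str(row["path"]),
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
            hour=float(row["hour"]),
        )
        for _, row in df.iterrows()
    ]
    return Manifest(entries)


def write_manifest(manifest: Manifest | Sequence[ManifestEntry], path: str | os.PathLike) -> None:
    """Write a manifest as CSV with the fixed header."""
    if not isinstance(manifest, Manifest):
        manifest = Manifest(list(manifest))
    manifest.to_frame().to_csv(path, index=False)
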