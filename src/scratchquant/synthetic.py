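"""Synthetic microscopy images with planted ground truth.

Two generators back the test and benchmark fixtures:

* :func:`generate_scratch_series` renders phase-contrast-like monolayers —
  overlapping textured ellipses ("cells") with bright rims on a flat darker
  background — with a planted vertical scratch gap of known center and
  width, and a closure time course in which cells re-occupy the gap from
  its edges inward until a planted per-hour fill fraction is reached.
* :func:`generate_spot_image` renders a fluorescence field: isotropic
  Gaussian bumps of known centers on a constant background.

Both emit a :class:`SyntheticTruth` record next to every image (per-pixel
cell mask, gap geometry, exact spot centers) so every downstream stage can
be scored against planted truth.  A single integer seed governs all
stochastic draws; per-image sub-streams are derived deterministically, so
identical parameters and seed give bit-identical rasters.

Cells are drawn with interior speckle texture and bright rims
deliberately: gradient-magnitude segmentation keys on texture and edges,
and featureless flat cells would be misclassified by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import GreyImage, ValidationError

__all__ = [
    "ScratchSimParams",
    "SyntheticTruth",
    "generate_scratch_series",
    "generate_spot_image",
]

# rendering levels (intensity units on [0, 1]); chosen so media is flat and
# dark, cell interiors are mid-grey and textured, and rims are bright
_BACKGROUND = 0.40
_CELL_BASE = 0.50
_CELL_SHADE = 0.06  # per-cell uniform shading half-range
_RIM_LEVEL = 0.75
_RIM_INNER = 0.80  # rim occupies normalized radius [_RIM_INNER, 1]


@dataclass(frozen=True)
class ScratchSimParams:
    """Conditions of a simulated scratch-assay series.

    The defaults mirror a typical acquisition: a 1600x1200 field with a
    ~200-column central scratch, imaged at 0/24/48 h while cells migrate
    in from the gap edges (half the gap area occupied by 24 h, 90% by
    48 h), with mild sensor noise.
    """

    width: int = 1600
    height: int = 1200
    gap_center: int = 800
    gap_width_0: int = 200
    #: hour -> fraction of the hour-0 gap area occupied by cells
    fill_fraction: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 24.0: 0.5, 48.0: 0.9}
    )
    cell_density: float = 25.0  # cells per 10^4 px^2
    cell_radius_range: tuple[float, float] = (14.0, 22.0)
    texture_contrast: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0
    condition: str = "sim"
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.gap_width_0 < self.width:
            raise ValidationError("need 0 < gap_width_0 < width")
        hours = sorted(self.fill_fraction)
        if not hours or hours[0] != 0 or self.fill_fraction[hours[0]] != 0:
            raise ValidationError("fill_fraction must include hour 0 with value 0")
        fills = [self.fill_fraction[h] for h in hours]
        if any(not 0 <= f <= 1 for f in fills) or any(
            b < a for a, b in zip(fills, fills[1:])
        ):
            raise ValidationError("fill_fraction must be in [0,1] and non-decreasing")
        if self.cell_density <= 0:
            raise ValidationError("cell_density must be positive")
        spacing = float(np.sqrt(1e4 / self.cell_density))
        rmin, rmax = self.cell_radius_range
        if not 0 < rmin <= rmax:
            raise ValidationError("cell_radius_range must satisfy 0 < min <= max")
        if spacing > 2 * rmin:
            raise ValidationError(
                f"infeasible density: spacing {spacing:.1f} px exceeds cell "
                f"diameter {2 * rmin:.1f} px — cells cannot tile the monolayer"
            )
        if self.noise_sd < 0 or self.texture_contrast < 0:
            raise ValidationError("noise_sd and texture_contrast must be >= 0")

    @property
    def gap_left(self) -> int:
        return self.gap_center - self.gap_width_0 // 2

    @property
    def gap_right(self) -> int:
        return self.gap_left + self.gap_width_0

    @property
    def hours(self) -> list[float]:
        return sorted(self.fill_fraction)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated image."""

    hour: float = 0.0
    gap_mask: np.ndarray | None = None  # True inside the hour-0 gap band
    cell_mask: np.ndarray | None = None  # True where a cell pixel was drawn
    gap_center: int | None = None
    gap_width: int | None = None
    occupied_fraction_in_gap: float | None = None
    spot_centers: np.ndarray | None = None  # (n, 2) float (row, col)
    min_spot_separation: float | None = None


@dataclass(frozen=True)
class _Cell:
    row: float
    col: float
    a: float  # semi-axis
    b: float
    theta: float
    shade: float
    rim_delta: float


def _cell_field(params: ScratchSimParams) -> list[_Cell]:
    """Jittered-grid candidate cells covering the whole canvas.

    The grid spacing follows cell_density; radii exceed the spacing so
    neighbouring ellipses overlap and the union covers its region with only
    small interstitial holes.  The list is a fixed function of the seed, so
    the monolayer looks identical across the hours of one series.
    """
    rng = np.random.default_rng([params.seed, 101])
    spacing = float(np.sqrt(1e4 / params.cell_density))
    rmin, rmax = params.cell_radius_range
    rows = np.arange(-spacing, params.height + spacing, spacing)
    cols = np.arange(-spacing, params.width + spacing, spacing)
    cells = []
    for r0 in rows:
        for c0 in cols:
            jr, jc = rng.uniform(-0.45 * spacing, 0.45 * spacing, size=2)
            a, b = rng.uniform(rmin, rmax, size=2)
            cells.append(
                _Cell(
                    row=r0 + jr,
                    col=c0 + jc,
                    a=a,
                    b=b,
                    theta=rng.uniform(0, np.pi),
                    shade=rng.uniform(-_CELL_SHADE, _CELL_SHADE),
                    rim_delta=rng.uniform(-0.03, 0.03),
                )
            )
    return cells


def _allowed_columns(params: ScratchSimParams, fill: float) -> np.ndarray:
    """Boolean per-column mask of where cells may exist at a given fill.

    Outside the gap always; inside the gap, two bands growing inward from
    the gap edges whose combined width is ``fill`` x gap width (migration
    from the wound margins).
    """
    allowed = np.ones(params.width, dtype=bool)
    allowed[params.gap_left : params.gap_right] = False
    band = int(round(fill * params.gap_width_0 / 2.0))
    if band > 0:
        allowed[params.gap_left : params.gap_left + band] = True
        allowed[params.gap_right - band : params.gap_right] = True
    return allowed


def _render(
    params: ScratchSimParams,
    cells: list[_Cell],
    allowed_cols: np.ndarray,
    speckle: np.ndarray,
    noise_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cells clipped to the allowed columns; return (image, cell_mask)."""
    h, w = params.height, params.width
    canvas = np.full((h, w), _BACKGROUND)
    cell_mask = np.zeros((h, w), dtype=bool)
    # columns along a clip boundary (<= 2 px from a disallowed column): cells
    # cut there present a membrane edge, rendered bright like any cell rim
    face_cols = np.zeros(w, dtype=bool)
    for off in (1, 2):
        face_cols[off:] |= allowed_cols[off:] & ~allowed_cols[:-off]
        face_cols[:-off] |= allowed_cols[:-off] & ~allowed_cols[off:]
    for cell in cells:
        rad = max(cell.a, cell.b)
        r0 = max(int(cell.row - rad) - 1, 0)
        r1 = min(int(cell.row + rad) + 2, h)
        c0 = max(int(cell.col - rad) - 1, 0)
        c1 = min(int(cell.col + rad) + 2, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy = yy - cell.row
        dx = xx - cell.col
        ct, st = np.cos(cell.theta), np.sin(cell.theta)
        u = (dx * ct + dy * st) / cell.a
        v = (-dx * st + dy * ct) / cell.b
        d2 = u * u + v * v
        inside = (d2 <= 1.0) & allowed_cols[np.newaxis, c0:c1]
        if not inside.any():
            continue
        patch_canvas = canvas[r0:r1, c0:c1]
        patch_canvas[inside] = _CELL_BASE + cell.shade
        rim = inside & ((d2 >= _RIM_INNER**2) | face_cols[np.newaxis, c0:c1])
        patch_canvas[rim] = _RIM_LEVEL + cell.rim_delta
        cell_mask[r0:r1, c0:c1] |= inside
    canvas[cell_mask] += params.texture_contrast * 0.4 * speckle[cell_mask]
    if params.noise_sd > 0:
        canvas = canvas + noise_rng.normal(0.0, params.noise_sd, size=(h, w))
    return np.clip(canvas, 0.0, 1.0), cell_mask


def generate_scratch_series(
    params: ScratchSimParams,
) -> list[tuple[GreyImage, SyntheticTruth]]:
    """Simulate one replicate's scratch-closure time course.

    Returns one ``(GreyImage, SyntheticTruth)`` pair per hour in
    ``params.fill_fraction``, in hour order.  The hour-0 gap band is
    cell-free by construction; the truth occupied fraction is recomputed
    exactly from the emitted cell mask.
    """
    cells = _cell_field(params)
    spk_rng = np.random.default_rng([params.seed, 202])
    speckle = ndimage.gaussian_filter(
        spk_rng.standard_normal((params.height, params.width)), sigma=1.5
    )
    speckle /= speckle.std()

    gap_mask = np.zeros((params.height, params.width), dtype=bool)
    gap_mask[:, params.gap_left : params.gap_right] = True
    gap_area = int(gap_mask.sum())

    out = []
    for hidx, hour in enumerate(params.hours):
        fill = params.fill_fraction[hour]
        allowed = _allowed_columns(params, fill)
        noise_rng = np.random.default_rng([params.seed, 303, hidx])
        pixels, cell_mask = _render(params, cells, allowed, speckle, noise_rng)
        image = GreyImage(
            pixels,
            condition=params.condition,
            replicate=params.replicate,
            hour=hour,
        )
        truth = SyntheticTruth(
            hour=hour,
            gap_mask=gap_mask,
            cell_mask=cell_mask,
            gap_center=params.gap_center,
            gap_width=params.gap_width_0,
            occupied_fraction_in_gap=float((cell_mask & gap_mask).sum() / gap_area),
        )
        out.append((image, truth))
    return out


def generate_spot_image(
    width: int = 512,
    height: int = 512,
    n_spots: int = 25,
    spot_centers: np.ndarray | None = None,
    spot_sigma: float = 3.0,
    peak: float = 0.8,
    background: float = 0.1,
    noise_sd: float = 0.02,
    min_separation: float = 30.0,
    margin: float = 20.0,
    seed: int = 0,
) -> tuple[GreyImage, SyntheticTruth]:
    """Simulate a fluorescence field of isotropic Gaussian spots.

    Centers may be supplied explicitly; otherwise ``n_spots`` centers are
    drawn uniformly, rejecting candidates closer than ``min_separation`` to
    an accepted one or within ``margin`` of the border.  The image is the
    sum of Gaussian bumps of amplitude ``peak`` on a constant background,
    plus optional Gaussian noise.
    """
    if spot_sigma <= 0:
        raise ValidationError("spot_sigma must be positive")
    rng = np.random.default_rng([seed, 404])
    if spot_centers is None:
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < n_spots:
            attempts += 1
            if attempts > 10000 * max(n_spots, 1):
                raise ValidationError(
                    f"cannot place {n_spots} spots with separation "
                    f"{min_separation} in a {height}x{width} field"
                )
            r = rng.uniform(margin, height - margin)
            c = rng.uniform(margin, width - margin)
            if all(np.hypot(r - r2, c - c2) >= min_separation for r2, c2 in centers):
                centers.append((r, c))
        spot_centers = np.array(centers).reshape(-1, 2)
    else:
        spot_centers = np.asarray(spot_centers, dtype=float).reshape(-1, 2)
        if spot_centers.size and (
            spot_centers.min() < 0
            or spot_centers[:, 0].max() >= height
            or spot_centers[:, 1].max() >= width
        ):
            raise ValidationError("spot centers must lie within the image")

    pixels = np.full((height, width), float(background))
    yy = np.arange(height)[:, None]
    xx = np.arange(width)[None, :]
    for r, c in spot_centers:
        # local patch only; the bump is negligible beyond 5 sigma
        ext = int(np.ceil(5 * spot_sigma))
        r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, height)
        c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, width)
        d2 = (yy[r0:r1] - r) ** 2 + (xx[:, c0:c1] - c) ** 2
        pixels[r0:r1, c0:c1] += peak * np.exp(-d2 / (2 * spot_sigma**2))
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=(height, width))
    pixels = np.clip(pixels, 0.0, 1.0)

    if spot_centers.shape[0] >= 2:
        from scipy.spatial.distance import pdist

        min_sep = float(pdist(spot_centers).min())
    else:
        min_sep = np.inf
    truth = SyntheticTruth(
        spot_centers=spot_centers, min_spot_separation=min_sep
    )
    return GreyImage(pixels), truth
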