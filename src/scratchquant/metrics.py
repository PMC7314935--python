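"""Scalar wound-healing endpoints: gap width, closure, cell-to-space ratio.

The initial (hour-0) disruption region is the maximal contiguous run of
near-all-black columns containing the detected center.  All later-hour
endpoints are anchored to that region: gap width is re-measured around the
replicate's own hour-0 center, and the cell-to-space ratio counts white vs
black pixels restricted to the hour-0 region's columns — quantifying how
much of the original wound has been re-occupied by cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .profiling import ColumnProfile
from .segmentation import BinaryMask

__all__ = [
    "GapRegion",
    "GapMetrics",
    "DEFAULT_GAP_THRESHOLD",
    "gap_region_from_t0",
    "gap_width",
    "cell_to_space_ratio",
    "gap_metrics",
]

#: columns with black_fraction >= this count as part of the gap; slightly
#: below 1.0 so a few stray white pixels do not fragment the run
DEFAULT_GAP_THRESHOLD = 0.95


@dataclass(frozen=True)
class GapRegion:
    """Half-open column interval [left, right) of the hour-0 disruption."""

    left: int
    right: int
    source_hour: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.left < self.right:
            raise ValidationError(
                f"invalid gap region [{self.left}, {self.right})"
            )
        if self.source_hour != 0:
            raise ValidationError("gap region must derive from the hour-0 profile")

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class GapMetrics:
    """Endpoints for one (condition, replicate, hour)."""

    condition: str
    replicate: int
    hour: float
    gap_width_px: int
    closure_percent: float
    cell_to_space_ratio: float  # inf when the region holds no black pixel
    occupied_fraction: float


def _run_around(bf: np.ndarray, center: int, threshold: float) -> tuple[int, int] | None:
    """Maximal contiguous run of bf >= threshold containing `center`, or None."""
    if np.isnan(bf[center]) or bf[center] < threshold:
        return None
    above = bf >= threshold
    left = center
    while left > 0 and above[left - 1]:
        left -= 1
    right = center + 1
    n = bf.shape[0]
    while right < n and above[right]:
        right += 1
    return left, right


def gap_region_from_t0(
    profile0: ColumnProfile, threshold: float = DEFAULT_GAP_THRESHOLD
) -> GapRegion:
    """Hour-0 disruption region: the thresholded run containing the center.

    Raises
    ------
    ValidationError
        If the profile has no detected center, the threshold is outside
        (0, 1], or the center column itself is below the threshold.
    """
    if profile0.hour != 0:
        raise ValidationError("gap region requires the hour-0 profile")
    if profile0.center is None:
        raise ValidationError("profile has no detected center; run find_gap_center")
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    run = _run_around(profile0.black_fraction, profile0.center, threshold)
    if run is None:
        raise ValidationError(
            f"no gap at center: black_fraction[{profile0.center}] below {threshold}"
        )
    return GapRegion(left=run[0], right=run[1], source_hour=0.0)


def gap_width(
    profile: ColumnProfile,
    center: int | None = None,
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> int:
    """Width (columns) of the thresholded gap run at this profile's hour.

    ``center`` defaults to the profile's own center and, for t > 0 profiles,
    should be the center inherited from the replicate's hour-0 profile.
    Returns 0 when the column at the anchoring center is below threshold
    (gap closed there).
    """
    if center is None:
        center = profile.center
    if center is None:
        raise ValidationError("gap_width needs a center (own or inherited)")
    if not 0 <= center < profile.width:
        raise ValidationError(f"center {center} outside profile width {profile.width}")
    run = _run_around(profile.black_fraction, center, threshold)
    return 0 if run is None else run[1] - run[0]


def cell_to_space_ratio(mask: BinaryMask, region: GapRegion) -> tuple[float, float]:
    """White:black pixel ratio and occupied fraction within a gap region.

    Counts are restricted to columns ``[region.left, region.right)`` over
    all rows.  The ratio is ``inf`` when the region holds no black pixel
    (fully occupied); ``occupied_fraction`` = white / (white + black) is
    always defined and satisfies ``ratio / (1 + ratio)`` wherever the ratio
    is finite.
    """
    if region.right > mask.width:
        raise ValidationError(
            f"region [{region.left}, {region.right}) exceeds mask width {mask.width}"
        )
    sub = mask.pixels[:, region.left : region.right]
    white = int(sub.sum())
    black = int(sub.size - white)
    ratio = np.inf if black == 0 else white / black
    return ratio, white / sub.size


def gap_metrics(
    mask: BinaryMask,
    profile: ColumnProfile,
    region0: GapRegion,
    width0: int,
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> GapMetrics:
    """Assemble all endpoints for one time point of one replicate.

    ``region0``/``width0`` come from the replicate's hour-0 profile; the
    hour-0 row has closure 0 by construction.
    """
    center0 = (region0.left + region0.right - 1) // 2
    w = gap_width(profile, center=center0, threshold=threshold)
    closure = 0.0 if profile.hour == 0 else 100.0 * (1.0 - w / width0)
    ratio, occ = cell_to_space_ratio(mask, region0)
    return GapMetrics(
        condition=mask.condition,
        replicate=mask.replicate,
        hour=mask.hour,
        gap_width_px=w,
        closure_percent=closure,
        cell_to_space_ratio=ratio,
        occupied_fraction=occ,
    )
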