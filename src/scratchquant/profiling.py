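"""Column-wise black/white profiles, disruption-center alignment, averaging.

The migration statistic is computed per image column: the fraction of black
(media) pixels in each column, and the black-to-white (B/W) pixel ratio.
At hour 0 the scratch appears as a run of all-black columns; its center
column defines the disruption center.  Replicate profiles are re-centered
onto a common axis by an integer column shift so that profiles from
different fields — with the scratch at different positions — can be
averaged and compared across time points.

``black_fraction`` (bounded in [0, 1]) is the primary per-column statistic
and the one that is averaged; ``bw_ratio`` is reported alongside it, with
``+inf`` marking columns that contain no white pixel (the ratio is finite
exactly where black_fraction < 1) — such entries are excluded from any
averaging because unbounded ratios are ill-conditioned to average and the
centering column is by definition the white = 0 case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ValidationError
from .segmentation import BinaryMask

__all__ = [
    "ColumnProfile",
    "AlignedHourProfile",
    "AlignedProfileSet",
    "NoDisruptionError",
    "column_profile",
    "find_gap_center",
    "recenter",
    "average_profiles",
]

#: window (columns) of the moving average used when no all-black column exists
_CENTER_SMOOTH_WINDOW = 51


class NoDisruptionError(ValueError):
    """Raised when an hour-0 profile shows no detectable disruption."""


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column black statistics of one binarized image.

    ``black_fraction[c]`` = black pixels in column ``c`` / column height;
    ``bw_ratio[c]`` = black / white pixels in column ``c`` (``+inf`` when
    white = 0).  On a re-centered common axis, columns with no source data
    are NaN in both vectors.  ``center`` is the detected (or inherited)
    disruption-center column, if any.
    """

    black_fraction: np.ndarray
    bw_ratio: np.ndarray
    hour: float = 0.0
    replicate: int = 1
    condition: str = ""
    center: int | None = None

    def __post_init__(self) -> None:
        bf = np.asarray(self.black_fraction, dtype=float)
        bw = np.asarray(self.bw_ratio, dtype=float)
        if bf.ndim != 1 or bf.shape != bw.shape:
            raise ValidationError("profile vectors must be 1D and equally long")
        valid = ~np.isnan(bf)
        if np.any((bf[valid] < 0) | (bf[valid] > 1)):
            raise ValidationError("black_fraction entries must lie in [0, 1]")
        object.__setattr__(self, "black_fraction", bf)
        object.__setattr__(self, "bw_ratio", bw)

    @property
    def width(self) -> int:
        return self.black_fraction.shape[0]

    def with_center(self, center: int) -> "ColumnProfile":
        return replace(self, center=center)


def column_profile(mask: BinaryMask) -> ColumnProfile:
    """Compute per-column black fraction and B/W ratio from a mask."""
    white = mask.pixels.sum(axis=0).astype(float)
    height = float(mask.height)
    black = height - white
    with np.errstate(divide="ignore"):
        bw = np.where(white > 0, black / np.maximum(white, 1e-300), np.inf)
        bw[white > 0] = black[white > 0] / white[white > 0]
    return ColumnProfile(
        black_fraction=black / height,
        bw_ratio=bw,
        hour=mask.hour,
        replicate=mask.replicate,
        condition=mask.condition,
    )


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a 1D boolean array."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def find_gap_center(profile: ColumnProfile) -> int:
    """Locate the disruption center in an hour-0 profile.

    If all-black columns (black_fraction == 1) exist, returns the midpoint
    of the longest contiguous run of them (lower median for even-length
    runs; first run wins a length tie).  Otherwise falls back, with a
    warning, to the argmax of the 51-column moving average of
    black_fraction.

    Raises
    ------
    NoDisruptionError
        If the maximum black_fraction is below 0.5 — no credible scratch.
    """
    if profile.hour != 0:
        raise ValidationError(
            f"gap center must be located on an hour-0 profile, got hour {profile.hour}"
        )
    bf = profile.black_fraction
    if np.nanmax(bf) < 0.5:
        raise NoDisruptionError(
            f"no detectable disruption: max black_fraction {np.nanmax(bf):.3f} < 0.5"
        )
    runs = _runs_of(bf >= 1.0)
    if runs:
        start, stop = max(runs, key=lambda r: r[1] - r[0])
        return (start + stop - 1) // 2  # lower median of [start, stop)
    warnings.warn(
        "no all-black column at hour 0; falling back to smoothed argmax "
        "of black_fraction",
        stacklevel=2,
    )
    kernel = np.ones(_CENTER_SMOOTH_WINDOW) / _CENTER_SMOOTH_WINDOW
    smoothed = np.convolve(np.nan_to_num(bf), kernel, mode="same")
    return int(np.argmax(smoothed))


def recenter(
    profile: ColumnProfile,
    center: int,
    target_center: int,
    target_width: int,
) -> ColumnProfile:
    """Shift a profile so ``center`` lands on ``target_center``.

    The shift is an integer number of columns (no interpolation).  Source
    columns shifted outside ``[0, target_width)`` are dropped; target
    columns with no source column are NaN (missing), never zero-filled.
    """
    if target_width <= 0:
        raise ValidationError(f"target_width must be positive, got {target_width}")
    if not 0 <= center < profile.width:
        raise ValidationError(
            f"center {center} outside profile of width {profile.width}"
        )
    shift = target_center - center
    bf = np.full(target_width, np.nan)
    bw = np.full(target_width, np.nan)
    src = np.arange(profile.width)
    dst = src + shift
    keep = (dst >= 0) & (dst < target_width)
    bf[dst[keep]] = profile.black_fraction[src[keep]]
    bw[dst[keep]] = profile.bw_ratio[src[keep]]
    return ColumnProfile(
        black_fraction=bf,
        bw_ratio=bw,
        hour=profile.hour,
        replicate=profile.replicate,
        condition=profile.condition,
        center=target_center,
    )


@dataclass(frozen=True)
class AlignedHourProfile:
    """Replicate-averaged profile for one time point on the common axis.

    ``mean_black_fraction``/``dispersion`` (standard error) are NaN where no
    replicate contributes; ``n_replicates`` is 0 there.  ``mean_bw_ratio``
    averages only finite ratio entries.
    """

    hour: float
    mean_black_fraction: np.ndarray
    dispersion: np.ndarray
    n_replicates: np.ndarray
    mean_bw_ratio: np.ndarray
    target_center: int
    target_width: int
    condition: str = ""


@dataclass
class AlignedProfileSet:
    """Per-hour averaged profiles of one condition on a shared centered axis."""

    target_center: int
    target_width: int
    condition: str = ""
    by_hour: dict[float, AlignedHourProfile] = field(default_factory=dict)

    @property
    def hours(self) -> list[float]:
        return sorted(self.by_hour)

    def add(self, entry: AlignedHourProfile) -> None:
        if entry.target_width != self.target_width:
            raise ValidationError("axis width mismatch in AlignedProfileSet")
        self.by_hour[entry.hour] = entry


def average_profiles(profiles: list[ColumnProfile]) -> AlignedHourProfile:
    """Average re-centered replicate profiles sharing one time point.

    Per column: mean of black_fraction over contributing (non-NaN)
    replicates, the standard error of that mean (0 where a single replicate
    contributes), and the contributing-replicate count.  B/W ratios are
    averaged over finite entries only.
    """
    if not profiles:
        raise ValidationError("cannot average an empty profile list")
    hours = {p.hour for p in profiles}
    if len(hours) > 1:
        raise ValidationError(f"profiles mix hours {sorted(hours)}")
    widths = {p.width for p in profiles}
    if len(widths) > 1:
        raise ValidationError("profiles must share a common axis width")
    centers = {p.center for p in profiles}
    if len(centers) > 1:
        raise ValidationError("profiles must share a common target center")

    bf = np.vstack([p.black_fraction for p in profiles])
    n = np.sum(~np.isnan(bf), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(bf, axis=0)
        sd = np.nanstd(bf, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.where(n == 1, 0.0, np.nan))

    bw = np.vstack([p.bw_ratio for p in profiles])
    bw_valid = np.isfinite(bw)
    bw_sum = np.where(bw_valid, bw, 0.0).sum(axis=0)
    bw_n = bw_valid.sum(axis=0)
    mean_bw = np.where(bw_n > 0, bw_sum / np.maximum(bw_n, 1), np.nan)

    p0 = profiles[0]
    return AlignedHourProfile(
        hour=p0.hour,
        mean_black_fraction=mean,
        dispersion=sem,
        n_replicates=n,
        mean_bw_ratio=mean_bw,
        target_center=p0.center if p0.center is not None else p0.width // 2,
        target_width=p0.width,
        condition=p0.condition,
    )
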