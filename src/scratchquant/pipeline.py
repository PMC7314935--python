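"""End-to-end orchestration: manifest in, tables/plots/report out.

``run_scratch_pipeline`` executes the full migration analysis: every image
is segmented and profiled; each replicate is centered on its hour-0
disruption column and all its hours are re-centered onto a common axis;
profiles are averaged per condition and hour; gap metrics are tabulated per
(condition, replicate, hour); and conditions are compared statistically per
hour.  ``run_spot_pipeline`` does the same orchestration for ROI spot
counts.  All CSV numbers are written with 6 significant digits so reruns
with identical inputs are byte-identical; each run writes its effective
configuration and a provenance log next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from .fluoro import RectROI, SpotParams, count_spots
from .io import Manifest, ValidationError, load_image, load_manifest
from .profiling import average_profiles, column_profile, find_gap_center, recenter
from .segmentation import SegmentationParams, binarize
from .stats import compare_groups, summarize

__all__ = ["RunConfig", "run_scratch_pipeline", "run_spot_pipeline"]

logger = logging.getLogger("scratchquant")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    manifest: str
    out_dir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    gap_threshold: float = mx.DEFAULT_GAP_THRESHOLD
    target_width: int | None = None  # None -> minimum replicate width
    spots: SpotParams = field(default_factory=SpotParams)
    roi: tuple[int, int, int, int] | None = None  # top, left, bottom, right
    alpha: float = 0.05
    seed: int = 0
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fmt(x) -> str:
    """6-significant-digit CSV formatting for cross-platform stable goldens."""
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return ""
        if np.isinf(x):
            return "inf"
        return f"{x:.6g}"
    return str(x)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False, lineterminator="\n")


def _write_provenance(config: RunConfig, out: Path, extra: dict | None = None) -> None:
    from . import __version__

    meta = {
        "package": "scratchquant",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    if extra:
        meta.update(extra)
    (out / "run_config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _plot_profiles(aligned_rows: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cond, sub in aligned_rows.groupby("condition"):
        fig, ax = plt.subplots(figsize=(8, 4))
        for hour, hsub in sub.groupby("hour"):
            ax.plot(
                hsub["column_index"],
                hsub["black_fraction"],
                label=f"{hour:g} h",
                linewidth=0.8,
            )
        ax.set_xlabel("column (centered axis)")
        ax.set_ylabel("black fraction")
        ax.set_title(f"condition: {cond}")
        ax.legend()
        fig.tight_layout()
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in cond)
        fig.savefig(out / f"profiles_{safe}.png", dpi=110)
        plt.close(fig)


def run_scratch_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full scratch-assay analysis described in the module docstring.

    Writes ``profiles.csv`` (per-replicate raw profiles), ``aligned.csv``
    (per-condition/hour averaged profiles on the common axis),
    ``metrics.csv`` (per-replicate endpoints), ``stats.csv`` +
    ``stats_report.txt``, per-condition profile plots, and
    ``run_config.json``.  Returns the main tables keyed by name.

    Unreadable images are reported (path and stage) and skipped; remaining
    images are processed.  A replicate whose hour-0 image failed is dropped
    with a logged error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(config.manifest)
    failures: list[str] = []

    # stage 1: segment + profile every readable image
    per_image: dict[tuple[str, int, float], tuple] = {}
    for entry in manifest:
        try:
            img = load_image(entry.path, entry.condition, entry.replicate, entry.hour)
            mask = binarize(img, config.segmentation)
            prof = column_profile(mask)
        except (OSError, ValidationError) as exc:
            msg = f"segment/profile failed for {entry.path}: {exc}"
            logger.error(msg)
            failures.append(msg)
            continue
        per_image[(entry.condition, entry.replicate, entry.hour)] = (mask, prof)

    # stage 2: per-replicate centering + metrics
    replicates: dict[tuple[str, int], dict] = {}
    for (cond, rep, hour), (mask, prof) in per_image.items():
        replicates.setdefault((cond, rep), {})[hour] = (mask, prof)

    widths = [prof.width for _, prof in per_image.values()]
    if not widths:
        raise ValidationError("no image in the manifest could be processed")
    target_width = config.target_width or min(widths)
    target_center = target_width // 2

    profile_rows, metric_rows = [], []
    aligned_profiles: dict[tuple[str, float], list] = {}
    for (cond, rep), by_hour in sorted(replicates.items()):
        if 0.0 not in by_hour:
            msg = f"replicate {cond}/{rep}: hour-0 image unavailable; skipped"
            logger.error(msg)
            failures.append(msg)
            continue
        mask0, prof0 = by_hour[0.0]
        try:
            center0 = find_gap_center(prof0)
            prof0 = prof0.with_center(center0)
            region0 = mx.gap_region_from_t0(prof0, config.gap_threshold)
        except (ValidationError, ValueError) as exc:
            msg = f"replicate {cond}/{rep}: centering failed: {exc}"
            logger.error(msg)
            failures.append(msg)
            continue
        width0 = region0.width
        for hour in sorted(by_hour):
            mask, prof = by_hour[hour]
            m = mx.gap_metrics(mask, prof, region0, width0, config.gap_threshold)
            metric_rows.append(dataclasses.asdict(m))
            shifted = recenter(prof, center0, target_center, target_width)
            aligned_profiles.setdefault((cond, hour), []).append(shifted)
            for c in range(prof.width):
                profile_rows.append(
                    (cond, hour, rep, c, prof.black_fraction[c], prof.bw_ratio[c])
                )

    profiles_df = pd.DataFrame(
        profile_rows,
        columns=["condition", "hour", "replicate", "column_index", "black_fraction", "bw_ratio"],
    )
    metrics_df = pd.DataFrame(metric_rows)

    # stage 3: averaged profiles per condition/hour on the common axis
    aligned_rows = []
    for (cond, hour), profs in sorted(aligned_profiles.items()):
        avg = average_profiles(profs)
        for c in range(avg.target_width):
            aligned_rows.append(
                (
                    cond,
                    hour,
                    "mean",
                    c,
                    avg.mean_black_fraction[c],
                    avg.mean_bw_ratio[c],
                    avg.dispersion[c],
                    int(avg.n_replicates[c]),
                )
            )
    aligned_df = pd.DataFrame(
        aligned_rows,
        columns=[
            "condition", "hour", "replicate", "column_index",
            "black_fraction", "bw_ratio", "sem", "n",
        ],
    )

    # stage 4: group statistics across conditions, per hour > 0
    stats_rows = []
    report_lines = []
    if not metrics_df.empty:
        for hour in sorted(metrics_df["hour"].unique()):
            sub = metrics_df[metrics_df["hour"] == hour]
            tbl = sub.rename(columns={"occupied_fraction": "value"})[
                ["condition", "replicate", "value"]
            ]
            summary = summarize(tbl)
            for _, row in summary.iterrows():
                stats_rows.append(
                    (hour, row["condition"], "occupied_fraction", row["n"],
                     row["mean"], row["sem"], "", "", "")
                )
            report_lines.append(f"hour {hour:g}: occupied fraction, mean +/- SE")
            for _, row in summary.iterrows():
                report_lines.append(
                    f"  {row['condition']}: {row['mean']:.4f} +/- {row['sem']:.4f} (n={row['n']})"
                )
            n_cond = tbl["condition"].nunique()
            min_n = tbl.groupby("condition")["value"].count().min()
            if n_cond >= 2 and min_n >= 2:
                cmp_res = compare_groups(tbl, alpha=config.alpha)
                report_lines.append(
                    f"  ANOVA: F={cmp_res.anova_f:.4g} p={cmp_res.anova_p:.4g} ({cmp_res.method})"
                )
                for _, pr in cmp_res.pairwise.iterrows():
                    flag = "*" if pr["significant"] else "ns"
                    stats_rows.append(
                        (hour, "", "occupied_fraction", "", "", "",
                         f"{pr['group1']} vs {pr['group2']}", pr["p_adj"], flag)
                    )
                    report_lines.append(
                        f"  {pr['group1']} vs {pr['group2']}: p_adj={pr['p_adj']:.4g} [{flag}]"
                    )
            else:
                warnings.warn(f"hour {hour:g}: fewer than 2 comparable groups; summary only")
                report_lines.append("  (single group or n<2 — no comparison)")
    stats_df = pd.DataFrame(
        stats_rows,
        columns=["hour", "condition", "endpoint", "n", "mean", "sem",
                 "comparison", "p_adj", "flag"],
    )

    _write_csv(profiles_df, out / "profiles.csv")
    _write_csv(aligned_df, out / "aligned.csv")
    _write_csv(metrics_df, out / "metrics.csv")
    _write_csv(stats_df, out / "stats.csv")
    (out / "stats_report.txt").write_text("\n".join(report_lines) + "\n")
    _write_provenance(config, out, {"failures": failures})
    if config.make_plots and not aligned_df.empty:
        _plot_profiles(aligned_df, out)

    return {
        "profiles": profiles_df,
        "aligned": aligned_df,
        "metrics": metrics_df,
        "stats": stats_df,
    }


def _roi_from_entry(manifest_df: pd.DataFrame | None, entry, config: RunConfig) -> RectROI:
    """Per-image ROI from manifest columns roi_top/left/bottom/right, else global."""
    if manifest_df is not None:
        row = manifest_df[
            (manifest_df["path"] == entry.path)
            & (manifest_df["condition"] == entry.condition)
        ]
        cols = ["roi_top", "roi_left", "roi_bottom", "roi_right"]
        if len(row) and all(c in manifest_df.columns for c in cols):
            vals = row.iloc[0][cols]
            if not vals.isna().any():
                return RectROI(int(vals[0]), int(vals[1]), int(vals[2]), int(vals[3]))
    if config.roi is not None:
        return RectROI(*config.roi)
    raise ValidationError(
        f"no ROI for image {entry.path}: supply config.roi or manifest roi_* columns"
    )


def run_spot_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Count spots per fluorescence image and compare conditions.

    Writes ``spots.csv`` (one row per detected spot), ``spot_counts.csv``
    (one row per image), ``spot_stats.csv`` + ``spot_report.txt`` and
    ``run_config.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(config.manifest)
    try:
        mdf = pd.read_csv(config.manifest)
    except Exception:
        mdf = None

    spot_rows, count_rows = [], []
    for entry in manifest:
        roi = _roi_from_entry(mdf, entry, config)
        img = load_image(entry.path, entry.condition, entry.replicate, entry.hour)
        n, spots = count_spots(img, roi, config.spots)
        count_rows.append((entry.path, entry.condition, entry.replicate, entry.hour, n))
        for r, c, s in spots:
            spot_rows.append(
                (entry.path, entry.condition, entry.replicate, entry.hour,
                 f"{roi.top},{roi.left},{roi.bottom},{roi.right}", r, c, s)
            )

    spots_df = pd.DataFrame(
        spot_rows,
        columns=["image", "condition", "replicate", "hour", "roi", "row", "col", "sigma"],
    )
    counts_df = pd.DataFrame(
        count_rows, columns=["image", "condition", "replicate", "hour", "count"]
    )

    tbl = counts_df.rename(columns={"count": "value"})[["condition", "replicate", "value"]]
    summary = summarize(tbl)
    report = ["spot counts, mean +/- SE"]
    for _, row in summary.iterrows():
        report.append(
            f"  {row['condition']}: {row['mean']:.3f} +/- {row['sem']:.3f} (n={row['n']})"
        )
    stats_rows = [
        ("", row["condition"], row["n"], row["mean"], row["sem"], "", "", "")
        for _, row in summary.iterrows()
    ]
    if tbl["condition"].nunique() >= 2 and tbl.groupby("condition")["value"].count().min() >= 2:
        cmp_res = compare_groups(tbl, alpha=config.alpha)
        report.append(f"  ANOVA: F={cmp_res.anova_f:.4g} p={cmp_res.anova_p:.4g}")
        for _, pr in cmp_res.pairwise.iterrows():
            flag = "*" if pr["significant"] else "ns"
            stats_rows.append(
                ("cmp", "", "", "", "",
                 f"{pr['group1']} vs {pr['group2']}", pr["p_adj"], flag)
            )
            report.append(
                f"  {pr['group1']} vs {pr['group2']}: p_adj={pr['p_adj']:.4g} [{flag}]"
            )
    else:
        warnings.warn("single condition (or n<2): spot summary only, no comparison")
        report.append("  (no comparison possible)")
    stats_df = pd.DataFrame(
        stats_rows,
        columns=["kind", "condition", "n", "mean", "sem", "comparison", "p_adj", "flag"],
    )

    _write_csv(spots_df, out / "spots.csv")
    _write_csv(counts_df, out / "spot_counts.csv")
    _write_csv(stats_df, out / "spot_stats.csv")
    (out / "spot_report.txt").write_text("\n".join(report) + "\n")
    _write_provenance(config, out)
    return {"spots": spots_df, "counts": counts_df, "stats": stats_df}
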