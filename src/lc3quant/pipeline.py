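"""End-to-end orchestration: simulate -> segment -> detect -> classify -> stats.

Every run writes CSV tables (nuclei, puncta, per-image summary, condition
statistics) plus a JSON metadata file echoing all parameters, the seed and any
warnings.  Reruns with identical config and inputs reproduce byte-identical
CSV content: every stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocalization import colocalize_dataset, pearson_coefficient
from .config import RunConfig
from .detection import (
    despeckle,
    detect_blobs_log,
    puncta_table,
    score_puncta,
    summarize_sample,
    suppress_masked_blobs,
)
from .image import MultiChannelImage
from .io import load_multichannel, write_table
from .segmentation import (
    LabeledNucleiMask,
    count_cells,
    flag_bright_cells,
    filter_small_regions,
    make_nuclei_mask,
    split_touching_nuclei,
)
from .stats import unpaired_t_test
from .synthetic import generate_dataset
from .tandem import TandemClassificationConfig, classify_tandem_puncta

logger = logging.getLogger("lc3quant")


@dataclass
class RunReport:
    """Outcome of one pipeline run; accounts for every input image."""

    mode: str
    summaries: pd.DataFrame
    condition_stats: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    output_dir: Path | None = None

    @property
    def n_processed(self) -> int:
        return len(self.summaries)


def _masked_max(raster: np.ndarray, exclusion: np.ndarray | None) -> float:
    """Raster max over non-excluded pixels (threshold reference)."""
    if exclusion is not None and exclusion.any():
        outside = ~exclusion
        if outside.any():
            return float(raster[outside].max())
    return float(raster.max())


def _segment_image(image: MultiChannelImage, cfg: RunConfig) -> LabeledNucleiMask:
    seg = cfg.segmentation
    mask = make_nuclei_mask(image.blue, seg.smoothing_sigma)
    lnm = split_touching_nuclei(mask, min_area_hint=seg.min_area)
    lnm = filter_small_regions(lnm, seg.min_area)
    bright_raster = image.channel(seg.bright_channel)
    return flag_bright_cells(lnm, bright_raster, seg.fence_k, seg.halo_radius)


def _detect_image(image: MultiChannelImage, lnm: LabeledNucleiMask, cfg: RunConfig,
                  channel: str) -> list:
    det = cfg.detection
    raster = image.channel(channel)
    if det.median_window is not None:
        raster = despeckle(raster, det.median_window)
    threshold_abs = det.threshold_rel * _masked_max(raster, lnm.exclusion_mask)
    blobs = detect_blobs_log(
        raster,
        sigma_min=det.sigma_min, sigma_max=det.sigma_max, n_scales=det.n_scales,
        threshold_abs=threshold_abs, overlap_max=det.overlap_max,
    )
    blobs = suppress_masked_blobs(blobs, lnm.labels, lnm.exclusion_mask)
    return score_puncta(
        blobs,
        green=image.green,
        red=image.red,
        radius_coeff=det.radius_coeff,
    )


def _condition_stats(summary_df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Pairwise unpaired t-tests between conditions on a per-image statistic."""
    rows = []
    conditions = sorted(summary_df["condition"].unique())
    for cond_a, cond_b in itertools.combinations(conditions, 2):
        a = summary_df.loc[summary_df["condition"] == cond_a, value_col].to_numpy()
        b = summary_df.loc[summary_df["condition"] == cond_b, value_col].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            res = unpaired_t_test(a, b)
        except ValueError:
            continue
        rows.append(dict(
            condition_a=cond_a, condition_b=cond_b, statistic=value_col,
            mean_a=res.mean_a, sd_a=res.sd_a, n_a=res.n_a,
            mean_b=res.mean_b, sd_b=res.sd_b, n_b=res.n_b,
            t=res.t, df=res.degrees_of_freedom, p_value=res.p_value,
            significant=res.significant,
        ))
    return pd.DataFrame(rows, columns=[
        "condition_a", "condition_b", "statistic", "mean_a", "sd_a", "n_a",
        "mean_b", "sd_b", "n_b", "t", "df", "p_value", "significant",
    ])


def _write_metadata(cfg: RunConfig, report: RunReport, out: Path) -> None:
    def default(obj):
        if isinstance(obj, Path):
            return str(obj)
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    meta = {
        "software": "lc3quant",
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "parameters": {
            "segmentation": dataclasses.asdict(cfg.segmentation),
            "detection": dataclasses.asdict(cfg.detection),
            "tandem": dataclasses.asdict(cfg.tandem),
            "colocalization": dataclasses.asdict(cfg.colocalization),
        },
        "n_images": len(cfg.images),
        "n_processed": report.n_processed,
        "skipped": [{"image": n, "reason": r} for n, r in report.skipped],
        "warnings": report.warnings,
    }
    out.write_text(json.dumps(meta, indent=2, sort_keys=True, default=default))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the stages of ``cfg.mode`` and write all output tables.

    Per-image failures are recorded in the report (and metadata) as skipped
    images with a reason, never silently dropped.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate":
        return _run_simulate(cfg)
    if cfg.mode == "colocalization":
        return _run_colocalization(cfg)
    return _run_quantify(cfg)


def _run_simulate(cfg: RunConfig) -> RunReport:
    t0 = time.perf_counter()
    truth_df, manifest_df = generate_dataset(
        cfg.synthetic.conditions, cfg.synthetic.n_images, cfg.output_dir
    )
    logger.info("simulate: %d images in %.2fs", len(manifest_df), time.perf_counter() - t0)
    per_image = (
        truth_df[truth_df["kind"] == "punctum"]
        .groupby("image")
        .size()
        .reindex(manifest_df["name"], fill_value=0)
    )
    summaries = manifest_df.assign(true_puncta=per_image.to_numpy())
    report = RunReport(mode="simulate", summaries=summaries, condition_stats=None,
                       output_dir=cfg.output_dir)
    _write_metadata(cfg, report, cfg.output_dir / "run_metadata.json")
    return report


def _load_entry(entry) -> MultiChannelImage:
    return load_multichannel(
        entry.name, blue=entry.blue, green=entry.green,
        red=entry.red if entry.red is not None else None,
    )


def quantify_images(
    images: list[MultiChannelImage],
    cfg: RunConfig,
    conditions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Quantify already-loaded images (the in-memory core of puncta/tandem runs).

    Returns (summary table, nuclei table, puncta table, skipped) where skipped
    holds (image name, reason) for per-image failures.  Detection runs on the
    green channel in ``puncta`` mode and on red in ``tandem`` mode, where each
    surviving punctum is additionally classified by green positivity.
    """
    detect_channel = "red" if cfg.mode == "tandem" else "green"
    conditions = conditions or {}
    segmented, masks, skipped = [], [], []

    t0 = time.perf_counter()
    for image in images:
        try:
            lnm = _segment_image(image, cfg)
        except Exception as exc:  # noqa: BLE001 - reported, never dropped
            logger.warning("segmentation failed for %s: %s", image.name, exc)
            skipped.append((image.name, str(exc)))
            continue
        logger.debug("%s: %d nuclei labels", image.name, lnm.n_labels)
        segmented.append(image)
        masks.append(lnm)
    logger.info("segmentation: %d images in %.2fs", len(segmented), time.perf_counter() - t0)

    if not segmented:
        raise RuntimeError("no image could be segmented; see skipped reasons")

    cell_counts = count_cells(masks)

    t0 = time.perf_counter()
    nuclei_rows, puncta_frames, summary_rows = [], [], []
    for image, lnm, cc in zip(segmented, masks, cell_counts):
        try:
            puncta = _detect_image(image, lnm, cfg, detect_channel)
            if cfg.mode == "tandem":
                puncta, _, _ = classify_tandem_puncta(
                    puncta, image.green,
                    TandemClassificationConfig(
                        green_positivity_factor=cfg.tandem.green_positivity_factor
                    ),
                    exclusion_mask=lnm.exclusion_mask,
                )
            summary = summarize_sample(puncta, cc, image=image.name)
        except Exception as exc:  # noqa: BLE001
            logger.warning("quantification failed for %s: %s", image.name, exc)
            skipped.append((image.name, str(exc)))
            continue
        nuclei_rows.append(lnm.records.assign(image=image.name))
        puncta_frames.append(puncta_table(puncta, image=image.name))
        summary_rows.append(dict(
            image=image.name, condition=conditions.get(image.name, "default"),
            effective_cell_count=summary.effective_cell_count,
            n_interior=cc.n_interior,
            puncta_count=summary.puncta_count,
            total_puncta_area=summary.total_puncta_area,
            puncta_area_per_cell=summary.puncta_area_per_cell,
            n_autophagosome=summary.n_autophagosome,
            n_autolysosome=summary.n_autolysosome,
        ))
    logger.info("detection: %d images in %.2fs", len(summary_rows), time.perf_counter() - t0)

    summary_df = pd.DataFrame(summary_rows)
    nuclei_df = (
        pd.concat(nuclei_rows, ignore_index=True) if nuclei_rows else pd.DataFrame()
    )
    puncta_df = (
        pd.concat(puncta_frames, ignore_index=True) if puncta_frames else pd.DataFrame()
    )
    return summary_df, nuclei_df, puncta_df, skipped


def _run_quantify(cfg: RunConfig) -> RunReport:
    images, skipped, conditions = [], [], {}
    for entry in cfg.images:
        try:
            images.append(_load_entry(entry))
            conditions[entry.name] = entry.condition
        except Exception as exc:  # noqa: BLE001
            logger.warning("load failed for %s: %s", entry.name, exc)
            skipped.append((entry.name, str(exc)))
    if not images:
        raise RuntimeError("no image could be loaded; see skipped reasons")

    summary_df, nuclei_df, puncta_df, quant_skipped = quantify_images(
        images, cfg, conditions
    )
    skipped.extend(quant_skipped)
    stats_df = _condition_stats(summary_df, "puncta_area_per_cell") if len(summary_df) else None

    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if len(nuclei_df):
        write_table(nuclei_df, out / "nuclei.csv")
    if len(puncta_df):
        write_table(puncta_df, out / "puncta.csv")
    write_table(summary_df, out / "summary.csv")
    if stats_df is not None and len(stats_df):
        write_table(stats_df, out / "condition_stats.csv")

    report = RunReport(mode=cfg.mode, summaries=summary_df, condition_stats=stats_df,
                       skipped=skipped, output_dir=out)
    _write_metadata(cfg, report, out / "run_metadata.json")
    return report


def _run_colocalization(cfg: RunConfig) -> RunReport:
    coloc = cfg.colocalization
    pairs, roi_masks, skipped = [], {}, []
    conditions = {}
    for entry in cfg.images:
        try:
            image = _load_entry(entry)
            a = image.channel(coloc.channel_a)
            b = image.channel(coloc.channel_b)
            roi = None
            if coloc.roi == "nuclei_excluded":
                lnm = _segment_image(image, cfg)
                roi = (lnm.labels == 0) & ~lnm.exclusion_mask
            elif image.blue is not None and cfg.segmentation.fence_k > 0:
                # default ROI: whole image minus bright-cell halos
                try:
                    lnm = _segment_image(image, cfg)
                    roi = ~lnm.exclusion_mask
                    if roi.all():
                        roi = None
                except Exception:  # noqa: BLE001 - segmentation optional here
                    roi = None
        except Exception as exc:  # noqa: BLE001
            logger.warning("colocalization load failed for %s: %s", entry.name, exc)
            skipped.append((entry.name, str(exc)))
            continue
        pairs.append((entry.name, a, b, roi))
        conditions[entry.name] = entry.condition

    if not pairs:
        raise RuntimeError("no image pair could be loaded; see skipped reasons")
    result = colocalize_dataset(pairs)
    skipped.extend(result.skipped)

    records = result.records.copy()
    records["condition"] = records["name"].map(conditions)
    group = (
        records.groupby("condition")["r"]
        .agg(mean_r="mean", sd_r=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
    stats_df = _condition_stats(records.rename(columns={"name": "image"}), "r")

    out = cfg.output_dir
    write_table(records, out / "colocalization.csv")
    write_table(group, out / "colocalization_summary.csv")
    if len(stats_df):
        write_table(stats_df, out / "condition_stats.csv")

    report = RunReport(mode="colocalization", summaries=records,
                       condition_stats=stats_df, skipped=skipped, output_dir=out)
    _write_metadata(cfg, report, out / "run_metadata.json")
    return report
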