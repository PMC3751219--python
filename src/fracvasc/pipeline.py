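"""End-to-end pipeline drivers composing the analysis stages.

``run_ct_pipeline`` takes a configured micro-CT volume through
segmentation, mask cleanup, region selection, per-slice counting and
size-distribution summarisation; ``run_ldi_pipeline`` takes perfusion
scans (or a pre-extracted tidy table) through ROI statistics, the
contralateral daily-variation correction and baseline-relative series.
Both are deterministic given config + inputs and embed the full
configuration in their summary output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import ctquant, ldi
from .io import (
    RunConfig,
    read_roi_set,
    read_scan,
    read_volume,
    region_selection_from_config,
    write_histogram_csv,
    write_slice_stats_csv,
    write_summary_json,
)

logger = logging.getLogger("fracvasc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _stage(name: str):
    logger.info("stage: %s", name)


def run_ct_pipeline(config: RunConfig, volume: ctquant.VolumeStack | None = None) -> dict:
    """Run the full micro-CT quantification pipeline.

    Returns the summary dict (also written to ``<out_prefix>.summary.json``
    alongside per-slice and histogram CSVs). A pre-loaded volume may be
    passed instead of reading ``config.volume`` from disk.
    """
    if volume is None:
        if not config.volume:
            raise PipelineError("read_volume: no input volume configured")
        try:
            _stage("read_volume")
            volume = read_volume(config.volume, config.sidecar)
        except Exception as exc:
            raise PipelineError(f"read_volume: {config.volume}: {exc}") from exc

    try:
        _stage("segment_four_class")
        labels = ctquant.segment_four_class(
            volume,
            method=config.segmentation_method,
            thresholds=config.thresholds,
        )
    except Exception as exc:
        raise PipelineError(f"segment_four_class: {exc}") from exc

    try:
        _stage("clean_vessel_mask")
        mask = ctquant.clean_vessel_mask(
            labels,
            close_radius=config.close_radius,
            median_radius=config.median_radius,
            min_size=config.min_size,
            artifact_slices=volume.artifact_slices,
        )
        _stage("select_region")
        selection = region_selection_from_config(config, volume.n_slices)
        _stage("count_vessels_per_slice")
        stats = ctquant.count_vessels_per_slice(
            mask,
            selection=selection,
            connectivity=config.connectivity,
            voxel_size_um=volume.voxel_size_um,
        )
        _stage("size_histogram")
        hist = ctquant.size_histogram(stats)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"quantification: {exc}") from exc

    analysed = [s for s in stats if not s.artifact]
    summary = {
        "region": {
            "mode": selection.mode,
            "slice_interval": [selection.start, selection.stop],
            "n_slices_analysed": len(analysed),
            "span_mm": selection.span_mm(volume.voxel_size_um),
        },
        "totals": {
            "total_vessel_count_summed": int(
                sum(s.vessel_count for s in analysed)
            ),
            "total_vessel_area_voxels": int(
                sum(s.total_vessel_area_voxels for s in analysed)
            ),
            "small_vessel_fraction": hist.small_vessel_fraction,
            "small_vessel_count_summed": hist.n_small,
            "empty_region": hist.empty,
        },
        "histogram": {
            "bin_uppers_voxels": [
                "inf" if u == float("inf") else u for u in hist.bin_uppers
            ],
            "counts": list(hist.counts),
        },
        "provenance": {
            "config": config.to_dict(),
            "thresholds": labels.provenance.get("thresholds"),
            "segmentation_method": labels.provenance.get("method"),
            "cleanup_params": mask.cleanup_params,
            "connectivity": config.connectivity,
        },
    }

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_slice_stats_csv(stats, f"{prefix}.slices.csv")
    write_histogram_csv(hist, f"{prefix}.histogram.csv")
    write_summary_json(summary, f"{prefix}.summary.json")
    return summary


def extract_series_from_scans(config: RunConfig) -> pd.DataFrame:
    """Build the tidy (animal, limb, region, day, perfusion) table from scans.

    ``config.scan_manifest`` is a CSV with columns (path, animal, limb,
    day) listing one scan grid file per row; ``config.roi_file`` names the
    ROI set applied to every scan. Regional means become the ``perfusion``
    column; maxima are carried alongside.
    """
    if not config.scan_manifest or not config.roi_file:
        raise PipelineError("extract_series: scan_manifest and roi_file required")
    manifest = pd.read_csv(config.scan_manifest)
    needed = {"path", "animal", "limb", "day"}
    if not needed <= set(manifest.columns):
        raise PipelineError(
            f"extract_series: manifest lacks columns {sorted(needed - set(manifest.columns))}"
        )
    if manifest.empty:
        raise PipelineError("extract_series: scan manifest is empty")
    rois = read_roi_set(config.roi_file)
    base = Path(config.scan_manifest).parent
    rows = []
    for _, rec in manifest.iterrows():
        path = Path(rec["path"])
        if not path.is_absolute():
            path = base / path
        scan = read_scan(path)
        stats = ldi.roi_stats(scan, rois)
        for region, st in stats.items():
            rows.append(
                {
                    "animal": rec["animal"],
                    "limb": rec["limb"],
                    "region": region,
                    "day": float(rec["day"]),
                    "perfusion": st["mean"],
                    "max_perfusion": st["max"],
                }
            )
    return pd.DataFrame(rows)


def run_ldi_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the longitudinal perfusion analysis.

    Input is either a pre-extracted tidy table (``config.table`` CSV or the
    ``table`` argument) or a scan manifest + ROI file. Output is the
    corrected tidy CSV (animal, region, day, perfusion, daily_var,
    corrected_perfusion, percent_of_preop) written to
    ``<out_prefix>.corrected.csv`` with a provenance JSON beside it.
    """
    if table is None:
        if config.table:
            _stage("read_table")
            table = pd.read_csv(config.table)
        else:
            _stage("extract_series")
            table = extract_series_from_scans(config)
    if table.empty:
        raise PipelineError("ldi: input table is empty")

    try:
        _stage("daily_variation")
        dv = ldi.daily_variation(table, baseline_day=config.baseline_day)
        _stage("correct_perfusion")
        corrected = ldi.correct_perfusion(
            table,
            dv,
            baseline_day=config.baseline_day,
            convention=config.percent_convention,
        )
    except Exception as exc:
        raise PipelineError(f"correction: {exc}") from exc

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    corrected.to_csv(f"{prefix}.corrected.csv", index=False)
    write_summary_json(
        {"provenance": {"config": config.to_dict()}, "n_rows": int(len(corrected))},
        f"{prefix}.provenance.json",
    )
    return corrected
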