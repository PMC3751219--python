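"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as multi-page TIFF plus a YAML metadata sidecar (voxel
size, axis order, artifact slice ranges); scans as CSV grids or TIFF;
ROI sets and run configuration as YAML; tabular outputs as plain CSV
(comma, UTF-8, '.' decimal); summaries as JSON with full provenance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ctquant import (
    RegionSelection,
    SliceVesselStats,
    VesselSizeHistogram,
    VolumeStack,
)
from .ldi import ROI, ROISet, PerfusionScan


class MetadataError(ValueError):
    """Raised when a required sidecar metadata field is missing."""


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def sidecar_path_for(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".meta.yaml")


def write_volume(stack: VolumeStack, tiff_path: str | Path) -> Path:
    """Write a volume as multi-page TIFF with a YAML metadata sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack.voxels))
    meta = {
        "voxel_size_um": float(stack.voxel_size_um),
        "axis_order": stack.axis_order,
        "artifact_slices": [list(r) for r in stack.artifact_slices],
    }
    sidecar = sidecar_path_for(tiff_path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_volume(
    tiff_path: str | Path, sidecar: str | Path | None = None
) -> VolumeStack:
    """Read a multi-page TIFF volume and its metadata sidecar."""
    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar) if sidecar else sidecar_path_for(tiff_path)
    if not sidecar.exists():
        raise MetadataError(f"metadata sidecar not found: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text()) or {}
    for fieldname in ("voxel_size_um", "axis_order"):
        if fieldname not in meta:
            raise MetadataError(f"sidecar {sidecar} missing field {fieldname!r}")
    voxels = tifffile.imread(tiff_path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    return VolumeStack(
        voxels,
        voxel_size_um=float(meta["voxel_size_um"]),
        axis_order=str(meta["axis_order"]),
        artifact_slices=[tuple(r) for r in meta.get("artifact_slices", [])],
    )


def read_raw_volume(
    path: str | Path,
    dims: tuple[int, int, int],
    dtype: str,
    voxel_size_um: float,
    artifact_slices: Sequence[tuple[int, int]] = (),
) -> VolumeStack:
    """Read a raw binary volume with declared dims (z, y, x) and dtype."""
    data = np.fromfile(path, dtype=np.dtype(dtype))
    expected = int(np.prod(dims))
    if data.size != expected:
        raise ValueError(
            f"raw volume holds {data.size} voxels, dims {dims} need {expected}"
        )
    return VolumeStack(
        data.reshape(dims),
        voxel_size_um=voxel_size_um,
        artifact_slices=artifact_slices,
    )


# ---------------------------------------------------------------------------
# scans and ROIs
# ---------------------------------------------------------------------------

def read_scan(path: str | Path, pixel_pitch_mm: float = 0.1, **metadata) -> PerfusionScan:
    """Read a perfusion scan from a CSV grid (no header) or a TIFF image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.loadtxt(path, delimiter=",", ndmin=2)
    return PerfusionScan(grid, pixel_pitch_mm=pixel_pitch_mm, metadata=metadata)


def write_scan(scan: PerfusionScan, path: str | Path) -> None:
    np.savetxt(path, scan.grid, delimiter=",", fmt="%.6g")


def read_roi_set(path: str | Path) -> ROISet:
    """Read a named-ROI YAML file.

    Each entry is either ``{type: rect, bounds: [row0, row1, col0, col1]}``
    (half-open) or ``{type: polygon, vertices: [[x, y], ...]}`` with 0-based
    pixel coordinates.
    """
    raw = yaml.safe_load(Path(path).read_text())
    rois = {}
    for name, entry in raw.items():
        kind = entry.get("type")
        if kind == "rect":
            rois[name] = ROI(rect=tuple(int(v) for v in entry["bounds"]))
        elif kind == "polygon":
            rois[name] = ROI(polygon=[tuple(map(float, v)) for v in entry["vertices"]])
        else:
            raise ValueError(f"ROI {name!r} has unknown type {kind!r}")
    return ROISet(rois)


def write_roi_set(rois: ROISet, path: str | Path) -> None:
    out = {}
    for name, roi in rois.items():
        if roi.rect is not None:
            out[name] = {"type": "rect", "bounds": list(roi.rect)}
        else:
            out[name] = {
                "type": "polygon",
                "vertices": [list(v) for v in roi.polygon],
            }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_slice_stats_csv(
    stats: Sequence[SliceVesselStats], path: str | Path
) -> None:
    rows = [
        {
            "slice_index": s.slice_index,
            "vessel_count": s.vessel_count,
            "total_area_voxels": s.total_vessel_area_voxels,
            "total_area_um2": s.total_vessel_area_um2,
            "area_fraction": s.area_fraction,
            "artifact": s.artifact,
        }
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_histogram_csv(hist: VesselSizeHistogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bin_upper_voxels": [
                "inf" if math.isinf(u) else int(u) for u in hist.bin_uppers
            ],
            "count": list(hist.counts),
        }
    )
    df.to_csv(path, index=False)


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything that affects a pipeline run's numerical output.

    The full config is emitted in every summary's provenance block, so a
    run can be reproduced exactly from its outputs.
    """

    # inputs
    volume: str | None = None
    sidecar: str | None = None
    scan_manifest: str | None = None
    table: str | None = None
    roi_file: str | None = None
    # CT analysis
    voxel_size_um: float = 21.0
    region_mode: str = "full"  # full | mid_third | between_pins
    pin_ranges: list | None = None
    segmentation_method: str = "multi_threshold"
    thresholds: list | None = None
    close_radius: int = 1
    median_radius: int = 1
    min_size: int = 2
    connectivity: int = 8
    # LDI analysis
    baseline_day: float = -1.0
    percent_convention: str = "percent_of_baseline"
    # general
    seed: int = 0
    out_prefix: str = "fracvasc_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def region_selection_from_config(cfg: RunConfig, n_slices: int) -> RegionSelection:
    if cfg.region_mode == "full":
        return RegionSelection("full", 0, n_slices)
    if cfg.region_mode == "mid_third":
        return RegionSelection.mid_third(n_slices)
    if cfg.region_mode == "between_pins":
        if not cfg.pin_ranges:
            raise ValueError("between_pins region mode needs pin_ranges")
        return RegionSelection.between_pins(
            [tuple(r) for r in cfg.pin_ranges]
        )
    raise ValueError(f"unknown region mode {cfg.region_mode!r}")
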