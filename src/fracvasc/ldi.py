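"""Laser-Doppler perfusion imaging (LDI) analysis.

A scan is a 2D grid of perfusion (flux) values over the medial thigh,
2.5 cm x 2.5 cm at 0.1 mm pixel pitch. Four regions of interest are
analysed: the femoral artery, the distal femoral artery, the cranial region
overlying the fracture zone, and the caudal region. Regional means feed a
longitudinal analysis in which daily whole-animal fluctuations (depth of
anaesthesia, body temperature) are removed with the contralateral limb:
DailyVar(day) is the intact-limb regional mean divided by its pre-operative
value, the fractured-limb series is divided by DailyVar day by day, and the
corrected series is expressed as a percentage of its pre-operative value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from . import stats as _stats

#: the four standard scan regions
REGIONS = ("femoral_artery", "distal_femoral_artery", "cranial", "caudal")

#: numeric day coding for the pre-operative baseline scan
PREOP_DAY = -1.0


class ROIError(ValueError):
    """Raised when a region of interest selects no pixels."""


# ---------------------------------------------------------------------------
# scans and ROIs
# ---------------------------------------------------------------------------

@dataclass
class PerfusionScan:
    """A 2D perfusion map in arbitrary flux units (values >= 0)."""

    grid: np.ndarray
    pixel_pitch_mm: float = 0.1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("scan grid must be 2D")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if np.nanmin(self.grid) < 0:
            raise ValueError("perfusion values must be >= 0")


@dataclass
class ROI:
    """A rectangular or polygonal region of interest in pixel coordinates.

    Rectangles are half-open pixel boxes ``[row0, row1) x [col0, col1)``.
    Polygon membership uses the pixel-centre-in-polygon rule (pixel centre
    at integer coordinates, vertices as (x=col, y=row) pairs, 0-based);
    centres exactly on a shared edge belong to neither polygon, which
    avoids double counting between abutting ROIs.
    """

    rect: tuple[int, int, int, int] | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("exactly one of rect or polygon must be given")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask for a grid of the given shape."""
        out = np.zeros(shape, dtype=bool)
        if self.rect is not None:
            r0, r1, c0, c1 = self.rect
            out[max(r0, 0):r1, max(c0, 0):c1] = True
            return out
        poly = shapely.Polygon(self.polygon)
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
        return inside.reshape(shape)


@dataclass
class ROISet:
    """The four named scan regions. Labels are fixed by the protocol."""

    rois: Mapping[str, ROI]

    def __post_init__(self) -> None:
        if set(self.rois) != set(REGIONS):
            raise ValueError(
                f"ROI labels must be exactly {set(REGIONS)}, got {set(self.rois)}"
            )

    def __getitem__(self, region: str) -> ROI:
        return self.rois[region]

    def items(self):
        return self.rois.items()


def roi_stats(scan: PerfusionScan, rois: ROISet) -> dict[str, dict[str, float]]:
    """Mean and maximum perfusion per region.

    Statistics are taken over pixels whose centres fall inside the ROI.
    The mean is the value used in all downstream analysis; the maximum is
    reported alongside it.
    """
    out = {}
    for region, roi in rois.items():
        m = roi.mask(scan.grid.shape)
        n = int(m.sum())
        if n == 0:
            raise ROIError(f"ROI {region!r} contains no pixels")
        vals = scan.grid[m]
        out[region] = {
            "mean": float(vals.mean()),
            "max": float(vals.max()),
            "n_pixels": n,
        }
    return out


# ---------------------------------------------------------------------------
# longitudinal correction
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} lacks required columns: {missing}")


def daily_variation(
    table: pd.DataFrame, baseline_day: float = PREOP_DAY
) -> pd.DataFrame:
    """Per-day intact-limb ratio to its pre-operative value (DailyVar).

    From the intact-limb rows of a tidy table (animal, limb, region, day,
    perfusion), computes DailyVar(animal, region, day) =
    intact(day) / intact(baseline_day), region-matched; DailyVar at the
    baseline day is exactly 1. Days absent from the intact series are
    simply absent from the output (flagged gaps, never interpolated).
    """
    _check_columns(table, ("animal", "limb", "region", "day", "perfusion"), "table")
    intact = table[table["limb"] == "intact"]
    if intact.empty:
        raise ValueError("table contains no intact-limb rows")
    rows = []
    for (animal, region), grp in intact.groupby(["animal", "region"], sort=True):
        base = grp.loc[grp["day"] == baseline_day, "perfusion"]
        if base.empty:
            raise ValueError(
                f"no pre-operative (day {baseline_day}) intact value for "
                f"animal {animal!r}, region {region!r}"
            )
        base_val = float(base.iloc[0])
        if base_val <= 0:
            raise ValueError(
                f"non-positive pre-operative value for animal {animal!r}, "
                f"region {region!r}"
            )
        for _, r in grp.iterrows():
            rows.append(
                {
                    "animal": animal,
                    "region": region,
                    "day": float(r["day"]),
                    "daily_var": float(r["perfusion"]) / base_val,
                }
            )
    return pd.DataFrame(rows)


def correct_perfusion(
    table: pd.DataFrame,
    daily_var: pd.DataFrame,
    baseline_day: float = PREOP_DAY,
    convention: str = "percent_of_baseline",
) -> pd.DataFrame:
    """Divide fractured-limb perfusion by DailyVar and express vs baseline.

    corrected(day) = fractured(day) / DailyVar(day), matched on
    (animal, region, day); percent_of_preop(day) =
    100 * corrected(day) / corrected(baseline_day), so the pre-operative
    entry is exactly 100. With ``convention='percent_change'`` the output
    column is shifted by -100 (0 = unchanged).
    """
    if convention not in ("percent_of_baseline", "percent_change"):
        raise ValueError(f"unknown convention {convention!r}")
    _check_columns(table, ("animal", "limb", "region", "day", "perfusion"), "table")
    _check_columns(daily_var, ("animal", "region", "day", "daily_var"), "daily_var")
    if (daily_var["daily_var"] <= 0).any():
        raise ValueError("daily_var values must be positive")

    frac = table[table["limb"] == "fractured"].copy()
    if frac.empty:
        raise ValueError("table contains no fractured-limb rows")
    merged = frac.merge(daily_var, on=["animal", "region", "day"], how="left")
    unmatched = merged[merged["daily_var"].isna()]
    if not unmatched.empty:
        days = sorted(
            set(zip(unmatched["animal"], unmatched["region"], unmatched["day"]))
        )
        raise ValueError(f"no DailyVar for (animal, region, day): {days[:20]}")
    merged["corrected_perfusion"] = merged["perfusion"] / merged["daily_var"]

    out = []
    for (animal, region), grp in merged.groupby(["animal", "region"], sort=True):
        grp = grp.sort_values("day")
        base = grp.loc[grp["day"] == baseline_day, "corrected_perfusion"]
        if base.empty:
            raise ValueError(
                f"no pre-operative corrected value for animal {animal!r}, "
                f"region {region!r}"
            )
        base_val = float(base.iloc[0])
        # divide first so the baseline entry is exactly 100 (x/x == 1.0)
        pct = 100.0 * (grp["corrected_perfusion"] / base_val)
        if convention == "percent_change":
            pct = pct - 100.0
        grp = grp.assign(percent_of_preop=pct)
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    cols = [
        "animal", "region", "day", "perfusion", "daily_var",
        "corrected_perfusion", "percent_of_preop",
    ]
    extra = [c for c in result.columns if c not in cols and c != "limb"]
    return result[cols + extra]


# ---------------------------------------------------------------------------
# operator repeatability
# ---------------------------------------------------------------------------

def repeatability(measurements: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of regional means between raters.

    ``measurements`` is a long table (scan_id, rater, region,
    mean_perfusion) from two or more raters (or repeats of one rater)
    analysing a common scan set. For every region and every rater pair,
    scans common to both are rank-correlated; the per-region average over
    pairs is reported as rater_a = rater_b = 'all'.
    """
    _check_columns(
        measurements, ("scan_id", "rater", "region", "mean_perfusion"),
        "measurements",
    )
    raters = sorted(measurements["rater"].unique(), key=str)
    if len(raters) < 2:
        raise ValueError("repeatability needs at least 2 raters or repeats")
    rows = []
    for region, grp in measurements.groupby("region", sort=True):
        wide = grp.pivot_table(
            index="scan_id", columns="rater", values="mean_perfusion"
        )
        rhos = []
        for a, b in itertools.combinations(raters, 2):
            common = wide[[a, b]].dropna()
            if len(common) < 3:
                raise ValueError(
                    f"raters {a!r} and {b!r} share only {len(common)} scans "
                    f"in region {region!r}; rank correlation needs >= 3"
                )
            rho = _stats.spearman(common[a].to_numpy(), common[b].to_numpy())
            rhos.append(rho)
            rows.append(
                {"region": region, "rater_a": a, "rater_b": b, "rho": rho}
            )
        rows.append(
            {
                "region": region,
                "rater_a": "all",
                "rater_b": "all",
                "rho": float(np.mean(rhos)),
            }
        )
    return pd.DataFrame(rows)
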