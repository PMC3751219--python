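"""Synthetic vascular phantoms and simulated perfusion cohorts.

This module generates the two kinds of input the analysis pipeline
consumes, with exact ground truth attached:

* micro-CT phantoms — four-intensity-class volumes (air < tissue < vessel
  < bone, with the contrast-filled vessel class midway between soft tissue
  and bone) containing tubular vessels of known position and radius,
  optional cortical-bone annulus, Gaussian gray-value noise and
  saturated-white "pin artifact" slices. Ground-truth per-slice vessel
  counts and areas are computed from the tube geometry alone, never from
  any segmentation code.

* laser-Doppler cohorts — long-format longitudinal perfusion tables in
  which the fractured limb follows the characteristic post-osteotomy time
  course (immediate drop, recovery rising to about two weeks, then
  decline, modelled as a quadratic in days), the intact contralateral limb
  is flat at baseline, and every (animal, day) carries one shared
  log-normal multiplicative day effect on BOTH limbs emulating
  anaesthesia-depth/body-temperature fluctuations. Per-animal random
  intercepts and residual noise complete the generative model.

The rasterisation rule is fixed: a pixel belongs to a vessel when its
centre lies within the vessel radius of the centerline (for a vessel
parallel to the slice axis this is exactly the centre-in-disk rule per
slice). The generator and every ground-truth computation share this rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctquant import LabelMap, VolumeStack, AIR, TISSUE, VESSEL, BONE
from .ldi import ROI, ROISet, PerfusionScan, REGIONS, PREOP_DAY


class GeometryConflictError(ValueError):
    """Two vessels with different labels claim the same voxel."""


# ---------------------------------------------------------------------------
# CT phantom specification
# ---------------------------------------------------------------------------

@dataclass
class Vessel:
    """A tubular vessel defined by a centerline polyline and a radius.

    Centerline points are (z, y, x) voxel coordinates (floats, 0-based);
    the radius is physical (µm). A straight vessel has a two-point
    centerline.
    """

    centerline: Sequence[tuple[float, float, float]]
    radius_um: float
    label: int = 0

    def __post_init__(self) -> None:
        self.centerline = [tuple(float(c) for c in p) for p in self.centerline]
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        if not self.radius_um > 0:
            raise ValueError("vessel radius must be positive")

    @classmethod
    def axial(
        cls, y: float, x: float, radius_um: float, z0: float, z1: float,
        label: int = 0,
    ) -> "Vessel":
        """A straight vessel parallel to the slice axis at in-plane (y, x)."""
        return cls([(z0, y, x), (z1, y, x)], radius_um, label)


@dataclass
class BoneCylinder:
    """A hollow cortical-bone cylinder along the slice axis."""

    center_yx: tuple[float, float]
    outer_radius_um: float
    inner_radius_um: float

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_um < self.outer_radius_um:
            raise ValueError("need 0 < inner radius < outer radius")


@dataclass
class PhantomSpec:
    """Complete generative description of a synthetic micro-CT volume.

    ``class_intensities`` must be strictly ordered air < tissue < vessel <
    bone. ``artifact_slices`` are half-open slice ranges rendered saturated
    white (pin whiteout) and excluded from ground-truth totals.
    ``limb_radius_um``, when set, makes everything outside that in-plane
    radius air instead of tissue so all four classes are present.
    """

    dims: tuple[int, int, int]
    voxel_size_um: float = 21.0
    vessels: Sequence[Vessel] = field(default_factory=tuple)
    bone: BoneCylinder | None = None
    limb_radius_um: float | None = None
    class_intensities: Mapping[str, float] = field(
        default_factory=lambda: {"air": 0.0, "tissue": 80.0, "vessel": 160.0, "bone": 240.0}
    )
    noise_sd: float = 0.0
    artifact_slices: Sequence[tuple[int, int]] = field(default_factory=tuple)
    saturation_value: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise ValueError("dims must be 3 positive integers (z, y, x)")
        ci = self.class_intensities
        if not ci["air"] < ci["tissue"] < ci["vessel"] < ci["bone"]:
            raise ValueError(
                "class intensities must be strictly ordered air < tissue < vessel < bone"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nz, ny, nx = self.dims
        for v in self.vessels:
            for (z, y, x) in v.centerline:
                if not (0 <= z <= nz - 1 and 0 <= y <= ny - 1 and 0 <= x <= nx - 1):
                    raise ValueError(
                        f"centerline point {(z, y, x)} outside volume bounds"
                    )
        for a, b in self.artifact_slices:
            if not (0 <= a < b <= nz):
                raise ValueError(f"artifact range [{a}, {b}) outside [0, {nz})")

    def artifact_mask(self) -> np.ndarray:
        mask = np.zeros(self.dims[0], dtype=bool)
        for a, b in self.artifact_slices:
            mask[a:b] = True
        return mask


@dataclass
class SliceTruth:
    slice_index: int
    vessel_count: int
    per_vessel_areas: dict[int, int]  # vessel label -> pixel area


@dataclass
class GroundTruthMorphometry:
    """Exact per-slice morphometry derived from the phantom geometry.

    ``per_slice`` covers only non-artifact slices; totals are exact sums
    over those entries. ``small_vessel_fraction`` is 0 with ``empty=True``
    when the phantom contains no vessel cross-sections at all.
    """

    per_slice: list[SliceTruth]
    total_vessel_count_summed: int
    small_vessel_count_summed: int
    small_vessel_fraction: float
    empty: bool = False


# ---------------------------------------------------------------------------
# CT phantom generation
# ---------------------------------------------------------------------------

def _paint_vessel(ownership: np.ndarray, vessel: Vessel, radius_vox: float) -> None:
    """Mark voxels whose centres lie within radius_vox of the centerline.

    Raises GeometryConflictError when a voxel is already owned by a vessel
    with a different label.
    """
    nz, ny, nx = ownership.shape
    r = radius_vox
    pts = np.asarray(vessel.centerline, dtype=float)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        seg_len2 = float(d @ d)
        zlo = max(int(np.floor(min(p0[0], p1[0]) - r)), 0)
        zhi = min(int(np.ceil(max(p0[0], p1[0]) + r)), nz - 1)
        ylo = max(int(np.floor(min(p0[1], p1[1]) - r)), 0)
        yhi = min(int(np.ceil(max(p0[1], p1[1]) + r)), ny - 1)
        xlo = max(int(np.floor(min(p0[2], p1[2]) - r)), 0)
        xhi = min(int(np.ceil(max(p0[2], p1[2]) + r)), nx - 1)
        if zhi < zlo or yhi < ylo or xhi < xlo:
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(zlo, zhi + 1),
            np.arange(ylo, yhi + 1),
            np.arange(xlo, xhi + 1),
            indexing="ij",
        )
        pts_grid = np.stack([zz, yy, xx], axis=-1).astype(float)
        rel = pts_grid - p0
        if seg_len2 == 0.0:
            closest = np.zeros_like(rel)
        else:
            t = np.clip((rel @ d) / seg_len2, 0.0, 1.0)
            closest = t[..., None] * d
        dist2 = ((rel - closest) ** 2).sum(axis=-1)
        inside = dist2 <= r * r
        if not inside.any():
            continue
        block = ownership[zlo:zhi + 1, ylo:yhi + 1, xlo:xhi + 1]
        conflict = inside & (block >= 0) & (block != vessel.label)
        if conflict.any():
            other = int(block[conflict][0])
            raise GeometryConflictError(
                f"vessels {vessel.label} and {other} overlap "
                "(same voxel claimed by different labels)"
            )
        block[inside] = vessel.label


def _ground_truth_from_ownership(
    ownership: np.ndarray, artifact: np.ndarray
) -> GroundTruthMorphometry:
    per_slice: list[SliceTruth] = []
    total = small = 0
    for z in range(ownership.shape[0]):
        if artifact[z]:
            continue
        sl = ownership[z]
        labels_here = sl[sl >= 0]
        if labels_here.size:
            uniq, counts = np.unique(labels_here, return_counts=True)
            areas = {int(u): int(c) for u, c in zip(uniq, counts)}
        else:
            areas = {}
        per_slice.append(SliceTruth(z, len(areas), areas))
        total += len(areas)
        small += sum(1 for a in areas.values() if a <= 2)
    empty = total == 0
    return GroundTruthMorphometry(
        per_slice=per_slice,
        total_vessel_count_summed=total,
        small_vessel_count_summed=small,
        small_vessel_fraction=(small / total) if total else 0.0,
        empty=empty,
    )


def generate_ct_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeStack, GroundTruthMorphometry, LabelMap]:
    """Render a phantom volume with exact ground truth and true labels.

    Voxels are drawn as class mean intensity plus Gaussian noise (seeded).
    The label map is painted tissue-first, then air outside the limb
    radius, the bone annulus, and vessels on top. Ground truth is computed
    from the vessel geometry via the centre-in-tube rasterisation rule;
    artifact slices are rendered saturated white in the volume and excluded
    from ground-truth totals (the label map keeps the true geometry there,
    for segmentation testing on artifact-free specs).

    Vessels narrower than one voxel edge are generated with a
    sub-resolution warning; vessels with different labels that overlap are
    rejected with :class:`GeometryConflictError`.
    """
    nz, ny, nx = spec.dims
    labels = np.full(spec.dims, TISSUE, dtype=np.uint8)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    if spec.limb_radius_um is not None:
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        r_vox = spec.limb_radius_um / spec.voxel_size_um
        outside = (yy - cy) ** 2 + (xx - cx) ** 2 > r_vox**2
        labels[:, outside] = AIR
    if spec.bone is not None:
        by, bx = spec.bone.center_yx
        rin = spec.bone.inner_radius_um / spec.voxel_size_um
        rout = spec.bone.outer_radius_um / spec.voxel_size_um
        d2 = (yy - by) ** 2 + (xx - bx) ** 2
        annulus = (d2 >= rin**2) & (d2 <= rout**2)
        labels[:, annulus] = BONE

    ownership = np.full(spec.dims, -1, dtype=np.int32)
    for v in spec.vessels:
        if v.radius_um < spec.voxel_size_um:
            warnings.warn(
                f"vessel {v.label}: radius {v.radius_um} µm is below one "
                f"voxel edge ({spec.voxel_size_um} µm); sub-resolution vessel"
            )
        _paint_vessel(ownership, v, v.radius_um / spec.voxel_size_um)
    labels[ownership >= 0] = VESSEL

    artifact = spec.artifact_mask()
    truth = _ground_truth_from_ownership(ownership, artifact)

    intensities = np.array(
        [
            spec.class_intensities["air"],
            spec.class_intensities["tissue"],
            spec.class_intensities["vessel"],
            spec.class_intensities["bone"],
        ]
    )
    volume = intensities[labels].astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sd, size=spec.dims).astype(
            np.float32
        )
    volume[artifact] = spec.saturation_value

    stack = VolumeStack(
        volume,
        voxel_size_um=spec.voxel_size_um,
        artifact_slices=spec.artifact_slices,
    )
    label_map = LabelMap(labels, provenance={"source": "phantom", "seed": spec.seed})
    return stack, truth, label_map


def random_phantom_spec(
    seed: int,
    dims: tuple[int, int, int] = (48, 64, 64),
    n_vessels: int | None = None,
    radius_range_vox: tuple[float, float] = (0.6, 6.0),
    noise_sd: float = 0.0,
    with_artifacts: bool = True,
    voxel_size_um: float = 21.0,
) -> PhantomSpec:
    """Draw a random but well-posed phantom specification.

    Vessels are straight tubes, near-parallel to the slice axis with a
    small random tilt, placed with enough in-plane separation from each
    other, from the bone annulus and from the limb boundary that every
    vessel is a distinct connected cross-section on every slice. Vessel
    count defaults to uniform in 0..10, radii uniform in
    ``radius_range_vox`` voxels. Optionally two pin-artifact whiteout
    ranges are inserted near the ends of the stack.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = dims
    if n_vessels is None:
        n_vessels = int(rng.integers(0, 11))

    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    limb_r = 0.46 * min(ny, nx)
    bone_outer = 0.14 * min(ny, nx)
    bone = BoneCylinder(
        center_yx=(cy, cx),
        outer_radius_um=bone_outer * voxel_size_um,
        inner_radius_um=0.5 * bone_outer * voxel_size_um,
    )

    max_tilt = 2.0  # voxels of in-plane drift over the full stack
    placed: list[tuple[float, float, float]] = []  # (y, x, clearance radius)
    vessels: list[Vessel] = []
    attempts = 0
    while len(vessels) < n_vessels and attempts < 2000:
        attempts += 1
        r_vox = float(rng.uniform(*radius_range_vox))
        # clearance: tube radius + tilt drift + 2 px so cross-sections stay disjoint
        clearance = r_vox + max_tilt + 2.0
        y = float(rng.uniform(clearance, ny - 1 - clearance))
        x = float(rng.uniform(clearance, nx - 1 - clearance))
        d_center = np.hypot(y - cy, x - cx)
        if d_center < bone_outer + clearance or d_center > limb_r - clearance:
            continue
        if any(
            np.hypot(y - py, x - px) < c + clearance for py, px, c in placed
        ):
            continue
        dy, dx = rng.uniform(-max_tilt, max_tilt, size=2)
        vessels.append(
            Vessel(
                [(0.0, y - dy / 2, x - dx / 2), (nz - 1.0, y + dy / 2, x + dx / 2)],
                radius_um=r_vox * voxel_size_um,
                label=len(vessels),
            )
        )
        placed.append((y, x, clearance))

    artifact_slices: list[tuple[int, int]] = []
    if with_artifacts and nz >= 16:
        w = max(2, nz // 16)
        artifact_slices = [(2, 2 + w), (nz - 2 - w, nz - 2)]

    return PhantomSpec(
        dims=dims,
        voxel_size_um=voxel_size_um,
        vessels=vessels,
        bone=bone,
        limb_radius_um=limb_r * voxel_size_um,
        noise_sd=noise_sd,
        artifact_slices=artifact_slices,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# perfusion cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class RegionEffects:
    """Fixed-effect time course of one region in the fractured limb.

    The pre-operative mean is ``baseline``; from the moment of operation
    the mean follows baseline*(1-drop_fraction) + lin*t + quad*t² in days
    post-op, i.e. an immediate drop followed by a quadratic recovery that
    peaks and then declines.
    """

    baseline: float
    drop_fraction: float
    lin: float
    quad: float

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in [0, 1)")

    def mean(self, day: float) -> float:
        """Fractured-limb mean perfusion at the given day (PREOP_DAY = pre-op)."""
        if day == PREOP_DAY:
            return self.baseline
        return self.baseline * (1.0 - self.drop_fraction) + self.lin * day + self.quad * day**2


#: default regional time courses: the femoral-artery and cranial regions
#: respond strongly (drop then recovery peaking near two weeks at ~150-160 %
#: of baseline), the distal-femoral and caudal regions to a lesser degree
DEFAULT_REGION_EFFECTS: dict[str, RegionEffects] = {
    "femoral_artery": RegionEffects(400.0, 0.35, 12.0, -0.28),
    "distal_femoral_artery": RegionEffects(350.0, 0.35, 10.0, -0.24),
    "cranial": RegionEffects(200.0, 0.40, 18.9, -0.45),
    "caudal": RegionEffects(180.0, 0.25, 6.0, -0.15),
}

#: measurement schedule in days post-op; PREOP_DAY codes the pre-operative scan
DEFAULT_TIMEPOINTS = (PREOP_DAY, 0.0, 1.0, 2.0, 4.0, 7.0, 14.0, 28.0, 42.0)


@dataclass
class CohortSpec:
    """Generative description of a longitudinal perfusion cohort.

    Every (animal, day) draws one log-normal day multiplier (sd
    ``day_multiplier_sd`` on the log scale, fixed at exactly 1 on the
    pre-operative day, which serves as the reference) applied
    multiplicatively to BOTH limbs; each animal draws one additive normal
    intercept shared by all its series; residual noise is additive normal.
    """

    n_animals: int = 32
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    regions: Mapping[str, RegionEffects] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EFFECTS)
    )
    random_intercept_sd: float = 20.0
    day_multiplier_sd: float = 0.1
    residual_sd: float = 15.0
    seed: int = 0
    strict_positive: bool = True

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for sd in (self.random_intercept_sd, self.day_multiplier_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("sd parameters must be >= 0")
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if PREOP_DAY not in self.timepoints:
            raise ValueError("timepoints must include the pre-operative day")


def generate_ldi_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a longitudinal cohort as a tidy long-format table.

    Returns columns (animal, limb, region, day, timepoint, perfusion):
    fractured-limb regional means follow the drop-then-quadratic-recovery
    fixed effects, intact-limb means are flat at baseline, and both limbs
    of an animal share its day multiplier. Reproducible under a fixed seed.

    With ``strict_positive`` (default) any non-positive generated value —
    only possible under pathological parameter choices — raises; otherwise
    such values are clipped to a tiny positive number with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    animals = [f"A{i + 1:03d}" for i in range(spec.n_animals)]
    intercepts = rng.normal(0.0, spec.random_intercept_sd, size=spec.n_animals)

    rows = []
    for ai, animal in enumerate(animals):
        day_mult = {}
        for day in spec.timepoints:
            day_mult[day] = (
                1.0
                if day == PREOP_DAY
                else float(np.exp(rng.normal(0.0, spec.day_multiplier_sd)))
            )
        for region, eff in spec.regions.items():
            for limb in ("fractured", "intact"):
                for day in spec.timepoints:
                    mu = eff.mean(day) if limb == "fractured" else eff.baseline
                    eps = (
                        rng.normal(0.0, spec.residual_sd)
                        if spec.residual_sd > 0
                        else 0.0
                    )
                    value = (mu + intercepts[ai]) * day_mult[day] + eps
                    rows.append(
                        {
                            "animal": animal,
                            "limb": limb,
                            "region": region,
                            "day": day,
                            "timepoint": "preop" if day == PREOP_DAY else f"d{day:g}",
                            "perfusion": value,
                        }
                    )
    df = pd.DataFrame(rows)
    bad = df["perfusion"] <= 0
    if bad.any():
        if spec.strict_positive:
            raise ValueError(
                f"{int(bad.sum())} non-positive perfusion values generated; "
                "parameters are pathological (or set strict_positive=False to clip)"
            )
        warnings.warn(f"clipping {int(bad.sum())} non-positive perfusion values")
        df.loc[bad, "perfusion"] = 1e-6
    return df


# ---------------------------------------------------------------------------
# synthetic single scans
# ---------------------------------------------------------------------------

def generate_ldi_scan(
    region_means: Mapping[str, float],
    pitch_mm: float = 0.1,
    size_mm: tuple[float, float] = (25.0, 25.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float | None = None,
    metadata: dict | None = None,
) -> tuple[PerfusionScan, ROISet]:
    """Render a synthetic perfusion map with its generating ROI set.

    The layout mimics a medial-thigh scan: a high-perfusion femoral-artery
    stripe runs the height of the field (proximal half = femoral artery,
    distal half = distal femoral artery), with the cranial field to its
    left and the caudal field to its right. Each region is painted at its
    requested mean; Gaussian noise is added and clipped at zero. The ROI
    set used for generation is returned so ROI extraction can be tested
    round-trip.
    """
    missing = set(REGIONS) - set(region_means)
    if missing:
        raise ValueError(f"region_means lacks regions: {sorted(missing)}")
    h = int(round(size_mm[0] / pitch_mm))
    w = int(round(size_mm[1] / pitch_mm))
    if h < 10 or w < 10:
        raise ValueError("scan grid too small for the standard layout")

    c0, c1 = int(0.46 * w), int(0.54 * w)
    rois = ROISet(
        {
            "femoral_artery": ROI(rect=(int(0.05 * h), int(0.45 * h), c0, c1)),
            "distal_femoral_artery": ROI(rect=(int(0.55 * h), int(0.95 * h), c0, c1)),
            "cranial": ROI(rect=(int(0.25 * h), int(0.75 * h), int(0.08 * w), int(0.40 * w))),
            "caudal": ROI(rect=(int(0.25 * h), int(0.75 * h), int(0.60 * w), int(0.92 * w))),
        }
    )

    if background is None:
        background = 0.75 * min(region_means.values())
    grid = np.full((h, w), float(background))
    # artery stripe first, halves at the two artery means
    grid[: h // 2, c0:c1] = region_means["femoral_artery"]
    grid[h // 2:, c0:c1] = region_means["distal_femoral_artery"]
    for region in ("cranial", "caudal"):
        r0, r1, cc0, cc1 = rois[region].rect
        grid[r0:r1, cc0:cc1] = region_means[region]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = np.clip(grid + rng.normal(0.0, noise_sd, size=grid.shape), 0.0, None)

    scan = PerfusionScan(grid, pixel_pitch_mm=pitch_mm, metadata=metadata or {})
    return scan, rois
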