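"""Micro-CT vessel morphometry for contrast-perfused limbs.

Volumes of Microfil-perfused limbs are segmented into four tissue classes
(air < tissue < vessel < bone, in order of increasing CT density; the
contrast-filled vessels sit between soft tissue and bone), the vessel class
is cleaned into a binary mask, and vessels are quantified slice by slice:
2D connected components are counted as vessel cross-sections, their pixel
areas are binned into decade size classes, and the small-vessel fraction
(cross-sections of area <= 2 voxels over all cross-sections) summarises the
prevalence of newly formed small vessels.

Counting is deliberately per-2D-slice and summed over the analysed region:
a single 3D vessel running through N slices contributes N cross-sections.
No 3D deduplication is attempted; "vessel number" is a slice-wise aggregate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage import measure, morphology

from . import stats as _stats

#: tissue classes in order of increasing CT density; index = label value
CLASS_NAMES = ("air", "tissue", "vessel", "bone")
AIR, TISSUE, VESSEL, BONE = range(4)

#: decade bin upper bounds in voxels; right-closed bins (prev, upper]
DECADE_BIN_UPPERS = (1, 2, 5, 10, 50, 100, 500, 1000, 5000, math.inf)

#: cross-sections of this area (voxels) or less count as "small vessels"
SMALL_VESSEL_MAX_AREA = 2


class DegenerateHistogramError(ValueError):
    """Raised when the gray-value histogram cannot support four classes."""


class GeometryError(ValueError):
    """Raised for inconsistent region/pin geometry."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VolumeStack:
    """A 3D grayscale stack, slice axis first (z, y, x), 0-based.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Gray values; any numeric dtype.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (21 for the scans this
        pipeline was designed around).
    artifact_slices : sequence of (start, stop)
        Half-open slice-index ranges whited out by fixator-pin artifacts;
        excluded from all quantification.
    """

    voxels: np.ndarray
    voxel_size_um: float = 21.0
    axis_order: str = "zyx"
    artifact_slices: Sequence[tuple[int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be 3D with at least one voxel per axis")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.axis_order != "zyx":
            raise ValueError("only 'zyx' axis order is supported")
        self.artifact_slices = tuple(
            (int(a), int(b)) for a, b in self.artifact_slices
        )
        nz = self.voxels.shape[0]
        for a, b in self.artifact_slices:
            if not (0 <= a < b <= nz):
                raise ValueError(f"artifact range [{a}, {b}) outside [0, {nz})")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def artifact_mask(self) -> np.ndarray:
        """Boolean per-slice mask, True where a slice is artifact-affected."""
        mask = np.zeros(self.n_slices, dtype=bool)
        for a, b in self.artifact_slices:
            mask[a:b] = True
        return mask


@dataclass
class LabelMap:
    """Per-voxel tissue class (0=air, 1=tissue, 2=vessel, 3=bone)."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if self.labels.min() < 0 or self.labels.max() > 3:
            raise ValueError("labels must be in 0..3")


@dataclass
class VesselMask:
    """Binary vessel mask after cleanup; cleanup parameters are recorded."""

    mask: np.ndarray
    cleanup_params: dict = field(default_factory=dict)
    artifact_slices: Sequence[tuple[int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.artifact_slices = tuple((int(a), int(b)) for a, b in self.artifact_slices)

    def artifact_mask(self) -> np.ndarray:
        out = np.zeros(self.mask.shape[0], dtype=bool)
        for a, b in self.artifact_slices:
            out[a:b] = True
        return out


@dataclass
class SliceVesselStats:
    """Vessel cross-section statistics for one analysed slice."""

    slice_index: int
    vessel_count: int
    per_vessel_areas: list[int]
    total_vessel_area_voxels: int
    total_vessel_area_um2: float
    area_fraction: float
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.vessel_count != len(self.per_vessel_areas):
            raise ValueError("vessel_count must equal len(per_vessel_areas)")
        if self.total_vessel_area_voxels != sum(self.per_vessel_areas):
            raise ValueError("total area must equal the sum of per-vessel areas")
        if not 0.0 <= self.area_fraction <= 1.0:
            raise ValueError("area_fraction must be in [0, 1]")


@dataclass
class VesselSizeHistogram:
    """Decade histogram of cross-section areas summed over analysed slices.

    Bins are right-closed intervals (prev_upper, upper] with upper bounds
    1, 2, 5, 10, 50, 100, 500, 1000, 5000 voxels plus an overflow bin, so
    the bin counts always sum to the total number of cross-sections.
    ``small_vessel_fraction`` is the number of cross-sections of area <= 2
    voxels divided by the total number (0, with ``empty=True``, when there
    are no vessels at all).
    """

    bin_uppers: tuple = DECADE_BIN_UPPERS
    counts: tuple = ()
    n_total: int = 0
    n_small: int = 0
    small_vessel_fraction: float = 0.0
    empty: bool = False

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n_total:
            raise ValueError("bin counts must sum to the total vessel number")
        if not 0.0 <= self.small_vessel_fraction <= 1.0:
            raise ValueError("small_vessel_fraction must be in [0, 1]")


@dataclass
class RegionSelection:
    """Half-open slice interval selecting the analysed region.

    ``between_pins`` selects the fracture zone between fixator pins 2 and 3
    of a fractured limb; ``mid_third`` selects the middle third of an intact
    femur, the level-matched control region.
    """

    mode: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.mode not in ("between_pins", "mid_third", "full"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if not self.start < self.stop:
            raise GeometryError(
                f"empty slice interval [{self.start}, {self.stop})"
            )

    @classmethod
    def mid_third(cls, n_slices: int) -> "RegionSelection":
        """Middle third of an ``n_slices`` stack, floor/ceil to integers."""
        start = math.floor(n_slices / 3)
        stop = math.ceil(2 * n_slices / 3)
        return cls("mid_third", start, stop)

    @classmethod
    def between_pins(
        cls, pin_artifact_ranges: Sequence[tuple[int, int]]
    ) -> "RegionSelection":
        """Interval between the artifact ranges of pins 2 and 3.

        ``pin_artifact_ranges`` are the four half-open whiteout ranges of the
        fixator pins, sorted proximal to distal. The analysed interval runs
        from the first slice after pin 2's range to the first slice of pin
        3's range.
        """
        ranges = [(int(a), int(b)) for a, b in pin_artifact_ranges]
        if len(ranges) != 4:
            raise GeometryError(f"expected 4 pin ranges, got {len(ranges)}")
        if ranges != sorted(ranges):
            raise GeometryError("pin ranges must be sorted proximal to distal")
        start, stop = ranges[1][1], ranges[2][0]
        if start >= stop:
            raise GeometryError(
                f"no gap between pin 2 (ends {start}) and pin 3 (starts {stop})"
            )
        return cls("between_pins", start, stop)

    @property
    def n_slices(self) -> int:
        return self.stop - self.start

    def span_mm(self, voxel_size_um: float) -> float:
        """Physical length of the selected interval in millimetres."""
        return self.n_slices * voxel_size_um / 1000.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _mode_valley_thresholds(sample: np.ndarray) -> list[float]:
    """Three cut values from the modes of the gray-value histogram.

    Peaks of the Gaussian-smoothed log-histogram are the tissue-class
    modes. With four modes, each cut sits at the histogram valley between
    consecutive modes. Vessels are typically a fraction of a percent of the
    voxels, so a criterion that weights classes by their mass (e.g.
    multi-level Otsu) will split a dominant mode before isolating the
    vessel band; valley positions are insensitive to class imbalance. When
    only three modes are present the absent class is taken to be the
    contrast-filled vessel band — rare by nature and, by the contrast
    protocol, midway in density between soft tissue and bone — and its two
    cuts are placed at 1/4 and 3/4 of the tissue-to-bone mode distance.
    """
    counts, edges = np.histogram(sample, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    smooth = ndimage.gaussian_filter1d(np.log1p(counts.astype(float)), sigma=2.0)
    # pad so modes sitting in the first/last bin are still detected as peaks
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    peaks, props = signal.find_peaks(padded, prominence=0.5)
    peaks = peaks - 1
    if len(peaks) > 4:
        order = np.argsort(props["prominences"])[::-1][:4]
        peaks = np.sort(peaks[order])
    if len(peaks) < 3:
        present = [CLASS_NAMES[i] for i in range(len(peaks))]
        raise DegenerateHistogramError(
            f"histogram shows only {len(peaks)} mode(s); cannot separate "
            f"four classes (at most {present} distinguishable)"
        )

    def valley(i, j):
        k = i + int(np.argmin(smooth[i:j + 1]))
        return float(centers[k])

    if len(peaks) == 4:
        return [valley(peaks[k], peaks[k + 1]) for k in range(3)]
    # three modes: infer the vessel band between the tissue and bone modes
    p_air, p_tissue, p_bone = peaks
    t_mode, b_mode = float(centers[p_tissue]), float(centers[p_bone])
    return [
        valley(p_air, p_tissue),
        t_mode + 0.25 * (b_mode - t_mode),
        t_mode + 0.75 * (b_mode - t_mode),
    ]


def segment_four_class(
    volume: VolumeStack,
    method: str = "multi_threshold",
    thresholds: Sequence[float] | None = None,
) -> LabelMap:
    """Classify every voxel as air, tissue, vessel or bone.

    Classes are assigned monotonically in gray value: three increasing cut
    points map intensity bins to air < tissue < vessel < bone. In
    ``multi_threshold`` mode the cuts are chosen automatically from the
    modes of the histogram of non-artifact slices (see
    :func:`_mode_valley_thresholds`); in ``supplied_thresholds`` mode the
    caller provides exactly three strictly increasing cut values. The
    thresholds used are recorded in the label map's provenance.

    Raises
    ------
    DegenerateHistogramError
        If the histogram cannot support four classes (e.g. a constant
        volume), naming the collapse.
    """
    vox = volume.voxels
    if method == "supplied_thresholds":
        if thresholds is None or len(thresholds) != 3:
            raise ValueError("supplied_thresholds mode needs exactly 3 cut values")
        cuts = [float(t) for t in thresholds]
        if not cuts[0] < cuts[1] < cuts[2]:
            raise ValueError("thresholds must be strictly increasing")
    elif method == "multi_threshold":
        keep = ~volume.artifact_mask()
        sample = vox[keep] if keep.any() else vox
        n_distinct = np.unique(sample).size
        if n_distinct < 3:
            raise DegenerateHistogramError(
                f"only {n_distinct} distinct gray value(s): classes "
                f"{CLASS_NAMES[n_distinct - 1:]} collapse and cannot be separated"
            )
        cuts = _mode_valley_thresholds(sample.ravel())
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    labels = np.digitize(vox, cuts).astype(np.uint8)
    return LabelMap(
        labels,
        provenance={"method": method, "thresholds": [float(c) for c in cuts]},
    )


# ---------------------------------------------------------------------------
# mask cleanup
# ---------------------------------------------------------------------------

def clean_vessel_mask(
    labels: LabelMap | np.ndarray,
    close_radius: int = 1,
    median_radius: int = 1,
    min_size: int = 2,
    artifact_slices: Sequence[tuple[int, int]] = (),
) -> VesselMask:
    """Binarise the vessel class and smooth/cohere it into a clean mask.

    Order of operations: binarise -> in-plane morphological closing
    (disk of ``close_radius``) -> in-plane median smoothing (disk of
    ``median_radius``) -> removal of 3D connected components smaller than
    ``min_size`` voxels (26-connectivity). The size filter is 3D on purpose:
    isolated noise voxels are 3D singletons, while genuine sub-resolution
    vessels persist across slices, so a 3D filter suppresses speckle without
    deleting true 1-voxel cross-sections. With all parameters 0 the mask
    equals the raw vessel class exactly. Artifact slices are always zeroed.
    """
    if any(p < 0 for p in (close_radius, median_radius, min_size)):
        raise ValueError("cleanup parameters must be >= 0")
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    mask = lab == VESSEL

    if close_radius > 0:
        # square footprint: a gap of up to close_radius voxels is bridged
        footprint = np.ones((2 * close_radius + 1,) * 2, dtype=bool)
        mask = np.stack(
            [morphology.closing(sl, footprint) for sl in mask]
        )
    if median_radius > 0:
        footprint = morphology.disk(median_radius)
        mask = np.stack(
            [
                ndimage.median_filter(sl.astype(np.uint8), footprint=footprint) > 0
                for sl in mask
            ]
        )
    if min_size > 0:
        # remove components strictly smaller than min_size voxels
        mask = morphology.remove_small_objects(
            mask, max_size=min_size - 1, connectivity=3
        )

    for a, b in artifact_slices:
        mask[a:b] = False
    return VesselMask(
        mask,
        cleanup_params={
            "close_radius": close_radius,
            "median_radius": median_radius,
            "min_size": min_size,
        },
        artifact_slices=artifact_slices,
    )


# ---------------------------------------------------------------------------
# region selection and per-slice counting
# ---------------------------------------------------------------------------

def select_region(stack_or_mask, selection: RegionSelection):
    """Return the sub-stack of slices selected by ``selection``.

    Accepts a :class:`VolumeStack`, :class:`VesselMask` or bare 3D array
    and returns the same kind restricted to ``[start, stop)``. Artifact
    ranges are clipped into the new coordinate frame.
    """

    def _shift_ranges(ranges, start, stop):
        out = []
        for a, b in ranges:
            a2, b2 = max(a, start) - start, min(b, stop) - start
            if a2 < b2:
                out.append((a2, b2))
        return tuple(out)

    s = selection
    if isinstance(stack_or_mask, VolumeStack):
        if s.stop > stack_or_mask.n_slices:
            raise GeometryError("selection extends past the end of the stack")
        return VolumeStack(
            stack_or_mask.voxels[s.start:s.stop],
            voxel_size_um=stack_or_mask.voxel_size_um,
            artifact_slices=_shift_ranges(
                stack_or_mask.artifact_slices, s.start, s.stop
            ),
        )
    if isinstance(stack_or_mask, VesselMask):
        if s.stop > stack_or_mask.mask.shape[0]:
            raise GeometryError("selection extends past the end of the mask")
        return VesselMask(
            stack_or_mask.mask[s.start:s.stop],
            cleanup_params=dict(stack_or_mask.cleanup_params),
            artifact_slices=_shift_ranges(
                stack_or_mask.artifact_slices, s.start, s.stop
            ),
        )
    arr = np.asarray(stack_or_mask)
    if s.stop > arr.shape[0]:
        raise GeometryError("selection extends past the end of the array")
    return arr[s.start:s.stop]


def count_vessels_per_slice(
    mask: VesselMask,
    selection: RegionSelection | None = None,
    connectivity: int = 8,
    voxel_size_um: float = 21.0,
) -> list[SliceVesselStats]:
    """Count vessel cross-sections on every analysed slice.

    Each slice is labelled independently by 2D connected components at the
    given in-plane connectivity (4 or 8); one component = one vessel
    cross-section. Slices inside artifact ranges are flagged and carry zero
    counts so they never contribute to totals. ``area_fraction`` is total
    vessel area over the full slice area.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    arr = mask.mask
    start, stop = (0, arr.shape[0]) if selection is None else (
        selection.start, selection.stop,
    )
    if stop > arr.shape[0]:
        raise GeometryError("selection extends past the end of the mask")
    artifact = mask.artifact_mask()
    slice_area = arr.shape[1] * arr.shape[2]
    um2_per_voxel = voxel_size_um ** 2

    out: list[SliceVesselStats] = []
    for z in range(start, stop):
        if artifact[z]:
            out.append(
                SliceVesselStats(z, 0, [], 0, 0.0, 0.0, artifact=True)
            )
            continue
        lab, n = measure.label(
            arr[z], connectivity=skimage_conn, return_num=True
        )
        areas = np.bincount(lab.ravel(), minlength=n + 1)[1:] if n else np.array([], int)
        total = int(areas.sum())
        out.append(
            SliceVesselStats(
                slice_index=z,
                vessel_count=int(n),
                per_vessel_areas=[int(a) for a in areas],
                total_vessel_area_voxels=total,
                total_vessel_area_um2=total * um2_per_voxel,
                area_fraction=total / slice_area,
            )
        )
    return out


# ---------------------------------------------------------------------------
# size distribution
# ---------------------------------------------------------------------------

def size_histogram(stats: Sequence[SliceVesselStats]) -> VesselSizeHistogram:
    """Bin all cross-section areas into decade size classes.

    Each area is assigned to the first bin whose upper bound is >= the area
    (right-closed decades 1, 2, 5, 10, 50, 100, 500, 1000, 5000 voxels plus
    overflow). Artifact-flagged slices are ignored. An empty region yields
    ``small_vessel_fraction = 0`` with ``empty=True`` rather than NaN.
    """
    if not stats:
        raise ValueError("stats must be non-empty")
    areas: list[int] = []
    for s in stats:
        if s.artifact:
            continue
        areas.extend(s.per_vessel_areas)
    areas_arr = np.asarray(areas, dtype=float)
    if areas_arr.size and areas_arr.min() <= 0:
        raise ValueError("vessel areas must be positive")

    uppers = np.asarray(DECADE_BIN_UPPERS, dtype=float)
    counts = np.zeros(len(DECADE_BIN_UPPERS), dtype=int)
    if areas_arr.size:
        idx = np.searchsorted(uppers, areas_arr, side="left")
        np.add.at(counts, idx, 1)
    n_total = int(areas_arr.size)
    n_small = int((areas_arr <= SMALL_VESSEL_MAX_AREA).sum())
    return VesselSizeHistogram(
        bin_uppers=DECADE_BIN_UPPERS,
        counts=tuple(int(c) for c in counts),
        n_total=n_total,
        n_small=n_small,
        small_vessel_fraction=(n_small / n_total) if n_total else 0.0,
        empty=n_total == 0,
    )


def area_to_physical(area_voxels: float, voxel_size_um: float) -> dict:
    """Convert a cross-section area in voxels to physical units.

    Returns the area in µm² and the diameter (µm) of the circle with the
    same area — the conventional way to express vessel calibre from a
    cross-section.
    """
    if area_voxels < 1:
        raise ValueError("area_voxels must be >= 1")
    if not voxel_size_um > 0:
        raise ValueError("voxel_size_um must be positive")
    area_um2 = area_voxels * voxel_size_um ** 2
    return {
        "area_um2": area_um2,
        "equivalent_diameter_um": 2.0 * math.sqrt(area_um2 / math.pi),
    }


# ---------------------------------------------------------------------------
# limb comparison
# ---------------------------------------------------------------------------

@dataclass
class LimbComparison:
    """Per-animal fractured-vs-intact paired comparison of morphometry."""

    animals: list
    count_differences: np.ndarray
    small_fraction_differences: np.ndarray
    count_test: "_stats.PairedTResult"
    small_fraction_test: "_stats.PairedTResult"


def compare_limbs(
    fractured: Mapping[object, VesselSizeHistogram],
    intact: Mapping[object, VesselSizeHistogram],
    m: int = 2,
) -> LimbComparison:
    """Pair fractured and intact morphometry per animal and test differences.

    Computes per-animal paired differences (fractured minus intact) in total
    vessel count and small-vessel fraction and applies a paired t-test with
    Bonferroni correction for the family of ``m`` comparisons.
    """
    missing = sorted(set(fractured) ^ set(intact), key=str)
    if missing:
        raise ValueError(f"unmatched animals between limbs: {missing}")
    animals = sorted(fractured, key=str)
    f_counts = np.array([fractured[a].n_total for a in animals], dtype=float)
    i_counts = np.array([intact[a].n_total for a in animals], dtype=float)
    f_small = np.array(
        [fractured[a].small_vessel_fraction for a in animals], dtype=float
    )
    i_small = np.array(
        [intact[a].small_vessel_fraction for a in animals], dtype=float
    )
    return LimbComparison(
        animals=list(animals),
        count_differences=f_counts - i_counts,
        small_fraction_differences=f_small - i_small,
        count_test=_stats.paired_t_bonferroni(f_counts, i_counts, m=m),
        small_fraction_test=_stats.paired_t_bonferroni(f_small, i_small, m=m),
    )
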