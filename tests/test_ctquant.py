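"""Segmentation, cleanup, region selection, counting and size histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracvasc import ctquant, phantom
from fracvasc.ctquant import (
    AIR, BONE, TISSUE, VESSEL,
    DegenerateHistogramError,
    GeometryError,
    LabelMap,
    RegionSelection,
    SliceVesselStats,
    VesselMask,
    VolumeStack,
)

from _oracles import brute_closing, decade_bin_counts, flood_fill_components


def _mask(arr, artifact=()):
    return VesselMask(np.asarray(arr, dtype=bool), artifact_slices=artifact)


class TestSegmentation:
    def _plateau_volume(self, noise_sd=0.0, seed=0):
        spec = phantom.PhantomSpec(
            dims=(8, 40, 40),
            vessels=[phantom.Vessel.axial(20.0, 20.0, 4 * 21.0, 0, 7)],
            bone=phantom.BoneCylinder((10.0, 10.0), 6 * 21.0, 3 * 21.0),
            limb_radius_um=18 * 21.0,
            noise_sd=noise_sd,
            seed=seed,
        )
        return phantom.generate_ct_phantom(spec)

    def test_noiseless_plateaus_classified_perfectly(self):
        stack, _, labels = self._plateau_volume()
        seg = ctquant.segment_four_class(stack)
        assert (seg.labels == labels.labels).mean() == 1.0
        assert seg.provenance["method"] == "multi_threshold"
        assert len(seg.provenance["thresholds"]) == 3

    def test_noisy_plateaus_agree_above_99_percent(self):
        # noise sd 10 against inter-class spacing 80: Gaussian-tail
        # misclassification at midpoint thresholds is ~2*Phi(-4) per voxel
        stack, _, labels = self._plateau_volume(noise_sd=10.0, seed=4)
        seg = ctquant.segment_four_class(stack)
        assert (seg.labels == labels.labels).mean() >= 0.99

    def test_constant_volume_is_an_error_not_a_one_class_map(self):
        vol = VolumeStack(np.full((4, 8, 8), 50.0))
        with pytest.raises(DegenerateHistogramError, match="distinct"):
            ctquant.segment_four_class(vol)

    def test_supplied_thresholds_and_monotone_assignment(self):
        vol = VolumeStack(
            np.array([[[0.0, 70.0], [150.0, 230.0]]])
        )
        seg = ctquant.segment_four_class(
            vol, method="supplied_thresholds", thresholds=[40, 120, 200]
        )
        np.testing.assert_array_equal(
            seg.labels[0], [[AIR, TISSUE], [VESSEL, BONE]]
        )

    def test_supplied_thresholds_must_increase(self):
        vol = VolumeStack(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="strictly increasing"):
            ctquant.segment_four_class(
                vol, method="supplied_thresholds", thresholds=[100, 50, 200]
            )


class TestCleanVesselMask:
    def test_all_zero_parameters_is_identity(self, rng):
        labels = rng.integers(0, 4, size=(4, 16, 16)).astype(np.uint8)
        out = ctquant.clean_vessel_mask(LabelMap(labels), 0, 0, 0)
        np.testing.assert_array_equal(out.mask, labels == VESSEL)

    def test_closing_bridges_one_voxel_gap(self):
        # two segments separated by a single-voxel gap in-plane
        labels = np.zeros((1, 9, 9), dtype=np.uint8)
        labels[0, 4, 1:4] = VESSEL
        labels[0, 4, 5:8] = VESSEL
        out = ctquant.clean_vessel_mask(LabelMap(labels), close_radius=1,
                                        median_radius=0, min_size=0)
        comps = flood_fill_components(out.mask[0], 8)
        assert len(comps) == 1
        np.testing.assert_array_equal(
            out.mask[0], brute_closing(labels[0] == VESSEL, 1)
        )

    def test_min_size_removes_speckle_keeps_vessels(self):
        labels = np.zeros((3, 8, 8), dtype=np.uint8)
        labels[1, 2, 2] = VESSEL            # isolated 1-voxel speckle
        labels[:, 5, 5] = VESSEL            # 3-voxel vessel through the stack
        labels[:, 5, 6] = VESSEL            # area 2 per slice
        out = ctquant.clean_vessel_mask(LabelMap(labels), 0, 0, min_size=2)
        assert not out.mask[1, 2, 2]
        assert out.mask[:, 5, 5:7].all()

    def test_artifact_slices_forced_to_zero(self):
        labels = np.full((4, 6, 6), VESSEL, dtype=np.uint8)
        out = ctquant.clean_vessel_mask(
            LabelMap(labels), 0, 0, 0, artifact_slices=[(1, 3)]
        )
        assert out.mask[0].all() and out.mask[3].all()
        assert not out.mask[1:3].any()

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ctquant.clean_vessel_mask(LabelMap(np.zeros((1, 2, 2), np.uint8)), -1, 0, 0)


class TestRegionSelection:
    def test_mid_third_of_1500_slices(self):
        sel = RegionSelection.mid_third(1500)
        assert (sel.start, sel.stop) == (500, 1000)

    def test_mid_third_rounds_outward(self):
        sel = RegionSelection.mid_third(100)
        assert (sel.start, sel.stop) == (33, 67)

    def test_between_pins_interval_and_physical_span(self):
        sel = RegionSelection.between_pins(
            [(100, 120), (400, 420), (800, 820), (1100, 1120)]
        )
        assert (sel.start, sel.stop) == (420, 800)
        assert sel.n_slices == 380
        # 380 slices at 21 um ~ 8 mm, the expected fracture-zone length
        assert sel.span_mm(21.0) == pytest.approx(7.98)

    def test_between_pins_no_gap_is_error(self):
        with pytest.raises(GeometryError, match="no gap"):
            RegionSelection.between_pins(
                [(0, 10), (20, 40), (40, 60), (70, 80)]
            )

    def test_unsorted_pins_rejected(self):
        with pytest.raises(GeometryError, match="sorted"):
            RegionSelection.between_pins(
                [(400, 420), (100, 120), (800, 820), (1100, 1120)]
            )

    def test_select_region_slices_and_shifts_artifacts(self):
        vol = VolumeStack(np.arange(60, dtype=float).reshape(15, 2, 2),
                          artifact_slices=[(4, 6)])
        sel = RegionSelection.mid_third(15)
        sub = ctquant.select_region(vol, sel)
        assert sub.n_slices == 5
        assert sub.voxels[0, 0, 0] == 5 * 4
        assert sub.artifact_slices == ((0, 1),)


class TestCounting:
    def test_two_disjoint_squares(self):
        m = np.zeros((1, 8, 8), dtype=bool)
        m[0, 1:3, 1:3] = True
        m[0, 5:7, 5:7] = True
        (s,) = ctquant.count_vessels_per_slice(_mask(m), connectivity=8)
        assert s.vessel_count == 2
        assert sorted(s.per_vessel_areas) == [4, 4]
        assert s.total_vessel_area_voxels == 8
        assert s.area_fraction == pytest.approx(8 / 64)

    def test_diagonal_chain_connectivity_dependence(self):
        m = np.zeros((1, 5, 5), dtype=bool)
        m[0, [1, 2, 3], [1, 2, 3]] = True
        (s8,) = ctquant.count_vessels_per_slice(_mask(m), connectivity=8)
        (s4,) = ctquant.count_vessels_per_slice(_mask(m), connectivity=4)
        assert (s8.vessel_count, s8.per_vessel_areas) == (1, [3])
        assert (s4.vessel_count, sorted(s4.per_vessel_areas)) == (3, [1, 1, 1])

    def test_empty_slice(self):
        (s,) = ctquant.count_vessels_per_slice(_mask(np.zeros((1, 4, 4), bool)))
        assert s.vessel_count == 0 and s.area_fraction == 0.0

    def test_artifact_slices_flagged_and_zero(self):
        m = np.ones((3, 4, 4), dtype=bool)
        stats = ctquant.count_vessels_per_slice(_mask(m, artifact=[(1, 2)]))
        assert [s.artifact for s in stats] == [False, True, False]
        assert stats[1].vessel_count == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        density=st.floats(0.05, 0.6),
        connectivity=st.sampled_from([4, 8]),
    )
    def test_counts_match_flood_fill_oracle(self, seed, density, connectivity):
        rng = np.random.default_rng(seed)
        m = rng.random((4, 24, 24)) < density
        stats = ctquant.count_vessels_per_slice(_mask(m), connectivity=connectivity)
        for z, s in enumerate(stats):
            oracle = flood_fill_components(m[z], connectivity)
            assert sorted(s.per_vessel_areas) == oracle
            assert s.vessel_count == len(oracle)
            assert s.total_vessel_area_voxels == sum(oracle)
            assert 0.0 <= s.area_fraction <= 1.0


class TestSizeHistogram:
    def _stats_from_areas(self, areas):
        return [
            SliceVesselStats(
                0, len(areas), list(areas), sum(areas),
                float(sum(areas)), min(sum(areas) / 10_000.0, 1.0),
            )
        ]

    def test_worked_example(self):
        hist = ctquant.size_histogram(self._stats_from_areas([1, 1, 2, 7, 600]))
        expected = {1: 2, 2: 1, 10: 1, 1000: 1}
        for upper, count in zip(hist.bin_uppers, hist.counts):
            assert count == expected.get(upper, 0)
        assert hist.small_vessel_fraction == pytest.approx(0.6)

    def test_all_small_gives_fraction_one(self):
        hist = ctquant.size_histogram(self._stats_from_areas([1, 2, 2, 1]))
        assert hist.small_vessel_fraction == 1.0

    def test_empty_region_flagged_zero_not_nan(self):
        hist = ctquant.size_histogram(
            [SliceVesselStats(0, 0, [], 0, 0.0, 0.0)]
        )
        assert hist.small_vessel_fraction == 0.0
        assert hist.empty

    def test_nonpositive_area_rejected(self):
        bad = [SliceVesselStats(0, 1, [0], 0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="positive"):
            ctquant.size_histogram(bad)

    def test_random_areas_match_brute_force_binning(self, rng):
        areas = rng.integers(1, 10_000, size=10_000).tolist()
        hist = ctquant.size_histogram(self._stats_from_areas(areas))
        assert list(hist.counts) == decade_bin_counts(areas, hist.bin_uppers)
        assert sum(hist.counts) == 10_000

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(areas=st.lists(st.integers(1, 6000), min_size=1, max_size=200))
    def test_conservation_and_small_fraction_definition(self, areas):
        hist = ctquant.size_histogram(self._stats_from_areas(areas))
        assert sum(hist.counts) == len(areas)
        # small fraction = (bin <=1 + bin (1,2]) / total
        assert hist.n_small == hist.counts[0] + hist.counts[1]
        assert hist.small_vessel_fraction == pytest.approx(
            sum(1 for a in areas if a <= 2) / len(areas)
        )


class TestPhysicalConversion:
    @pytest.mark.parametrize(
        "area,vs,expect_area,expect_diam",
        [
            (1, 21.0, 441.0, 2 * math.sqrt(441.0 / math.pi)),
            (2, 21.0, 882.0, 2 * math.sqrt(882.0 / math.pi)),
            (1, 1.0, 1.0, 2 * math.sqrt(1.0 / math.pi)),
        ],
    )
    def test_closed_form(self, area, vs, expect_area, expect_diam):
        out = ctquant.area_to_physical(area, vs)
        assert out["area_um2"] == pytest.approx(expect_area)
        assert out["equivalent_diameter_um"] == pytest.approx(expect_diam)

    def test_single_voxel_diameters_at_21_um(self):
        # 1 and 2 voxel cross-sections at 21 um: ~23.7 and ~33.5 um calibre
        assert ctquant.area_to_physical(1, 21.0)["equivalent_diameter_um"] == pytest.approx(23.7, abs=0.05)
        assert ctquant.area_to_physical(2, 21.0)["equivalent_diameter_um"] == pytest.approx(33.5, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ctquant.area_to_physical(0, 21.0)
        with pytest.raises(ValueError):
            ctquant.area_to_physical(1, 0.0)


class TestCompareLimbs:
    def _hist(self, n_total, n_small):
        counts = [0] * len(ctquant.DECADE_BIN_UPPERS)
        counts[1] = n_small
        counts[4] = n_total - n_small
        return ctquant.VesselSizeHistogram(
            counts=tuple(counts), n_total=n_total, n_small=n_small,
            small_vessel_fraction=n_small / n_total if n_total else 0.0,
            empty=n_total == 0,
        )

    def test_identical_limbs_zero_differences(self):
        h = {a: self._hist(50, 10) for a in "abcd"}
        cmp = ctquant.compare_limbs(h, dict(h))
        assert (cmp.count_differences == 0).all()
        assert (cmp.small_fraction_differences == 0).all()
        assert cmp.count_test.t == 0.0 and cmp.count_test.p_raw == 1.0

    def test_constant_offset_recovered(self):
        frac = {a: self._hist(55, 10) for a in "abcd"}
        intact = {a: self._hist(50, 10) for a in "abcd"}
        cmp = ctquant.compare_limbs(frac, intact)
        assert (cmp.count_differences == 5).all()
        assert cmp.count_test.degenerate  # exact constant difference

    def test_extra_small_vessels_shift_mean_difference(self, generate_quiet):
        """Fractured phantoms with k extra sub-resolution vessels recover k."""
        k = 3
        diffs = []
        for seed in range(4):
            intact_spec = phantom.random_phantom_spec(
                seed, dims=(12, 64, 64), n_vessels=4,
                radius_range_vox=(2.0, 4.0), with_artifacts=False,
            )
            extra = []
            used = [(v.centerline[0][1], v.centerline[0][2]) for v in intact_spec.vessels]
            rng = np.random.default_rng(seed + 100)
            while len(extra) < k:
                y, x = rng.uniform(12, 52, size=2)
                if all(np.hypot(y - py, x - px) > 9 for py, px in used):
                    extra.append((y, x))
                    used.append((y, x))
            frac_spec = phantom.PhantomSpec(
                dims=intact_spec.dims,
                vessels=list(intact_spec.vessels) + [
                    phantom.Vessel.axial(y, x, 0.7 * 21.0, 0, 11, label=10 + i)
                    for i, (y, x) in enumerate(extra)
                ],
                bone=intact_spec.bone,
                limb_radius_um=intact_spec.limb_radius_um,
            )
            _, t_intact, _ = generate_quiet(intact_spec)
            _, t_frac, _ = generate_quiet(frac_spec)
            n_slices = intact_spec.dims[0]
            diffs.append(
                (t_frac.total_vessel_count_summed - t_intact.total_vessel_count_summed)
                / n_slices
            )
        assert np.mean(diffs) == pytest.approx(k)

    def test_unmatched_animals_listed(self):
        frac = {"a": self._hist(10, 2), "b": self._hist(10, 2)}
        intact = {"a": self._hist(10, 2), "c": self._hist(10, 2)}
        with pytest.raises(ValueError, match=r"\['b', 'c'\]"):
            ctquant.compare_limbs(frac, intact)
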