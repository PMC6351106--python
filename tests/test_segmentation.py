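"""Nuclei mask, watershed splitting, area filter, fractional counting, bright cells."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

import lc3quant as lq
from conftest import disc_mask
from oracles import brute_force_otsu


class TestOtsuMask:
    def test_two_level_image_threshold_between_classes(self):
        img = np.full((64, 64), 10.0)
        img[disc_mask((64, 64), (32, 32), 12)] = 200.0
        mask = lq.make_nuclei_mask(img, smoothing_sigma=0)
        assert np.array_equal(mask, img == 200.0)

    def test_threshold_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        img = np.concatenate([
            rng.normal(60, 12, 3000), rng.normal(180, 20, 1000)
        ]).clip(0, 255).round().reshape(80, 50)
        from skimage.filters import threshold_otsu

        t_impl = threshold_otsu(img, nbins=256)
        t_oracle, _ = brute_force_otsu(img, nbins=256)
        assert t_impl == pytest.approx(t_oracle, abs=1e-9)

    def test_smoothing_is_inert_on_well_separated_classes(self):
        img = np.full((96, 96), 50.0)
        img[disc_mask((96, 96), (48, 48), 20)] = 1000.0
        m0 = lq.make_nuclei_mask(img, smoothing_sigma=0)
        m1 = lq.make_nuclei_mask(img, smoothing_sigma=1)
        # smoothing moves the boundary by less than a pixel ring
        assert (m0 ^ m1).sum() <= np.count_nonzero(m0) * 0.15
        assert m0[48, 48] and m1[48, 48]

    def test_constant_raster_raises(self):
        with pytest.raises(lq.DegenerateImageError, match="Otsu undefined"):
            lq.make_nuclei_mask(np.full((32, 32), 7.0))


class TestWatershedSplit:
    def test_single_disc_single_label(self):
        mask = disc_mask((96, 96), (48, 48), 20)
        lnm = lq.split_touching_nuclei(mask)
        assert lnm.n_labels == 1
        assert lnm.records.loc[0, "area"] == mask.sum()

    def test_two_overlapping_discs_are_split(self):
        mask = disc_mask((96, 128), (48, 48), 20) | disc_mask((96, 128), (48, 78), 20)
        lnm = lq.split_touching_nuclei(mask)
        assert lnm.n_labels == 2
        single = np.count_nonzero(disc_mask((96, 128), (48, 48), 20))
        for area in lnm.records["area"]:
            assert abs(area - single) / single < 0.15

    def test_disjoint_discs_match_connected_components(self):
        mask = disc_mask((128, 128), (30, 30), 15) | disc_mask((128, 128), (90, 95), 18)
        lnm = lq.split_touching_nuclei(mask)
        cc, n = ndi.label(mask)
        assert lnm.n_labels == n == 2
        # identical partition up to label permutation
        for k in range(1, n + 1):
            values = np.unique(lnm.labels[cc == k])
            assert len(values) == 1 and values[0] > 0

    def test_empty_mask_is_empty_labeling(self):
        lnm = lq.split_touching_nuclei(np.zeros((16, 16), dtype=bool))
        assert lnm.n_labels == 0
        assert lnm.labels.max() == 0

    def test_label_partition_conserves_foreground(self, clean_spec):
        raster, _ = lq.generate_nuclei_channel(clean_spec)
        mask = lq.make_nuclei_mask(raster)
        lnm = lq.split_touching_nuclei(mask)
        assert lnm.records["area"].sum() == mask.sum()


class TestAreaFilter:
    def _toy_labels(self, areas):
        labels = np.zeros((40, len(areas) * 30), dtype=np.int32)
        for i, a in enumerate(areas):
            side = int(np.sqrt(a))
            labels[:side, i * 30: i * 30 + (a // side)] = i + 1
        return lq.LabeledNucleiMask(labels, None)

    def test_min_area_zero_is_identity(self, clean_spec):
        raster, _ = lq.generate_nuclei_channel(clean_spec)
        lnm = lq.split_touching_nuclei(lq.make_nuclei_mask(raster))
        out = lq.filter_small_regions(lnm, 0)
        assert np.array_equal(out.labels, lnm.labels)

    def test_threshold_removes_small_labels(self):
        labels = np.zeros((30, 90), dtype=np.int32)
        labels[0:20, 0:20] = 1    # 400
        labels[0:14, 30:55] = 2   # 350
        labels[0:3, 60:64] = 3    # 12
        lnm = lq.LabeledNucleiMask(labels, None)
        lnm.records = lq.segmentation._build_records(labels)
        out = lq.filter_small_regions(lnm, 50)
        assert out.n_labels == 2
        assert sorted(out.records["area"]) == [350, 400]
        assert set(np.unique(out.labels)) == {0, 1, 2}  # recompacted

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(min_area=st.integers(0, 500), seed=st.integers(0, 10_000))
    def test_area_conservation(self, min_area, seed):
        """Surviving + removed areas always equal the original foreground."""
        rng = np.random.default_rng(seed)
        labels, _ = ndi.label(rng.random((48, 48)) > 0.6)
        lnm = lq.LabeledNucleiMask(labels.astype(np.int32), None)
        lnm.records = lq.segmentation._build_records(lnm.labels)
        out = lq.filter_small_regions(lnm, min_area)
        removed = lnm.records.loc[lnm.records["area"] < min_area, "area"].sum()
        assert out.records["area"].sum() + removed == np.count_nonzero(labels)


def _mask_from_areas(interior_areas, border_areas, shape=(64, 400)):
    """Build a LabeledNucleiMask with rectangular labels of given areas."""
    labels = np.zeros(shape, dtype=np.int32)
    col, k = 2, 0
    for a in interior_areas:  # interior: start at row 2
        k += 1
        labels[2: 2 + 10, col: col + a // 10] = k
        col += a // 10 + 4
    for a in border_areas:  # border: touch row 0
        k += 1
        labels[0:10, col: col + a // 10] = k
        col += a // 10 + 4
    lnm = lq.LabeledNucleiMask(labels, lq.segmentation._build_records(labels))
    return lnm


class TestFractionalCounting:
    def test_worked_case_three_plus_half(self):
        lnm = _mask_from_areas([100, 100, 100], [50])
        (cc,) = lq.count_cells([lnm])
        assert cc.n_interior == 3
        assert cc.n_border_effective == pytest.approx(0.5)
        assert cc.total_effective == pytest.approx(3.5)

    def test_border_fraction_capped_at_one(self):
        lnm = _mask_from_areas([100, 100, 100], [130])
        (cc,) = lq.count_cells([lnm])
        assert cc.n_border_effective == pytest.approx(1.0)

    def test_mean_area_is_dataset_wide(self):
        m1 = _mask_from_areas([100], [])
        m2 = _mask_from_areas([200], [60])
        c1, c2 = lq.count_cells([m1, m2])
        assert c1.mean_interior_area == c2.mean_interior_area == pytest.approx(150.0)
        assert c2.n_border_effective == pytest.approx(60 / 150)

    def test_only_border_nuclei_raises(self):
        lnm = _mask_from_areas([], [80, 90])
        with pytest.raises(ValueError, match="average nuclei size"):
            lq.count_cells([lnm])

    def test_adding_one_interior_nucleus_adds_exactly_one(self):
        base = [100, 110, 95]
        c_before = lq.count_cells([_mask_from_areas(base, [50])])[0]
        c_after = lq.count_cells([_mask_from_areas(base + [100], [50])])[0]
        # same mean (new nucleus at rounded mean area keeps it near-identical)
        assert c_after.n_interior == c_before.n_interior + 1
        assert c_after.total_effective == pytest.approx(c_before.total_effective + 1, abs=0.02)

    def test_effective_count_matches_generator_truth(self, clean_spec):
        img, truth = lq.generate_image(clean_spec)
        lnm = lq.segment_nuclei(img.blue)
        (cc,) = lq.count_cells([lnm])
        assert cc.total_effective == pytest.approx(truth.effective_cell_count_true, abs=0.5)


class TestBrightCells:
    def _labels_with_means(self, means):
        labels = np.zeros((20, len(means) * 12), dtype=np.int32)
        raster = np.zeros_like(labels, dtype=float)
        for i, m in enumerate(means):
            labels[2:12, i * 12: i * 12 + 10] = i + 1
            raster[2:12, i * 12: i * 12 + 10] = m
        lnm = lq.LabeledNucleiMask(labels, lq.segmentation._build_records(labels))
        return lnm, raster

    def test_equal_intensities_flag_nothing(self):
        lnm, raster = self._labels_with_means([100.0] * 6)
        out = lq.flag_bright_cells(lnm, raster)
        assert not out.records["excluded_bright"].any()
        assert not out.exclusion_mask.any()

    def test_hand_computed_tukey_fence(self):
        means = [100.0] * 9 + [10_000.0]
        lnm, raster = self._labels_with_means(means)
        out = lq.flag_bright_cells(lnm, raster, fence_k=1.5)
        # by hand: Q3 = 100, IQR = 0, fence = 100 -> only the 10k label exceeds
        flagged = out.records.loc[out.records["excluded_bright"], "mean_intensity"]
        assert list(flagged) == [10_000.0]

    def test_fewer_than_four_labels_flags_nothing(self):
        lnm, raster = self._labels_with_means([100.0, 100.0, 9_000.0])
        out = lq.flag_bright_cells(lnm, raster)
        assert not out.records["excluded_bright"].any()

    def test_generator_bright_cells_are_flagged(self):
        spec = lq.SyntheticSpec(seed=17, n_bright_cells=2,
                                noise_model=lq.NoiseModel(kind="none"))
        img, truth = lq.generate_image(spec)
        lnm = lq.segment_nuclei(img.blue)
        out = lq.flag_bright_cells(lnm, img.green)
        assert int(out.records["excluded_bright"].sum()) == 2
        # flagged labels sit on the truly bright nuclei
        for n in truth.nuclei:
            if n.is_bright:
                label = out.labels[int(n.center[0]), int(n.center[1])]
                assert label > 0
                row = out.records.loc[out.records["label"] == label].iloc[0]
                assert bool(row["excluded_bright"])

    def test_halo_extends_beyond_nucleus(self):
        means = [100.0] * 9 + [10_000.0]
        lnm, raster = self._labels_with_means(means)
        out = lq.flag_bright_cells(lnm, raster, halo_radius=5)
        nucleus = lnm.labels == 10
        assert out.exclusion_mask.sum() > nucleus.sum()
        assert out.exclusion_mask[nucleus].all()
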