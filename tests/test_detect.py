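import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mncount.detect import (
    analyze_image,
    binarize,
    boundary_chain_length,
    classify_blobs_by_erosion,
    classify_cells,
    clean_mask,
    cytoplasm_mask,
    dilate,
    erode,
    filter_micronuclei,
    measure_regions,
    RegionRecord,
    RegionTable,
    separate_cells,
    sigmoid_enhance,
)
from mncount.io import RGBMicrograph
from mncount.synth import SynthSpec, generate_micrograph

from _oracles import (
    ccw_chain_length,
    flood_fill_components,
    sliding_dilate,
    sliding_erode,
)


def disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


small_mask = arrays(bool, st.tuples(st.integers(4, 16), st.integers(4, 16)))


class TestBinarize:
    def test_blank_image_gives_empty_mask(self):
        assert not binarize(np.zeros((8, 8), np.uint8), 65).any()

    def test_pixel_equal_to_threshold_is_foreground(self):
        img = np.full((2, 2), 65, np.uint8)
        assert binarize(img, 65).all()

    @given(img=arrays(np.uint8, (16, 16)), th=st.integers(0, 255))
    def test_matches_per_pixel_comparison(self, img, th):
        expected = np.array(
            [[img[i, j] >= th for j in range(16)] for i in range(16)]
        )
        assert np.array_equal(binarize(img, th), expected)


class TestMorphology:
    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not clean_mask(mask, 3).any()

    def test_closing_fills_single_pixel_hole(self):
        mask = np.zeros((11, 11), bool)
        mask[1:10, 1:10] = True
        mask[5, 5] = False
        assert clean_mask(mask, 3)[5, 5]

    @given(mask=small_mask, k=st.sampled_from([3, 5]))
    def test_erode_dilate_match_sliding_window_oracles(self, mask, k):
        assert np.array_equal(erode(mask, k), sliding_erode(mask, k))
        assert np.array_equal(dilate(mask, k), sliding_dilate(mask, k))

    @given(mask=small_mask, k=st.sampled_from([3, 5]))
    def test_clean_is_open_then_close(self, mask, k):
        opened = sliding_dilate(sliding_erode(mask, k), k)
        closed = sliding_erode(sliding_dilate(opened, k), k)
        assert np.array_equal(clean_mask(mask, k), closed)


class TestBlobClassification:
    def test_large_disk_is_nucleus_restored_to_full_extent(self):
        mask = disk((64, 64), (32, 32), 20)
        nuclei, mn = classify_blobs_by_erosion(mask, 13)
        assert np.array_equal(nuclei, mask)
        assert not mn.any()
        # the brute-force eroded remnant really is nonempty
        assert sliding_erode(mask, 13).any()

    def test_small_disk_is_micronucleus_candidate(self):
        mask = disk((32, 32), (16, 16), 3)
        nuclei, mn = classify_blobs_by_erosion(mask, 13)
        assert not nuclei.any()
        assert np.array_equal(mn, mask)
        assert not sliding_erode(mask, 13).any()

    def test_empty_mask_gives_empty_outputs(self):
        mask = np.zeros((16, 16), bool)
        nuclei, mn = classify_blobs_by_erosion(mask, 13)
        assert not nuclei.any() and not mn.any()

    @given(mask=small_mask, k=st.sampled_from([5, 9]))
    def test_outputs_partition_the_input(self, mask, k):
        nuclei, mn = classify_blobs_by_erosion(mask, k)
        assert not (nuclei & mn).any()
        assert np.array_equal(nuclei | mn, mask)


class TestSigmoidEnhance:
    def test_center_maps_to_midgray(self):
        img = np.full((1, 1), 118, np.uint8)
        assert sigmoid_enhance(img, 118, 0.05)[0, 0] in (127, 128)

    def test_saturates_far_above_center(self):
        img = np.full((1, 1), 255, np.uint8)
        assert sigmoid_enhance(img, 118, 0.05)[0, 0] == 255

    def test_full_sweep_matches_scalar_formula(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = sigmoid_enhance(img, 118, 0.05)
        for v in range(256):
            expected = round(255.0 / (1.0 + np.exp(-0.05 * (v - 118))))
            assert out.ravel()[v] == expected

    def test_monotone_in_intensity(self):
        img = np.arange(256, dtype=np.uint8).reshape(1, 256)
        out = sigmoid_enhance(img, 80, 0.2).astype(int)
        assert (np.diff(out) >= 0).all()


class TestCytoplasmMask:
    def test_ring_interior_is_filled(self, base_params):
        red = np.zeros((64, 64), np.uint8)
        ring = disk((64, 64), (32, 32), 20) & ~disk((64, 64), (32, 32), 12)
        red[ring] = 200
        mask = cytoplasm_mask(red, np.zeros_like(red), base_params)
        assert mask[32, 32]

    def test_two_blobs_give_two_components(self, base_params):
        red = np.zeros((64, 96), np.uint8)
        red[disk((64, 96), (32, 24), 10)] = 200
        red[disk((64, 96), (32, 72), 10)] = 200
        mask = cytoplasm_mask(red, np.zeros_like(red), base_params)
        assert len(flood_fill_components(mask)) == 2

    def test_blank_channels_give_empty_mask(self, base_params):
        blank = np.zeros((32, 32), np.uint8)
        assert not cytoplasm_mask(blank, blank, base_params).any()


class TestSeparateCells:
    def test_one_nucleus_labels_whole_blob(self):
        cyto = disk((64, 64), (32, 32), 25)
        nuclei = disk((64, 64), (32, 32), 8)
        labels = separate_cells(cyto, nuclei)
        assert set(np.unique(labels)) == {0, 1}
        assert np.array_equal(labels > 0, cyto)

    def test_dumbbell_splits_near_perpendicular_bisector(self):
        shape = (96, 160)
        cyto = disk(shape, (48, 60), 30) | disk(shape, (48, 100), 30)
        nuclei = disk(shape, (48, 60), 8) | disk(shape, (48, 100), 8)
        labels = separate_cells(cyto, nuclei)
        assert labels.max() == 2
        line = cyto & (labels == 0)
        cols = np.nonzero(line)[1]
        assert cols.size > 0
        assert np.abs(cols - 80).max() <= 2

    def test_marker_free_blob_stays_unlabeled(self):
        shape = (64, 128)
        cyto = disk(shape, (32, 32), 20) | disk(shape, (32, 96), 20)
        nuclei = disk(shape, (32, 32), 8)
        labels = separate_cells(cyto, nuclei)
        assert labels.max() == 1
        assert not (labels[:, 70:] > 0).any()


class TestMeasureRegions:
    def test_single_pixel_convention(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        (rec,) = measure_regions(mask)
        assert rec.area == 1
        assert rec.perimeter == 0.0
        assert rec.circularity == 1.0

    def test_square_chain_perimeter(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        (rec,) = measure_regions(mask)
        assert rec.area == 100
        assert rec.perimeter == pytest.approx(36.0)
        assert rec.circularity == pytest.approx(0.97, abs=0.005)

    def test_rectangle_chain_perimeter(self):
        mask = np.zeros((7, 19), bool)
        mask[2:5, 2:17] = True
        (rec,) = measure_regions(mask)
        assert rec.area == 45
        assert rec.perimeter == pytest.approx(32.0)
        assert rec.circularity == pytest.approx(0.55, abs=0.005)

    @given(mask=small_mask)
    def test_chain_length_matches_reverse_walk_oracle(self, mask):
        for comp in flood_fill_components(mask):
            region = np.zeros_like(mask)
            for r, c in comp:
                region[r, c] = True
            assert boundary_chain_length(region) == pytest.approx(
                ccw_chain_length(region)
            )

    @given(mask=small_mask)
    def test_areas_partition_foreground(self, mask):
        table = measure_regions(mask)
        assert sum(r.area for r in table) == int(mask.sum())
        assert all(0.0 <= r.circularity <= 1.0 for r in table)


def _table(*records):
    return RegionTable(list(records))


def _rec(label, area, circ):
    return RegionRecord(label, area, 10.0, (0.0, 0.0), circ, (0, 0, 1, 1))


class TestFilterMicronuclei:
    def test_noise_floor_removes_small_regions(self, base_params):
        table = _table(_rec(1, 8, 1.0), _rec(2, 30, 1.0))
        kept = filter_micronuclei(table, base_params.replace(noise_reduction=11))
        assert kept.labels == [2]

    def test_circularity_threshold(self, base_params):
        rect = _rec(1, 45, 0.55)
        assert filter_micronuclei(
            _table(rect), base_params.replace(micronucleus_th=0.6)
        ).labels == []
        assert filter_micronuclei(
            _table(rect), base_params.replace(micronucleus_th=0.5)
        ).labels == [1]

    @given(
        areas=st.lists(st.integers(1, 60), min_size=1, max_size=20),
        circs=st.lists(st.floats(0, 1, allow_nan=False), min_size=20,
                       max_size=20),
    )
    def test_stricter_threshold_accepts_subset(self, base_params, areas, circs):
        table = _table(
            *(_rec(i, a, c) for i, (a, c) in enumerate(zip(areas, circs)))
        )
        loose = set(
            filter_micronuclei(
                table, base_params.replace(micronucleus_th=0.5)
            ).labels
        )
        strict = set(
            filter_micronuclei(
                table, base_params.replace(micronucleus_th=0.7)
            ).labels
        )
        assert strict <= loose


class TestClassifyCells:
    def _scene(self):
        labels = np.zeros((20, 40), np.int32)
        labels[:, :19] = 1
        labels[:, 21:] = 2
        nuclei = _table(
            RegionRecord(1, 50, 20.0, (10.0, 9.0), 0.9, (0, 0, 20, 19)),
            RegionRecord(2, 50, 20.0, (10.0, 30.0), 0.9, (0, 21, 20, 40)),
        )
        return labels, nuclei

    def test_cell_without_mn_is_normal(self):
        labels, nuclei = self._scene()
        records = classify_cells(labels, nuclei, _table())
        assert len(records) == 2
        assert not any(r.is_mn_cell for r in records)

    def test_two_mn_in_one_cytoplasm_count_once(self):
        labels, nuclei = self._scene()
        mn = _table(
            RegionRecord(1, 20, 10.0, (5.0, 5.0), 1.0, (0, 0, 1, 1)),
            RegionRecord(2, 20, 10.0, (15.0, 5.0), 1.0, (0, 0, 1, 1)),
        )
        records = classify_cells(labels, nuclei, mn)
        assert sum(r.is_mn_cell for r in records) == 1
        (mn_cell,) = [r for r in records if r.is_mn_cell]
        assert mn_cell.mn_labels == frozenset({1, 2})

    def test_mn_on_background_or_watershed_line_is_discarded(self):
        labels, nuclei = self._scene()
        mn = _table(RegionRecord(1, 20, 10.0, (10.0, 20.0), 1.0, (0, 0, 1, 1)))
        records = classify_cells(labels, nuclei, mn)
        assert not any(r.is_mn_cell for r in records)


class TestAnalyzeImage:
    def test_blank_image_counts_nothing(self):
        m = RGBMicrograph(np.zeros((64, 64, 3), np.uint8))
        with pytest.warns(UserWarning):
            res = analyze_image(m)
        assert (res.total_cells, res.mn_cells) == (0, 0)

    def test_rerun_is_bit_identical(self, small_scene):
        micrograph, _ = small_scene
        a = analyze_image(micrograph)
        b = analyze_image(micrograph)
        assert a.params == b.params
        assert (a.total_cells, a.mn_cells) == (b.total_cells, b.mn_cells)
        assert np.array_equal(a.cell_labels, b.cell_labels)
        assert np.array_equal(a.green_binary, b.green_binary)

    def test_counts_invariant_under_rotation_and_flip(self, small_scene,
                                                      base_params):
        micrograph, _ = small_scene
        p = base_params.replace(kernel_l=17, noise_reduction=21)
        ref = analyze_image(micrograph, p)
        for transform in (
            lambda px: np.rot90(px, 1),
            lambda px: np.rot90(px, 2),
            lambda px: np.rot90(px, 3),
            lambda px: px[:, ::-1],
        ):
            m2 = RGBMicrograph(np.ascontiguousarray(transform(micrograph.pixels)))
            res = analyze_image(m2, p)
            assert (res.total_cells, res.mn_cells) == (
                ref.total_cells, ref.mn_cells,
            )

    def test_mn_threshold_and_noise_are_monotone_knobs(self):
        spec = SynthSpec(height=512, width=512, n_cells=4, n_mn_cells=1,
                         n_debris=3, seed=5)
        micrograph, _ = generate_micrograph(spec)
        base = analyze_image(micrograph)
        previous = None
        for th in (0.3, 0.5, 0.7, 0.9):
            res = analyze_image(micrograph,
                                base.params.replace(micronucleus_th=th))
            assert res.total_cells == base.total_cells
            if previous is not None:
                assert res.mn_cells <= previous
            previous = res.mn_cells
        noisy = analyze_image(micrograph,
                              base.params.replace(noise_reduction=60))
        assert noisy.mn_cells <= base.mn_cells
        assert noisy.total_cells == base.total_cells

    def test_exclude_border_drops_edge_cells(self, base_params):
        px = np.zeros((64, 64, 3), np.uint8)
        px[disk((64, 64), (8, 8), 12)] = (140, 40, 0)  # cytoplasm off the edge
        px[disk((64, 64), (8, 8), 7)] = (30, 200, 0)
        px[disk((64, 64), (40, 40), 12)] = (140, 40, 0)
        px[disk((64, 64), (40, 40), 7)] = (30, 200, 0)
        m = RGBMicrograph(px)
        p = base_params.replace(kernel_l=9)
        assert analyze_image(m, p).total_cells == 2
        assert analyze_image(m, p, exclude_border=True).total_cells == 1
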