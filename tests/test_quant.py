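"""Clone segmentation, area measurement and coverage quantification."""

import numpy as np
import pandas as pd
import pytest

from cloneburden.images import CalibratedImage, write_tiff
from cloneburden.presets import get_preset
from cloneburden.quant import (
    CloneLabelMap,
    EmptyBatchError,
    NoGutError,
    anterior_roi,
    batch_quantify,
    compute_coverage,
    measure_clones,
    measure_gut,
    quantify_image,
    reduce_zplanes,
    segment_gfp,
)
from cloneburden.synth import generate_midgut


def _image(green=None, red=None, blue=None, pixel_size=1.0, shape=(64, 64)):
    channels, names = [], []
    for plane, name in ((green, "green"), (red, "red"), (blue, "blue")):
        if plane is not None:
            channels.append(np.asarray(plane, dtype=np.uint16))
            names.append(name)
    return CalibratedImage(
        data=np.stack(channels)[None],
        pixel_size_um=pixel_size,
        channel_names=tuple(names),
        image_id="unit",
    )


class TestSegmentGfp:
    def test_blank_channel_fixed_threshold_gives_empty_map(self):
        image = _image(green=np.zeros((64, 64)))
        labels = segment_gfp(image, "fixed", 100.0)
        assert labels.n_clones == 0

    def test_blank_channel_auto_mode_warns_not_raises(self):
        image = _image(green=np.zeros((64, 64)))
        with pytest.warns(UserWarning):
            labels = segment_gfp(image, "auto")
        assert labels.n_clones == 0

    def test_two_squares_give_two_hundred_pixel_labels(self):
        green = np.zeros((64, 64))
        green[5:15, 5:15] = 200
        green[30:40, 30:40] = 200
        labels = segment_gfp(_image(green=green), "fixed", 100.0, min_size_um2=0)
        assert labels.n_clones == 2
        counts = np.bincount(labels.labels.ravel())[1:]
        assert list(counts) == [100, 100]

    def test_threshold_is_strictly_greater_than(self):
        green = np.full((16, 16), 100)
        labels = segment_gfp(_image(green=green), "fixed", 100.0, min_size_um2=0)
        assert labels.n_clones == 0

    def test_min_size_filter_and_contiguous_relabelling(self):
        green = np.zeros((64, 64))
        green[2, 2] = 200  # single pixel: dropped at 10 um^2 filter
        green[20:30, 20:30] = 200
        labels = segment_gfp(_image(green=green), "fixed", 100.0, min_size_um2=10.0)
        assert labels.n_clones == 1
        assert set(np.unique(labels.labels)) == {0, 1}

    def test_threshold_monotonicity(self, small_control_gut):
        """Raising the fixed threshold never increases total labelled area."""
        image, _ = small_control_gut
        areas = [
            segment_gfp(image, "fixed", t, min_size_um2=0).total_area_um2()
            for t in (1000.0, 3000.0, 6000.0, 9000.0, 13000.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_auto_threshold_recovers_ground_truth_clones(self, apcras_gut):
        """Each true clone overlaps exactly one label with Jaccard >= 0.9."""
        image, truth = apcras_gut
        gut = measure_gut(image)
        labels = segment_gfp(image, "auto", gut_mask=gut.mask)
        for clone in truth.clones:
            true_mask = truth.clone_labels == clone.clone_id
            overlapping = np.unique(labels.labels[true_mask])
            overlapping = overlapping[overlapping > 0]
            assert overlapping.size == 1
            seg_mask = labels.labels == overlapping[0]
            jaccard = np.sum(true_mask & seg_mask) / np.sum(true_mask | seg_mask)
            assert jaccard >= 0.9


class TestMeasureClones:
    def test_area_scaling_with_pixel_size(self):
        labels = CloneLabelMap(
            labels=np.pad(np.ones((10, 10), dtype=np.int32), 5),
            threshold=0.0,
            pixel_size_um=0.5,
        )
        (m,) = measure_clones(labels)
        assert m.area_um2 == pytest.approx(25.0)

    def test_empty_label_map(self):
        labels = CloneLabelMap(np.zeros((8, 8), dtype=np.int32), 0.0, 1.0)
        assert measure_clones(labels) == []

    def test_areas_equal_brute_force_pixel_counts(self, small_control_gut):
        image, _ = small_control_gut
        gut = measure_gut(image)
        labels = segment_gfp(image, "auto", gut_mask=gut.mask)
        measured = {m.clone_id: m.area_um2 for m in measure_clones(labels)}
        counts = np.bincount(labels.labels.ravel())
        for cid, area in measured.items():
            assert area == counts[cid] * image.pixel_area_um2()

    def test_measured_area_matches_ground_truth_within_two_percent(self, apcras_gut):
        image, truth = apcras_gut
        gut = measure_gut(image)
        labels = segment_gfp(image, "auto", gut_mask=gut.mask)
        for clone in truth.clones:
            true_mask = truth.clone_labels == clone.clone_id
            seg_ids = np.unique(labels.labels[true_mask])
            seg_ids = seg_ids[seg_ids > 0]
            seg_area = np.sum(labels.labels == seg_ids[0]) * image.pixel_area_um2()
            assert seg_area == pytest.approx(clone.area_um2, rel=0.02)

    def test_nonpositive_pixel_size_rejected(self):
        labels = CloneLabelMap(np.zeros((4, 4), dtype=np.int32), 0.0, 1.0)
        with pytest.raises(ValueError):
            measure_clones(labels, pixel_size_um=0.0)


class TestMeasureGut:
    def test_solid_rectangle_area(self):
        red = np.zeros((300, 1100))
        red[50:250, 50:1050] = 5000  # 200 x 1000 px
        gut = measure_gut(_image(green=np.zeros((300, 1100)), red=red, shape=(300, 1100)))
        assert gut.gut_area_um2 == pytest.approx(200_000.0)

    def test_blank_red_channel_raises_no_gut(self):
        image = _image(green=np.zeros((32, 32)), red=np.zeros((32, 32)))
        with pytest.raises(NoGutError):
            measure_gut(image)

    def test_missing_red_channel_raises(self):
        image = _image(green=np.zeros((32, 32)))
        with pytest.raises(NoGutError):
            measure_gut(image)

    def test_largest_object_selected_and_holes_filled(self):
        red = np.zeros((64, 64))
        red[10:40, 10:40] = 5000
        red[20:25, 20:25] = 0  # hole: filled
        red[50:55, 50:55] = 5000  # smaller distractor object
        gut = measure_gut(_image(green=np.zeros((64, 64)), red=red))
        assert gut.gut_area_um2 == pytest.approx(900.0)

    def test_synthetic_gut_area_within_two_percent(self, small_control_gut):
        image, truth = small_control_gut
        gut = measure_gut(image)
        assert gut.gut_area_um2 == pytest.approx(truth.gut_area_um2, rel=0.02)


class TestComputeCoverage:
    def test_fifty_percent_coverage(self):
        gut_mask = np.zeros((100, 100), dtype=bool)
        gut_mask[:, :] = True
        labels = np.zeros((100, 100), dtype=np.int32)
        labels[:50, :] = 1
        from cloneburden.quant import GutMeasurement

        gut = GutMeasurement(10_000.0, gut_mask, 0.0, 1.0)
        cov = compute_coverage(CloneLabelMap(labels, 0.0, 1.0), gut)
        assert cov.percent_whole == pytest.approx(50.0)
        assert cov.gfp_area_um2 == pytest.approx(5000.0)

    def test_no_clones_is_zero_percent(self):
        from cloneburden.quant import GutMeasurement

        gut = GutMeasurement(64.0, np.ones((8, 8), dtype=bool), 0.0, 1.0)
        cov = compute_coverage(CloneLabelMap(np.zeros((8, 8), dtype=np.int32), 0.0, 1.0), gut)
        assert cov.percent_whole == 0.0

    def test_clone_outside_gut_counts_only_intersection(self):
        """Coverage equals the brute-force count of GFP-inside-gut pixels."""
        from cloneburden.quant import GutMeasurement

        gut_mask = np.zeros((20, 20), dtype=bool)
        gut_mask[:, :10] = True
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:10, 5:15] = 1  # half inside, half outside the gut
        gut = GutMeasurement(float(gut_mask.sum()), gut_mask, 0.0, 1.0)
        cov = compute_coverage(CloneLabelMap(labels, 0.0, 1.0), gut)
        brute = np.sum((labels > 0) & gut_mask) / gut_mask.sum() * 100.0
        assert cov.percent_whole == pytest.approx(brute)
        assert cov.gfp_area_um2 == pytest.approx(np.sum((labels > 0) & gut_mask))

    def test_disjoint_roi_rejected(self):
        from cloneburden.quant import GutMeasurement, RegionOfInterest

        gut_mask = np.zeros((20, 20), dtype=bool)
        gut_mask[:, :10] = True
        roi = np.zeros((20, 20), dtype=bool)
        roi[:, 15:] = True
        gut = GutMeasurement(float(gut_mask.sum()), gut_mask, 0.0, 1.0)
        with pytest.raises(ValueError):
            compute_coverage(
                CloneLabelMap(np.zeros((20, 20), dtype=np.int32), 0.0, 1.0),
                gut,
                RegionOfInterest(roi),
            )

    def test_coverage_bounds_on_synthetic_batches(self, control_batch, apcras_batch):
        for batch in (control_batch, apcras_batch):
            ok = batch["per_image"]
            assert ok["percent_whole"].between(0, 100).all()
            assert ok["percent_anterior"].between(0, 100).all()


class TestAnteriorRoi:
    def test_anterior_fraction_of_axial_extent(self):
        from cloneburden.quant import GutMeasurement

        gut_mask = np.zeros((10, 100), dtype=bool)
        gut_mask[:, 20:80] = True
        gut = GutMeasurement(600.0, gut_mask, 0.0, 1.0)
        roi = anterior_roi(gut, fraction=0.5)
        inter = roi.mask & gut_mask
        assert inter.sum() == pytest.approx(300, abs=10)
        assert not np.any(inter[:, 51:])

    def test_invalid_fraction(self):
        from cloneburden.quant import GutMeasurement

        gut = GutMeasurement(1.0, np.ones((4, 4), dtype=bool), 0.0, 1.0)
        with pytest.raises(ValueError):
            anterior_roi(gut, fraction=1.5)


class TestReduceZplanes:
    def test_single_plane_max_projection_is_identity(self):
        image = _image(green=np.arange(16).reshape(4, 4), shape=(4, 4))
        reduced = reduce_zplanes(image, "max_projection")
        np.testing.assert_array_equal(reduced.data, image.data)

    def test_projection_of_blank_plane_equals_other_plane(self):
        data = np.zeros((2, 1, 4, 4), dtype=np.uint16)
        data[0, 0] = 7
        image = CalibratedImage(data, 1.0, ("green",))
        reduced = reduce_zplanes(image, "max_projection")
        np.testing.assert_array_equal(reduced.data[0, 0], data[0, 0])

    def test_per_plane_returns_one_image_per_z(self):
        data = np.zeros((3, 1, 4, 4), dtype=np.uint16)
        image = CalibratedImage(data, 1.0, ("green",))
        planes = reduce_zplanes(image, "per_plane")
        assert len(planes) == 3
        assert planes[1].image_id.endswith("_z1")

    def test_unknown_mode_rejected(self):
        image = _image(green=np.zeros((4, 4)), shape=(4, 4))
        with pytest.raises(ValueError):
            reduce_zplanes(image, "median")

    def test_three_vs_nine_plane_coverage_comparable(self, small_geometry):
        """Few-plane and deep-stack renders give closely matching coverage."""
        from cloneburden.presets import RenderConfig

        results = []
        for n_z in (3, 9):
            image, _ = generate_midgut(
                get_preset("snail"),
                small_geometry,
                RenderConfig(n_zplanes=n_z),
                seed=21,
            )
            row, *_ = quantify_image(image)
            results.append(row["percent_whole"])
        assert abs(results[0] - results[1]) / results[1] < 0.15


@pytest.fixture(scope="module")
def batch_folder(tmp_path_factory, small_geometry):
    from cloneburden.synth import generate_batch

    folder = tmp_path_factory.mktemp("batch")
    generate_batch(get_preset("control"), 3, folder, seed=17, geometry=small_geometry)
    return folder


class TestBatchQuantify:
    def test_one_row_per_image(self, batch_folder):
        table = batch_quantify(batch_folder)
        assert len(table) == 3
        assert (table["status"] == "ok").all()

    def test_batch_equals_single_image_pipeline(self, batch_folder):
        """Batch row i is exactly the single-image pipeline on image i."""
        from cloneburden.images import read_tiff

        table = batch_quantify(batch_folder).set_index("image_id")
        for path in sorted(batch_folder.glob("control_gut???.tif")):
            image = read_tiff(path)
            row, *_ = quantify_image(image)
            batch_row = table.loc[image.image_id]
            for key in ("n_clones", "gfp_area_um2", "gut_area_um2", "percent_whole"):
                assert batch_row[key] == row[key]

    def test_corrupt_file_reported_not_fatal(self, batch_folder, tmp_path):
        import shutil

        folder = tmp_path / "mixed"
        shutil.copytree(batch_folder, folder)
        (folder / "corrupt.tif").write_bytes(b"this is not a tiff")
        table = batch_quantify(folder)
        assert (table["status"] == "ok").sum() == 3
        failed = table[table["status"] == "failed"]
        assert list(failed["image_id"]) == ["corrupt"]
        assert failed["error"].str.len().gt(0).all()

    def test_empty_folder_raises(self, tmp_path):
        (tmp_path / "notes.txt").write_text("no images here")
        with pytest.raises(EmptyBatchError):
            batch_quantify(tmp_path)
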