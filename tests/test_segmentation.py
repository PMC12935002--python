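"""Segmentation contracts: thresholding + watershed, curation rules,
puncta containment, parent assignment and the 62-px size filter."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.measure import label as cc_label

from redoxscope.segmentation import (
    CurationRules,
    DegenerateThresholdError,
    LabelMap,
    SegmentationParams,
    curate_cells,
    segment_cells,
    segment_puncta,
)

PARAMS_RAW = SegmentationParams(
    threshold_method="fixed", fixed_threshold=0.5, min_cell_area=0, border_policy="keep"
)


def _blob_image(centers, radius, shape=(128, 128)):
    img = np.zeros(shape)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        img[rr, cc] = 1.0
    return img


def test_two_disjoint_blobs_two_labels_with_exact_areas():
    img = _blob_image([(30, 30), (90, 90)], 10)
    lm = segment_cells(img, PARAMS_RAW)
    assert lm.n_objects == 2
    areas = sorted(np.bincount(lm.labels.ravel())[1:])
    rr, cc = disk((30, 30), 10, shape=img.shape)
    assert areas == [len(rr), len(rr)]


def test_touching_circles_with_two_distance_maxima_are_split():
    """Two overlapping circles whose distance-transform maxima exceed the
    seed-suppression distance come out as two labels."""
    img = _blob_image([(60, 45), (60, 75)], 16)
    assert cc_label(img > 0.5).max() == 1  # genuinely fused
    lm = segment_cells(img, PARAMS_RAW)
    assert lm.n_objects == 2


def test_blob_below_min_area_removed():
    img = _blob_image([(60, 60)], 4)  # area ~ 49 px
    params = PARAMS_RAW.model_copy(update={"min_cell_area": 100})
    assert segment_cells(img, params).n_objects == 0


def test_all_background_image_yields_empty_map():
    lm = segment_cells(np.zeros((32, 32)), PARAMS_RAW)
    assert lm.n_objects == 0


def test_constant_image_with_otsu_raises():
    with pytest.raises(DegenerateThresholdError):
        segment_cells(np.ones((32, 32)), SegmentationParams(threshold_method="otsu"))


def test_border_objects_dropped_by_default():
    img = np.zeros((64, 64))
    img[0:10, 20:30] = 1.0  # touches border
    img[30:40, 20:30] = 1.0
    lm = segment_cells(
        img, SegmentationParams(threshold_method="fixed", fixed_threshold=0.5,
                                min_cell_area=0)
    )
    assert lm.n_objects == 1


def test_watershed_equals_components_when_objects_are_disjoint():
    """On non-touching objects the watershed adds nothing: its regions are
    exactly the connected components."""
    rng = np.random.default_rng(7)
    img = np.zeros((200, 200))
    centers = [(30, 30), (30, 160), (100, 100), (160, 40), (170, 165)]
    for c in centers:
        rr, cc = disk(c, int(rng.integers(6, 12)), shape=img.shape)
        img[rr, cc] = 1.0
    lm = segment_cells(img, PARAMS_RAW)
    ref = cc_label(img > 0.5, connectivity=2)
    assert lm.n_objects == ref.max()
    # identical partition up to label permutation
    for lab in range(1, ref.max() + 1):
        vals = np.unique(lm.labels[ref == lab])
        assert vals.size == 1 and vals[0] > 0
    assert np.array_equal(lm.labels > 0, ref > 0)


# --- curation --------------------------------------------------------------


def _cells_fixture():
    labels = np.zeros((80, 120), dtype=np.int32)
    labels[10:30, 10:30] = 1
    labels[10:30, 50:70] = 2
    labels[50:70, 10:30] = 3
    chl = np.zeros((80, 120))
    chl[labels > 0] = 500.0
    return labels, chl


def test_dead_cell_removed_by_chlorophyll_rule():
    labels, chl = _cells_fixture()
    chl[labels == 2] = 0.0  # no chlorophyll: dead
    out, log = curate_cells([LabelMap(labels, "cell", 0)], [chl])
    assert 2 not in np.unique(out[0].labels)
    assert (0, 2, "dead") in log.removed


def test_fused_low_solidity_object_removed_as_overlap():
    labels = np.zeros((60, 100), dtype=np.int32)
    # dumbbell: two 10x10 squares joined by a thin bridge -> solidity ~220/300
    labels[20:30, 10:20] = 1
    labels[20:30, 30:40] = 1
    labels[24:26, 20:30] = 1
    labels[40:50, 60:70] = 2
    chl = np.where(labels > 0, 500.0, 0.0)
    out, log = curate_cells([LabelMap(labels, "cell", 0)], [chl])
    assert 1 not in np.unique(out[0].labels)
    assert (0, 1, "overlap") in log.removed
    assert 2 in np.unique(out[0].labels)


def test_healthy_scene_passes_through_unchanged():
    labels, chl = _cells_fixture()
    out, log = curate_cells([LabelMap(labels, "cell", 0)], [chl])
    np.testing.assert_array_equal(out[0].labels, labels)
    assert log.removed == []


def test_empty_input_passes_through():
    out, log = curate_cells([], [])
    assert out == [] and log.removed == []


# --- puncta ----------------------------------------------------------------

PUNCTA_PARAMS = SegmentationParams(
    puncta_threshold_method="fixed", puncta_fixed_threshold=500.0
)


def _host_cell(shape=(100, 200)):
    cells = np.zeros(shape, dtype=np.int32)
    cells[10:90, 10:190] = 1
    return LabelMap(cells, "cell", 0)


def test_small_punctum_filtered_large_retained():
    cells = _host_cell()
    gfp = np.zeros((100, 200))
    gfp[20:23, 20:30] = 1000.0  # 30 px < 62: filtered
    gfp[50:60, 50:60] = 1000.0  # 100 px: retained
    res = segment_puncta(gfp, cells, PUNCTA_PARAMS)
    assert res.labels.n_objects == 1
    assert res.n_removed_small == 1
    assert np.bincount(res.labels.labels.ravel())[1] == 100


def test_punctum_of_exactly_62_px_is_retained():
    """'Smaller than 62 pixels' are excluded, so 62 itself stays."""
    cells = _host_cell()
    gfp = np.zeros((100, 200))
    gfp[30:32, 30:61] = 1000.0  # 2 x 31 = 62 px
    res = segment_puncta(gfp, cells, PUNCTA_PARAMS)
    assert res.labels.n_objects == 1
    assert np.bincount(res.labels.labels.ravel())[1] == 62


def test_bright_region_outside_cells_is_ignored():
    cells = _host_cell()
    gfp = np.zeros((100, 200))
    gfp[0:8, 0:8] = 1e4  # outside the cell label entirely
    res = segment_puncta(gfp, cells, PUNCTA_PARAMS)
    assert res.labels.n_objects == 0


def test_puncta_pixels_inside_cells_and_parents_assigned(small_scene):
    from redoxscope.segmentation import segment_cells

    f = 0
    bf = small_scene.stack.channel("brightfield", f)
    gfp = small_scene.stack.channel("ex470", f)
    cells = segment_cells(bf, SegmentationParams(border_policy="keep"), f)
    res = segment_puncta(gfp, cells, size_filter=False)
    p = res.labels.labels
    assert ((p > 0) & (cells.labels == 0)).sum() == 0  # containment
    for punc in np.unique(p[p > 0]):
        assert res.parent_cell[int(punc)] in np.unique(cells.labels)


def test_size_filter_off_keeps_small_puncta():
    cells = _host_cell()
    gfp = np.zeros((100, 200))
    gfp[20:23, 20:30] = 1000.0
    res = segment_puncta(gfp, cells, PUNCTA_PARAMS, size_filter=False)
    assert res.labels.n_objects == 1
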