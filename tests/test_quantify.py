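"""Quantification pipeline: projections, threshold rule, metrics, THP-1."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpschip import imaging as I
from lpschip import quantify as Q


def _stack_from_channel(arr_zyx, role="marker"):
    """Wrap a (z, y, x) array as a 4-channel stack with the array in one role."""
    z, h, w = arr_zyx.shape
    data = np.zeros((z, 4, h, w), dtype=np.uint8)
    data[:, I.CHANNEL_ROLES.index(role)] = arr_zyx
    return I.ImageStack(data, 0.5)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_projection_of_constant_stack_is_identity():
    stack = _stack_from_channel(np.full((4, 8, 8), 77, np.uint8))
    assert np.all(Q.project(stack, "marker", "max") == 77)
    assert np.all(Q.project(stack, "marker", "average") == 77)


def test_projection_extremes_forced_arithmetic():
    arr = np.zeros((2, 4, 4), np.uint8)
    arr[1] = 255
    stack = _stack_from_channel(arr)
    assert np.all(Q.project(stack, "marker", "max") == 255)
    assert np.all(Q.project(stack, "marker", "average") == 128)  # half-up


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_projection_equals_bruteforce_reduction(seed):
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 256, size=(5, 16, 16), dtype=np.uint8)
    stack = _stack_from_channel(arr)
    assert np.array_equal(Q.project(stack, "marker", "max"),
                          arr.max(axis=0))
    expected = np.floor(arr.astype(float).mean(axis=0) + 0.5).astype(np.uint8)
    assert np.array_equal(Q.project(stack, "marker", "average"), expected)


def test_projection_rejects_bad_mode():
    stack = _stack_from_channel(np.zeros((2, 4, 4), np.uint8))
    with pytest.raises(Q.QuantifyError):
        Q.project(stack, "marker", "median")


# ---------------------------------------------------------------------------
# top-1% threshold rule
# ---------------------------------------------------------------------------

def _image_with_tail(q99_value, frac_above, size=400):
    """Uint8 image whose fraction of pixels > q99_value is frac_above."""
    n = size * size
    img = np.full(n, q99_value, np.uint8)
    k = int(round(frac_above * n))
    img[:k] = q99_value + 20
    return img.reshape(size, size)


def test_threshold_is_smallest_level_with_tail_below_1pct():
    img = _image_with_tail(9, 0.008)
    assert Q.noise_threshold([img]).value == 10
    img = _image_with_tail(14, 0.008)
    assert Q.noise_threshold([img]).value == 15


def test_threshold_all_zero_dummy():
    img = np.zeros((64, 64), np.uint8)
    assert Q.noise_threshold([img]).value == 1


def test_threshold_pools_across_images():
    a = _image_with_tail(9, 0.0)        # no tail at all
    b = _image_with_tail(9, 0.019)      # 1.9% tail; pooled -> 0.95%
    assert Q.noise_threshold([a, b]).value == 10


def test_threshold_requires_input():
    with pytest.raises(Q.QuantifyError):
        Q.noise_threshold([])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(180, 255))
def test_threshold_monotone_under_brighter_pixels(seed, bright):
    """Adding brighter pixels to the dummy set never lowers the threshold."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 30, size=(128, 128)).astype(np.uint8)
    t0 = Q.noise_threshold([base]).value
    extra = np.full((32, 128), bright, np.uint8)
    t1 = Q.noise_threshold([base, extra]).value
    assert t1 >= t0


# ---------------------------------------------------------------------------
# area-ratio metrics (forced arithmetic)
# ---------------------------------------------------------------------------

def test_icam_ratio_forced_arithmetic():
    img = np.zeros((100, 100), np.uint8)
    mask = np.zeros((100, 100), bool)
    mask[:100, :100] = True           # 10,000 cell pixels
    img[:10, :100] = 50               # 1,000 positive
    thr = Q.Threshold(10)
    assert Q.icam1_area_ratio(img, mask, thr) == pytest.approx(10.0)
    img[:] = 200
    assert Q.icam1_area_ratio(img, mask, thr) == pytest.approx(100.0)
    assert np.isnan(Q.icam1_area_ratio(img, np.zeros_like(mask), thr))


def test_vecad_ratio_forced_arithmetic():
    img = np.zeros((100, 100), np.uint8)
    mask = np.zeros((100, 100), bool)
    mask[:100, :100] = True           # VE+ inside the mask: union = mask
    img[:25, :100] = 40
    img[25, :80] = 40                 # 2,580 positive pixels
    thr = Q.Threshold(15)
    assert Q.vecad_area_ratio(img, mask, thr) == pytest.approx(25.8)
    assert Q.vecad_area_ratio(np.zeros_like(img), mask, thr) == 0.0
    # sum mode double-counts the positives in the denominator
    assert Q.vecad_area_ratio(img, mask, thr, denominator="sum") == \
        pytest.approx(100 * 2580 / 12580)


def test_norm_intensity_hand_example():
    thr = Q.Threshold(10)

    def img(mean):
        return np.full((32, 32), mean, np.uint8)

    groups = {"normal": [img(10), img(10)], "lps": [img(17), img(18)]}
    norm = Q.icam1_norm_intensity(groups, thr, "normal")
    assert norm["normal"] == pytest.approx([1.0, 1.0])
    assert norm["lps"] == pytest.approx([1.7, 1.8])
    # a single normal image normalizes itself to 1
    solo = Q.icam1_norm_intensity({"normal": [img(42)]}, thr, "normal")
    assert solo["normal"] == pytest.approx([1.0])


def test_norm_intensity_requires_normal_group():
    with pytest.raises(Q.QuantifyError):
        Q.icam1_norm_intensity({"lps": []}, Q.Threshold(10), "normal")


# ---------------------------------------------------------------------------
# cell-area mask
# ---------------------------------------------------------------------------

def test_cell_mask_recovers_truth(marker_scene):
    stack, truth = marker_scene
    mask = Q.cell_area_mask(Q.project(stack, "nucleus", "max"),
                            Q.project(stack, "actin", "average"))
    jac = (mask & truth.cell_mask).sum() / (mask | truth.cell_mask).sum()
    assert jac >= 0.9


def test_cell_mask_degenerate_inputs():
    blank = np.zeros((64, 64), np.uint8)
    assert not Q.cell_area_mask(blank, blank).any()
    bright = np.full((64, 64), 240, np.uint8)
    assert Q.cell_area_mask(blank, bright).all()


def test_cell_mask_requires_registration():
    with pytest.raises(Q.QuantifyError):
        Q.cell_area_mask(np.zeros((4, 4), np.uint8),
                         np.zeros((8, 8), np.uint8))


# ---------------------------------------------------------------------------
# THP-1 detection and migration distances
# ---------------------------------------------------------------------------

def test_detect_empty_channel():
    img = np.zeros((64, 64), np.uint8)
    assert Q.detect_thp1(img, Q.Threshold(10), 20) == []


def test_detect_planted_blobs_exact(thp1_scene, icam_threshold):
    stack, truth = thp1_scene
    tracker = Q.project(stack, "tracker", "max")
    cells = Q.detect_thp1(tracker, icam_threshold, 20)
    assert len(cells) == len(truth.thp1_cells)


def test_merged_blobs_count_as_one():
    img = np.zeros((64, 64), np.uint8)
    img[20:30, 20:30] = 100
    img[20:30, 30:40] = 100   # touching -> single component
    cells = Q.detect_thp1(img, Q.Threshold(10), 20)
    assert len(cells) == 1


def test_min_area_filters_specks():
    img = np.zeros((64, 64), np.uint8)
    img[5, 5] = 200
    img[30:40, 30:40] = 200
    assert len(Q.detect_thp1(img, Q.Threshold(10), 20)) == 1


def test_classification_and_distance_rules():
    mask_channel = np.zeros((32, 64), bool)
    mask_channel[10:15, 5:15] = True           # entirely left of the wall
    mask_gel = np.zeros((32, 64), bool)
    mask_gel[4:9, 40:50] = True                # gel side
    straddle = np.zeros((32, 64), bool)
    straddle[20:25, 18:26] = True              # spans the wall at x=20
    out = Q.classify_and_measure([mask_channel, mask_gel, straddle],
                                 wall_x_px=20, pixel_size_um=0.5)
    assert out[0] == ("adhered", 0.0)
    kind, dist = out[1]
    assert kind == "transmigrated"
    assert dist == pytest.approx((40 - 20) * 0.5)
    kind, dist = out[2]                        # any gel-side pixel counts
    assert kind == "transmigrated"
    assert dist == pytest.approx((21 - 20) * 0.5)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_distance_equals_bruteforce_pixel_scan(seed):
    rng = np.random.default_rng(seed)
    blob = rng.random((24, 48)) > 0.7
    if not blob.any():
        blob[3, 3] = True
    wall = 11
    px = 0.5
    (kind, dist), = Q.classify_and_measure([blob], wall, px)
    xs = np.nonzero(blob)[1]
    gel = xs[xs > wall]
    if gel.size:
        assert kind == "transmigrated"
        assert dist == pytest.approx(min((x - wall) * px for x in gel))
    else:
        assert kind == "adhered" and dist == 0.0


def test_end_to_end_scene_quantification(thp1_scene, icam_threshold):
    stack, truth = thp1_scene
    recs = Q.quantify_thp1_stack(stack, icam_threshold,
                                 wall_x_px=truth.wall_x_px, image_id="s")
    by = {r.metric: r.value for r in recs if r.metric.startswith("n_")}
    assert by["n_adhered"] == 20
    assert by["n_transmigrated"] == 3
    dists = sorted(r.value for r in recs
                   if r.metric == "migration_distance_um")
    planted = sorted(c.distance_um for c in truth.thp1_cells
                     if c.kind == "transmigrated")
    for d, p in zip(dists, planted):
        assert abs(d - p) <= 0.5 * stack.pixel_size_um
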