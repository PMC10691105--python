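"""Localization: activation maps, lambda schedule, masks, boxes, crops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestfusion.backbone import FeatureBlock, FeatureStack
from pestfusion.eflm import (ActivationMap, BoundingBox, LambdaSchedule,
                             MaskMap, aggregate_channels, crop_and_upsample,
                             intersect_masks, lambda_at, localize,
                             mask_to_bbox, threshold_mask)
from pestfusion.synthetic import generate_feature_stack_fixture


def brute_force_localize(blocks: list[np.ndarray], lam: float):
    """Independent elementwise re-implementation: channel sum, strict
    threshold at lam * mean, all-blocks intersection, min/max box with
    whole-map fallback."""
    h, w = blocks[0].shape[1:]
    masks = []
    for blk in blocks:
        a = np.zeros((h, w))
        for ch in blk:
            a += ch
        abar = a.sum() / (h * w)
        m = np.zeros((h, w), dtype=int)
        for i in range(h):
            for j in range(w):
                if a[i, j] > lam * abar:
                    m[i, j] = 1
        masks.append(m)
    inter = np.ones((h, w), dtype=int)
    for m in masks:
        inter = inter * m
    coords = [(i, j) for i in range(h) for j in range(w) if inter[i, j]]
    if not coords:
        return masks, inter, (0, h, 0, w)
    rs = [c[0] for c in coords]
    cs = [c[1] for c in coords]
    return masks, inter, (min(rs), max(rs) + 1, min(cs), max(cs) + 1)


# -- aggregation --------------------------------------------------------------

def test_aggregate_channels_worked_example():
    blk = FeatureBlock(np.array([[[1.0, 0.0], [0.0, 1.0]],
                                 [[1.0, 2.0], [3.0, 0.0]]]))
    a = aggregate_channels(blk)
    np.testing.assert_array_equal(a.values, [[2.0, 2.0], [3.0, 1.0]])
    assert a.mean_value == 2.0


def test_aggregate_single_channel_is_identity():
    vals = np.random.default_rng(0).normal(size=(1, 4, 4))
    a = aggregate_channels(FeatureBlock(vals))
    np.testing.assert_array_equal(a.values, vals[0])
    assert a.mean_value == pytest.approx(vals[0].mean())


# -- lambda schedule ----------------------------------------------------------

def test_lambda_schedule_endpoints_and_test_value():
    sched = LambdaSchedule(epochs=20)
    assert lambda_at(sched, 0, "train") == 0.0
    assert lambda_at(sched, 19, "train") == 1.0
    assert lambda_at(sched, 10, "test") == 0.5
    assert lambda_at(sched, 5, "val") == lambda_at(sched, 5, "train")


def test_lambda_schedule_edges():
    assert lambda_at(LambdaSchedule(epochs=1), 0, "train") == 1.0
    with pytest.raises(ValueError):
        lambda_at(LambdaSchedule(epochs=20), 20, "train")
    sched = LambdaSchedule(epochs=7)
    vals = [lambda_at(sched, e, "train") for e in range(7)]
    assert vals == sorted(vals) and all(0 <= v <= 1 for v in vals)


# -- thresholding / intersection / boxes --------------------------------------

def test_threshold_mask_worked_example():
    a = ActivationMap(np.array([[1.0, 3.0], [5.0, 7.0]]), 4.0)
    np.testing.assert_array_equal(threshold_mask(a, 0.5).values,
                                  [[0, 1], [1, 1]])


def test_threshold_mask_ties_drop_and_lam_zero():
    # at lam=1 every position of a constant map ties A = lam*mean exactly,
    # and strict inequality drops all of them
    const = ActivationMap(np.full((3, 3), 2.0), 2.0)
    assert threshold_mask(const, 1.0).values.sum() == 0
    # an all-zero map ties at every lam
    zero = ActivationMap(np.zeros((3, 3)), 0.0)
    assert threshold_mask(zero, 0.7).values.sum() == 0
    pos = ActivationMap(np.array([[1.0, 2.0], [3.0, 4.0]]), 2.5)
    assert threshold_mask(pos, 0.0).values.sum() == 4


def test_intersect_masks_examples():
    m1 = MaskMap(np.array([[1, 1], [0, 1]]))
    m2 = MaskMap(np.array([[1, 0], [0, 1]]))
    np.testing.assert_array_equal(intersect_masks([m1, m2]).values,
                                  [[1, 0], [0, 1]])
    eye = MaskMap(np.eye(3, dtype=int))
    ones = MaskMap(np.ones((3, 3), dtype=int))
    np.testing.assert_array_equal(
        intersect_masks([ones, eye, ones]).values, eye.values)
    np.testing.assert_array_equal(intersect_masks([m1]).values, m1.values)
    with pytest.raises(ValueError, match="mismatch"):
        intersect_masks([m1, MaskMap(np.ones((3, 3), dtype=int))])


def test_mask_to_bbox_examples():
    m = np.zeros((4, 5), dtype=int)
    m[1, 1] = m[2, 3] = 1
    assert mask_to_bbox(MaskMap(m)) == BoundingBox(1, 3, 1, 4)
    assert mask_to_bbox(MaskMap(np.zeros((4, 5), dtype=int))) == \
        BoundingBox(0, 4, 0, 5)     # empty mask falls back to the whole map
    assert mask_to_bbox(MaskMap(np.ones((4, 5), dtype=int))) == \
        BoundingBox(0, 4, 0, 5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_bbox_is_minimal_cover(seed):
    rng = np.random.default_rng(seed)
    m = (rng.random((6, 7)) < 0.3).astype(int)
    box = mask_to_bbox(MaskMap(m))
    rows, cols = np.nonzero(m)
    if rows.size:
        assert (rows >= box.row_start).all() and (rows < box.row_stop).all()
        assert (cols >= box.col_start).all() and (cols < box.col_stop).all()
        # no strictly smaller box covers: the extremes touch the edges
        assert box.row_start in rows and box.row_stop - 1 in rows
        assert box.col_start in cols and box.col_stop - 1 in cols


# -- crop + upsample ----------------------------------------------------------

def test_crop_full_box_is_identity():
    rng = np.random.default_rng(4)
    stack = FeatureStack([FeatureBlock(rng.normal(size=(3, 6, 6)))])
    out = crop_and_upsample(stack, BoundingBox(0, 6, 0, 6))
    assert np.abs(out.blocks[0].values - stack.blocks[0].values).max() < 1e-6


def test_crop_constant_block_stays_constant():
    stack = FeatureStack([FeatureBlock(np.full((2, 5, 5), 3.3))])
    out = crop_and_upsample(stack, BoundingBox(1, 4, 0, 2))
    np.testing.assert_allclose(out.blocks[0].values, 3.3)


def test_crop_single_cell_broadcasts_value():
    vals = np.arange(16.0).reshape(1, 4, 4)
    stack = FeatureStack([FeatureBlock(vals)])
    out = crop_and_upsample(stack, BoundingBox(2, 3, 1, 2))
    np.testing.assert_allclose(out.blocks[0].values, vals[0, 2, 1])


# -- localize composition -----------------------------------------------------

def test_localize_planted_hot_region():
    stack, _, expected_box = generate_feature_stack_fixture(
        8, 8, 3, (2, 5, 3, 6), hot_value=10.0, background_value=0.1, seed=0)
    _, box = localize(stack, 0.5)
    assert box == expected_box == BoundingBox(2, 5, 3, 6)


def test_localize_lambda_zero_is_identity():
    rng = np.random.default_rng(5)
    stack = FeatureStack([FeatureBlock(rng.uniform(0.1, 1.0, (4, 8, 8)))
                          for _ in range(3)])
    out, box = localize(stack, 0.0)
    assert box == BoundingBox(0, 8, 0, 8)
    for a, b in zip(out.blocks, stack.blocks):
        assert np.abs(a.values - b.values).max() < 1e-6


def test_localize_disjoint_blocks_fall_back_to_full_map():
    stack, _, expected_box = generate_feature_stack_fixture(
        8, 8, 3, [(0, 2, 0, 2), (4, 6, 4, 6), (6, 8, 0, 2)],
        hot_value=10.0, background_value=0.1, seed=1)
    _, box = localize(stack, 0.5)
    assert box == expected_box == BoundingBox(0, 8, 0, 8)


def test_localize_retained_positions_shrink_with_lambda():
    rng = np.random.default_rng(6)
    stack = FeatureStack([FeatureBlock(rng.uniform(0, 1, (4, 8, 8)))
                          for _ in range(3)])
    prev = None
    for lam in np.linspace(0, 1, 11):
        masks = [threshold_mask(aggregate_channels(b), lam)
                 for b in stack.blocks]
        cur = intersect_masks(masks).values
        if prev is not None:
            assert (cur <= prev).all()
        prev = cur


def test_localize_matches_brute_force_on_random_stacks():
    rng = np.random.default_rng(7)
    for _ in range(10):
        blocks = [rng.uniform(0, 1, (4, 8, 8)) for _ in range(3)]
        lam = rng.uniform(0, 1)
        _, box = localize(FeatureStack([FeatureBlock(b) for b in blocks]), lam)
        _, _, ref = brute_force_localize(blocks, lam)
        assert (box.row_start, box.row_stop, box.col_start, box.col_stop) == ref


def test_localize_num_blocks_subset():
    stack, _, _ = generate_feature_stack_fixture(
        8, 8, 3, [(0, 3, 0, 3), (0, 3, 0, 3), (5, 8, 5, 8)],
        hot_value=10.0, background_value=0.1, seed=2)
    _, box1 = localize(stack, 0.5, num_blocks=1)   # only the last block
    assert box1 == BoundingBox(5, 8, 5, 8)


def test_boxes_csv_export(tmp_path):
    from pestfusion.eflm import boxes_to_csv

    boxes = [BoundingBox(1, 3, 2, 5), BoundingBox(0, 8, 0, 8)]
    path = tmp_path / "boxes.csv"
    boxes_to_csv(["a.png", "b.png"], boxes, lam=0.5, path=path, stride=8)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("image_id")
    assert lines[1] == "a.png,8,24,16,40,0.5"   # stride 8 back-projection
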