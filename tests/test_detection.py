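"""Box geometry, losses, NMS, target assignment, and decode round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskdet.detection import (
    Detection,
    assign_targets,
    classification_loss,
    decode_box,
    encode_box,
    fuse_detections,
    iou,
    iou_loss,
    kmeans_anchors,
    nms,
)

boxes_st = st.tuples(
    st.floats(0, 50), st.floats(0, 50), st.floats(1, 50), st.floats(1, 50)
).map(lambda t: (t[0], t[1], t[0] + t[2], t[1] + t[3]))


def test_iou_known_values():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
    assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(a=boxes_st, b=boxes_st)
def test_iou_symmetric_and_bounded(a, b):
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == iou(b, a)
    assert iou(a, a) == 1.0


def test_iou_loss_closed_forms():
    assert iou_loss((0, 0, 2, 2), (0, 0, 2, 2)) == 0.0
    assert iou_loss((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(
        -np.log(1 / 7), abs=1e-9)
    disjoint = iou_loss((0, 0, 1, 1), (5, 5, 6, 6))
    assert np.isfinite(disjoint)
    assert disjoint == pytest.approx(-np.log(1e-7), abs=1e-6)


def test_iou_loss_monotone_in_overlap():
    """Sliding a unit box away from a fixed box decreases IoU and must
    increase the loss at every step."""
    fixed = (0.0, 0.0, 10.0, 10.0)
    losses = [iou_loss((dx, 0, dx + 10, 10), fixed)
              for dx in np.linspace(0, 9.5, 30)]
    assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))


def test_classification_loss_examples(rng):
    assert classification_loss([1.0, 0.0], [1.0, 0.0]) == pytest.approx(
        0.0, abs=1e-5)
    assert classification_loss([0.5, 0.5], [1.0, 0.0]) == pytest.approx(
        2 * np.log(2), abs=1e-9)
    # brute-force elementwise oracle on random simplex vectors
    for _ in range(50):
        p = rng.dirichlet(np.ones(4))
        y = np.eye(4)[rng.integers(0, 4)]
        pc = np.clip(p, 1e-7, 1 - 1e-7)
        ref = 0.0
        for k in range(4):
            ref -= y[k] * np.log(pc[k]) + (1 - y[k]) * np.log(1 - pc[k])
        assert classification_loss(p, y) == pytest.approx(ref, abs=1e-6)


def test_nms_keeps_best_of_overlapping_pair():
    a = Detection(np.array([0, 0, 10, 10.0]), 0, np.array([1.0]), 0.9)
    b = Detection(np.array([0, 0, 10, 11.0]), 0, np.array([1.0]), 0.8)
    kept = nms([a, b], iou_thr=0.5, conf_thr=0.1)
    assert len(kept) == 1 and kept[0].objectness == 0.9


def test_nms_is_class_wise():
    a = Detection(np.array([0, 0, 10, 10.0]), 0, np.array([1.0, 0.0]), 0.9)
    b = Detection(np.array([0, 0, 10, 11.0]), 1, np.array([0.0, 1.0]), 0.8)
    assert len(nms([a, b], iou_thr=0.5, conf_thr=0.1)) == 2


def _exhaustive_nms(dets, iou_thr, conf_thr):
    """O(n^2) oracle: repeatedly take the global best remaining detection
    and delete all same-class overlaps."""
    alive = [(i, d) for i, d in enumerate(dets) if d.score >= conf_thr]
    kept = []
    while alive:
        alive.sort(key=lambda t: (-t[1].score, t[0]))
        i, best = alive.pop(0)
        kept.append(i)
        alive = [(j, d) for j, d in alive
                 if d.class_id != best.class_id or iou(d.box, best.box) <= iou_thr]
    return sorted(kept)


def test_nms_matches_exhaustive_oracle(rng):
    for _ in range(10):
        dets = []
        for _ in range(50):
            x0, y0 = rng.uniform(0, 40, 2)
            w, h = rng.uniform(2, 20, 2)
            dets.append(Detection(np.array([x0, y0, x0 + w, y0 + h]),
                                  int(rng.integers(0, 3)),
                                  np.ones(3) / 3, float(rng.random())))
        got = nms(dets, 0.45, 0.1)
        got_ids = sorted(
            [i for i, d in enumerate(dets) if any(d is g for g in got)])
        assert got_ids == _exhaustive_nms(dets, 0.45, 0.1)


def test_fusion_merges_same_class_clusters():
    a = Detection(np.array([0, 0, 10, 10.0]), 0, np.array([1.0]), 0.9)
    b = Detection(np.array([2, 2, 12, 12.0]), 0, np.array([1.0]), 0.3)
    c = Detection(np.array([30, 30, 40, 40.0]), 0, np.array([1.0]), 0.5)
    fused = fuse_detections([a, b, c], iou_thr=0.3)
    assert len(fused) == 2
    merged = fused[0]
    expected = np.average(np.stack([a.box, b.box]), axis=0,
                          weights=[a.score, b.score])
    assert np.allclose(merged.box, expected)
    assert merged.objectness == 0.9


@settings(max_examples=60, deadline=None)
@given(cx=st.floats(2, 62), cy=st.floats(2, 62), w=st.floats(2, 30),
       h=st.floats(2, 30))
def test_decode_encode_round_trip(cx, cy, w, h):
    stride = 8.0
    prior = np.array([10.0, 12.0])
    box = np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
    cell = (int(cx // stride), int(cy // stride))
    t = encode_box(box, cell, prior, stride)
    back = decode_box(t, cell, prior, stride)
    assert np.abs(back - box).max() < 1e-4


def test_assignment_contracts():
    anchors = [np.array([[8.0, 8.0]]), np.array([[20.0, 20.0]])]
    strides = [8.0, 16.0]
    grids = [(8, 8), (4, 4)]
    # a gt exactly matching the level-1 prior goes to level 1
    gt = np.array([[22.0, 22.0, 42.0, 42.0]])
    slots = assign_targets(gt, [0], anchors, strides, grids,
                           multi_thr=None, neighbor_cells=False)
    assert len(slots) == 1 and slots[0].level == 1
    assert slots[0].cell == (2, 2)
    # single gt, single anchor, single-cell grid
    slots = assign_targets(np.array([[1, 1, 5, 5.0]]), [0],
                           [np.array([[4.0, 4.0]])], [64.0], [(1, 1)],
                           multi_thr=None, neighbor_cells=False)
    assert slots[0].cell == (0, 0)
    # every gt gets at least one responsible predictor
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(1, 6))
        x0 = rng.uniform(0, 40, n)
        y0 = rng.uniform(0, 40, n)
        gts = np.stack([x0, y0, x0 + rng.uniform(2, 20, n),
                        y0 + rng.uniform(2, 20, n)], axis=1)
        slots = assign_targets(gts, np.zeros(n, int), anchors, strides, grids)
        assert len({s.gt_index for s in slots}) == n
        assert len(slots) >= n


def test_kmeans_anchors_cover_box_scales(rng):
    wh = rng.uniform(4, 24, size=(60, 2))
    boxes = np.concatenate([np.zeros((60, 2)), wh], axis=1)
    priors = kmeans_anchors(boxes, 4, seed=0)
    assert priors.shape == (4, 2)
    areas = priors[:, 0] * priors[:, 1]
    assert (np.diff(areas) >= 0).all()
    assert priors.min() >= 1.0
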