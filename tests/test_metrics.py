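"""Evaluation oracles: greedy matching, 101-point AP, size bands, composite."""

import numpy as np
import pytest

from maskdet.metrics import (
    accuracy,
    ap_at,
    ap_by_size,
    coco_map,
    evaluate_detections,
    map_composite,
    match_detections,
    pr_points,
)


def det(box, score, cls=0):
    return (np.asarray(box, float), score, cls)


def scene(dets, gts_boxes, gts_labels=None):
    labels = gts_labels if gts_labels is not None else [0] * len(gts_boxes)
    return [dets], [(np.asarray(gts_boxes, float).reshape(-1, 4),
                     np.asarray(labels, int))]


def test_accuracy_basic():
    assert accuracy([1, 0, 1, 1], [1, 0, 0, 1]) == 0.75
    assert accuracy([2, 2], [2, 2]) == 1.0
    assert accuracy([0, 0], [1, 1]) == 0.0
    with pytest.raises(ValueError):
        accuracy([], [])
    with pytest.raises(ValueError):
        accuracy([1], [1, 2])


def test_single_perfect_detection_gives_unit_pr():
    dets, gts = scene([det([0, 0, 10, 10], 0.9)], [[0, 0.5, 10, 10.5]])
    precision, recall, envelope = pr_points(dets, gts, 0.5)
    assert precision.tolist() == [1.0] and recall.tolist() == [1.0]
    assert ap_at(dets, gts, 0.5) == 1.0


def test_spurious_second_detection_keeps_envelope_at_full_recall():
    dets, gts = scene(
        [det([0, 0, 10, 10], 0.9), det([30, 30, 40, 40], 0.8)],
        [[0, 0, 10, 10]],
    )
    precision, recall, envelope = pr_points(dets, gts, 0.5)
    assert precision.tolist() == [1.0, 0.5]
    assert recall.tolist() == [1.0, 1.0]
    # as a function of recall the envelope at recall 1.0 is 1.0, so AP is 1
    assert ap_at(dets, gts, 0.5) == 1.0


def test_half_recall_perfect_precision_gives_51_of_101():
    dets, gts = scene(
        [det([0, 0, 10, 10], 0.9)],
        [[0, 0, 10, 10], [50, 50, 60, 60]],
    )
    assert ap_at(dets, gts, 0.5) == pytest.approx(51 / 101, abs=1e-12)


def test_empty_scene_has_ap_zero():
    assert ap_at([[]], [(np.zeros((0, 4)), np.zeros(0, int))], 0.5) == 0.0


def test_envelope_is_monotone_nonincreasing(rng):
    dets, gts = _random_scene(rng, 20, 8)
    _, _, envelope = pr_points(dets, gts, 0.5)
    if len(envelope):
        assert (np.diff(envelope) <= 1e-12).all()


def test_ap_invariant_to_monotone_score_rescaling(rng):
    dets, gts = _random_scene(rng, 15, 5)
    base = ap_at(dets, gts, 0.5)
    rescaled = [[(b, float(np.tanh(3 * s) + 7), c) for b, s, c in per]
                for per in dets]
    assert ap_at(rescaled, gts, 0.5) == pytest.approx(base, abs=1e-12)


def test_duplicate_detection_never_raises_ap(rng):
    for _ in range(20):
        dets, gts = _random_scene(rng, 10, 4)
        base = ap_at(dets, gts, 0.5)
        m = match_detections(dets, gts, 0.5)
        if not m.tp.any():
            continue
        first_tp = m.order[np.argmax(m.tp)]
        dup_box, dup_score, dup_cls = dets[0][first_tp]
        dets_dup = [list(dets[0]) + [(dup_box, dup_score * 0.99, dup_cls)]]
        assert ap_at(dets_dup, gts, 0.5) <= base + 1e-12


def _random_scene(rng, n_dets, n_gts, n_classes=2, size=100):
    gts_boxes, gts_labels, dets = [], [], []
    for _ in range(n_gts):
        x0, y0 = rng.uniform(0, size - 20, 2)
        w, h = rng.uniform(4, 20, 2)
        gts_boxes.append([x0, y0, x0 + w, y0 + h])
        gts_labels.append(int(rng.integers(0, n_classes)))
    for _ in range(n_dets):
        if gts_boxes and rng.random() < 0.6:
            # jittered copy of some gt
            g = gts_boxes[int(rng.integers(0, len(gts_boxes)))]
            j = rng.normal(0, 3, 4)
            box = [g[0] + j[0], g[1] + j[1],
                   max(g[2] + j[2], g[0] + j[0] + 1),
                   max(g[3] + j[3], g[1] + j[1] + 1)]
        else:
            x0, y0 = rng.uniform(0, size - 20, 2)
            box = [x0, y0, x0 + rng.uniform(2, 25), y0 + rng.uniform(2, 25)]
        dets.append((np.asarray(box), float(rng.random()),
                     int(rng.integers(0, n_classes))))
    return [dets], [(np.asarray(gts_boxes, float).reshape(-1, 4),
                     np.asarray(gts_labels, int))]


def _brute_force_match(dets, gts, iou_thr):
    """Independent greedy matcher over explicit python structures."""
    from maskdet.detection import iou as iou_fn

    flat_d = [(img, b, s, c) for img, per in enumerate(dets)
              for b, s, c in per]
    flat_g = [(img, b, int(l)) for img, (bs, ls) in enumerate(gts)
              for b, l in zip(np.asarray(bs).reshape(-1, 4), ls)]
    order = sorted(range(len(flat_d)), key=lambda i: (-flat_d[i][2], i))
    taken = set()
    flags = []
    for di in order:
        img, box, _, cls = flat_d[di]
        cands = [(iou_fn(box, gb), gi) for gi, (gim, gb, gl) in
                 enumerate(flat_g)
                 if gim == img and gl == cls and gi not in taken]
        cands = [(v, gi) for v, gi in cands if v >= iou_thr]
        if cands:
            v, gi = max(cands, key=lambda t: (t[0], -t[1]))
            taken.add(gi)
            flags.append(True)
        else:
            flags.append(False)
    return np.array(flags, dtype=bool)


def test_matching_agrees_with_brute_force_on_200_scenes(rng):
    """Full TP/FP agreement between the matcher and an independent
    enumeration on randomized small scenes."""
    for _ in range(200):
        dets, gts = _random_scene(rng, int(rng.integers(0, 12)),
                                  int(rng.integers(0, 6)))
        got = match_detections(dets, gts, 0.5)
        ref = _brute_force_match(dets, gts, 0.5)
        assert np.array_equal(got.tp, ref)


def test_ap_cross_checked_against_independent_implementation(rng):
    """AP from the package vs. a from-scratch re-implementation of the
    101-point interpolated metric on 50 random scenes."""
    for _ in range(50):
        dets, gts = _random_scene(rng, int(rng.integers(1, 15)),
                                  int(rng.integers(1, 6)))
        tp = _brute_force_match(dets, gts, 0.5)
        n_gt = len(gts[0][0])
        tp_c = np.cumsum(tp)
        fp_c = np.cumsum(~tp)
        prec = tp_c / np.maximum(tp_c + fp_c, 1)
        rec = tp_c / n_gt
        ref = 0.0
        for r in np.linspace(0, 1, 101):
            cands = prec[rec >= r - 1e-12]
            ref += cands.max() if len(cands) else 0.0
        ref /= 101
        assert ap_at(dets, gts, 0.5) == pytest.approx(ref, abs=1e-9)


def test_size_bands_half_open_convention():
    # area exactly 32^2 falls in the middle band
    gt_small = [0, 0, 31, 31]          # area 961 < 1024
    gt_boundary = [40, 40, 72, 72]     # area exactly 1024
    dets = [det(gt_small, 0.9), det(gt_boundary, 0.8)]
    d, g = scene(dets, [gt_small, gt_boundary])
    ap_s, ap_m, ap_l = ap_by_size(d, g, 0.5)
    assert ap_s == 1.0 and ap_m == 1.0 and ap_l is None


def test_all_small_scene_small_band_equals_overall():
    dets = [det([0, 0, 10, 10], 0.9), det([30, 30, 38, 38], 0.7),
            det([60, 60, 70, 75], 0.5)]
    d, g = scene(dets, [[0, 0, 10, 10], [30, 30, 38, 38]])
    ap_s, ap_m, ap_l = ap_by_size(d, g, 0.5)
    assert ap_m is None and ap_l is None
    assert ap_s == pytest.approx(ap_at(d, g, 0.5), abs=1e-12)


def test_banding_matches_brute_force_oracle(rng):
    """Synthetic scene with known per-band memberships: recompute each band
    AP by filtering ground truths and matched detections by hand."""
    from maskdet.metrics import _ap_from_pr, _band_of

    for _ in range(30):
        dets, gts = _random_scene(rng, 12, 5, size=250)
        m = match_detections(dets, gts, 0.5)
        flat_g = [(b, l) for b, l in zip(gts[0][0], gts[0][1])]
        bands = [_band_of(float((b[2] - b[0]) * (b[3] - b[1])))
                 for b, _ in flat_g]
        got = dict(zip(("small", "medium", "large"),
                       ap_by_size(dets, gts, 0.5)))
        for band in ("small", "medium", "large"):
            n_band = bands.count(band)
            if n_band == 0:
                assert got[band] is None
                continue
            flags, _scores = [], []
            for rank in range(len(m.tp)):
                if m.tp[rank]:
                    if bands[m.matched_gt[rank][1]] != band:
                        continue
                    flags.append(True)
                else:
                    flags.append(False)
            if not flags:
                assert got[band] == 0.0
                continue
            tp = np.array(flags)
            prec = np.cumsum(tp) / (np.arange(len(tp)) + 1)
            rec = np.cumsum(tp) / n_band
            env = np.maximum.accumulate(prec[::-1])[::-1]
            assert got[band] == pytest.approx(_ap_from_pr(rec, env), abs=1e-12)


def test_map_composite_mean_and_fallback():
    assert map_composite(0.8, 0.8, 0.8, 0.8, 0.8) == pytest.approx(0.8)
    assert map_composite(1.0, 0.5, 0.5, 0.5, 0.5) == pytest.approx(0.6)
    with pytest.warns(UserWarning):
        assert map_composite(0.8, 0.8, 0.8, None, 0.8) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        map_composite(None, None, None, None, None)


def test_evaluate_detections_report_consistency(rng):
    dets, gts = _random_scene(rng, 20, 8)
    report = evaluate_detections(dets, gts)
    assert 0.0 <= report.accuracy <= 1.0
    for v in (report.ap50, report.ap75, report.coco_map):
        assert 0.0 <= v <= 1.0
    defined = [v for v in (report.ap50, report.ap75, report.ap_s,
                           report.ap_m, report.ap_l) if v is not None]
    assert report.map_composite == pytest.approx(np.mean(defined))
    assert report.coco_map == pytest.approx(coco_map(dets, gts))
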