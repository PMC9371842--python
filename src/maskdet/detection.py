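"""Single-stage anchor-based detection on top of the backbone feature maps.

The neck fuses the backbone's multi-scale maps with a top-down (FPN) pass
followed by a bottom-up (PAN) pass; a linear prediction head at every level
emits, per grid cell and anchor, raw offsets (tx, ty, tw, th), an objectness
logit and class logits.  Decoding follows the YOLO convention:

    center = (cell + sigmoid(t_xy)) * stride,   size = prior * exp(t_wh)

Training minimises, over assigned (ground truth, anchor) pairs,

    -ln IoU(box_pred, box_gt)                       (box regression)
    -sum_k [y_k ln p_k + (1 - y_k) ln(1 - p_k)]     (classification)

plus a binary cross-entropy objectness term.  By default objectness regresses
a geometric target — the IoU each cell-centred prior has with its best ground
truth — which is stationary over training and keeps the confidence ranking
comparable across images; the dynamic decoded-box-IoU target is available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import HierarchicalBackbone
from .nn import Adam, Linear, Module
from .patching import patchify
from .synthetic import AnnotatedImage

__all__ = [
    "Detection",
    "iou",
    "iou_matrix",
    "iou_loss",
    "classification_loss",
    "kmeans_anchors",
    "encode_box",
    "decode_box",
    "assign_targets",
    "nms",
    "fuse_detections",
    "Neck",
    "DetectionHead",
    "WindowDetector",
]

_EPS = 1e-7


@dataclass
class Detection:
    """One predicted box with class scores and confidence."""

    box: np.ndarray            # (4,) x_min, y_min, x_max, y_max, pixels
    class_id: int
    class_probs: np.ndarray    # simplex over classes
    objectness: float

    @property
    def score(self) -> float:
        return float(self.objectness * self.class_probs[self.class_id])


def iou(a, b) -> float:
    """Intersection-over-union of two well-ordered boxes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 4) and (m, 4) box arrays."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2])
        - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3])
        - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None,
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, _EPS)


def iou_loss(pred, gt, eps: float = _EPS) -> float:
    """Negative log IoU, clamped so disjoint boxes give a finite loss."""
    return float(-np.log(max(iou(pred, gt), eps)))


def classification_loss(p, y, eps: float = _EPS) -> float:
    """Per-class binary cross-entropy between simplex probs p and one-hot y."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability and target shapes differ")
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def kmeans_anchors(boxes: np.ndarray, k: int, seed: int = 0,
                   iters: int = 50) -> np.ndarray:
    """Cluster box (w, h) pairs with the 1 - IoU shape distance; returns
    (k, 2) priors sorted by area (classic YOLO anchor estimation)."""
    wh = np.stack(
        [boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1]], axis=1
    ).astype(float)
    rng = np.random.default_rng(seed)
    if len(wh) < k:
        wh = np.concatenate([wh] * (k // max(len(wh), 1) + 1))[: max(k, 1)]
    centers = wh[rng.choice(len(wh), size=k, replace=False)]
    for _ in range(iters):
        inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * np.minimum(
            wh[:, None, 1], centers[None, :, 1]
        )
        union = wh[:, 0:1] * wh[:, 1:2] + (centers[:, 0] * centers[:, 1])[None] - inter
        assign = np.argmax(inter / np.maximum(union, _EPS), axis=1)
        new = centers.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                new[j] = np.median(members, axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return np.maximum(centers[order], 1.0)


def encode_box(box: np.ndarray, cell: tuple[int, int], prior: np.ndarray,
               stride: float) -> np.ndarray:
    """Inverse of :func:`decode_box` for a box whose center lies within the
    cell's expanded reach (offset fraction in (-0.5, 1.5))."""
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    w, h = x1 - x0, y1 - y0
    fx = np.clip((cx / stride - cell[0] + 0.5) / 2.0, _EPS, 1 - _EPS)
    fy = np.clip((cy / stride - cell[1] + 0.5) / 2.0, _EPS, 1 - _EPS)
    return np.array(
        [np.log(fx / (1 - fx)), np.log(fy / (1 - fy)),
         np.log(w / prior[0]), np.log(h / prior[1])]
    )


def decode_box(t: np.ndarray, cell: tuple[int, int], prior: np.ndarray,
               stride: float) -> np.ndarray:
    """Raw offsets -> (x_min, y_min, x_max, y_max) in pixels (no clipping).

    The centre offset is 2*sigmoid(t) - 0.5 cells, letting neighbouring
    cells reach a ground truth near the cell boundary."""
    sx = 2.0 / (1.0 + np.exp(-t[0])) - 0.5
    sy = 2.0 / (1.0 + np.exp(-t[1])) - 0.5
    cx, cy = (cell[0] + sx) * stride, (cell[1] + sy) * stride
    w, h = prior[0] * np.exp(t[2]), prior[1] * np.exp(t[3])
    return np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])


@dataclass(frozen=True)
class AnchorSlot:
    """One responsible predictor: pyramid level, grid cell, anchor index."""

    gt_index: int
    level: int
    cell: tuple[int, int]      # (cx_cell, cy_cell)
    anchor: int


def _shape_iou(wh: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """IoU between a gt (w, h) and prior shapes, both centered at the origin."""
    inter = np.minimum(wh[0], priors[:, 0]) * np.minimum(wh[1], priors[:, 1])
    union = wh[0] * wh[1] + priors[:, 0] * priors[:, 1] - inter
    return inter / np.maximum(union, _EPS)


def assign_targets(
    boxes: np.ndarray,
    labels: np.ndarray,
    anchors: list[np.ndarray],
    strides: list[float],
    grid_shapes: list[tuple[int, int]],
    multi_thr: float | None = 0.5,
    neighbor_cells: bool = True,
) -> list[AnchorSlot]:
    """Assign each ground-truth box its best-shape anchor (plus any anchor
    with shape IoU >= multi_thr when enabled); the containing cell at that
    anchor's level is responsible, together with the two nearest neighbour
    cells when ``neighbor_cells`` (they reach the centre via the expanded
    offset range)."""
    slots: list[AnchorSlot] = []
    seen: set[tuple] = set()
    for g, box in enumerate(np.asarray(boxes, dtype=float).reshape(-1, 4)):
        wh = np.array([box[2] - box[0], box[3] - box[1]])
        cx, cy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
        per_level = [_shape_iou(wh, a) for a in anchors]
        flat = np.concatenate(per_level)
        picks = {int(np.argmax(flat))}
        if multi_thr is not None:
            picks |= set(np.nonzero(flat >= multi_thr)[0].tolist())
        offsets = np.cumsum([0] + [len(a) for a in anchors])
        for p in picks:
            level = int(np.searchsorted(offsets, p, side="right") - 1)
            a_idx = int(p - offsets[level])
            gh, gw = grid_shapes[level]
            cell_x = int(np.clip(cx // strides[level], 0, gw - 1))
            cell_y = int(np.clip(cy // strides[level], 0, gh - 1))
            cells = [(cell_x, cell_y)]
            if neighbor_cells:
                fx = cx / strides[level] - cell_x
                fy = cy / strides[level] - cell_y
                cells.append((cell_x + (1 if fx >= 0.5 else -1), cell_y))
                cells.append((cell_x, cell_y + (1 if fy >= 0.5 else -1)))
            for nx, ny in cells:
                if not (0 <= nx < gw and 0 <= ny < gh):
                    continue
                key = (g, level, nx, ny, a_idx)
                if key in seen:
                    continue
                seen.add(key)
                slots.append(AnchorSlot(g, level, (nx, ny), a_idx))
    return slots


def fuse_detections(dets: list[Detection], iou_thr: float = 0.3) -> list[Detection]:
    """Score-weighted box fusion: greedily cluster same-class detections by
    IoU with the current best and replace each cluster by the score-weighted
    average box carrying the cluster's maximum confidence.  Averaging over
    the anchor neighbourhood cancels per-anchor regression noise, which
    matters for small targets where one pixel of offset moves the IoU a lot.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = [False] * len(dets)
    fused: list[Detection] = []
    for i in order:
        if used[i]:
            continue
        used[i] = True
        cluster = [dets[i]]
        for j in order:
            if used[j] or dets[j].class_id != dets[i].class_id:
                continue
            if iou(dets[i].box, dets[j].box) > iou_thr:
                used[j] = True
                cluster.append(dets[j])
        weights = np.array([c.score for c in cluster])
        box = np.average(np.stack([c.box for c in cluster]), axis=0,
                         weights=weights)
        best = cluster[0]
        fused.append(Detection(box, best.class_id, best.class_probs,
                               best.objectness))
    return fused


def nms(dets: list[Detection], iou_thr: float = 0.45,
        conf_thr: float = 0.25) -> list[Detection]:
    """Class-wise greedy non-maximum suppression (score then index tie-break)."""
    if not (0.0 < iou_thr < 1.0):
        raise ValueError("iou_thr must lie in (0,1)")
    survivors: list[tuple[int, Detection]] = []
    candidates = [(i, d) for i, d in enumerate(dets) if d.score >= conf_thr]
    candidates.sort(key=lambda t: (-t[1].score, t[0]))
    for cls in sorted({d.class_id for _, d in candidates}):
        kept: list[tuple[int, Detection]] = []
        for i, d in candidates:
            if d.class_id != cls:
                continue
            if all(iou(d.box, k.box) <= iou_thr for _, k in kept):
                kept.append((i, d))
        survivors.extend(kept)
    survivors.sort(key=lambda t: t[0])
    return [d for _, d in survivors]


class Neck(Module):
    """FPN top-down + PAN bottom-up fusion to a single channel width."""

    def __init__(self, in_channels: list[int], width: int,
                 rng: np.random.Generator):
        if len(in_channels) < 2:
            raise ValueError("neck needs at least two pyramid levels")
        self.laterals = [Linear(c, width, rng) for c in in_channels]
        self.td_proj = [Linear(width, width, rng) for _ in in_channels[:-1]]
        self.bu_proj = [Linear(width, width, rng) for _ in in_channels[:-1]]
        self.width = width

    def __call__(self, maps: list[Tensor]) -> list[Tensor]:
        """maps: fine -> coarse, strictly halving spatial sizes."""
        for a, b in zip(maps, maps[1:]):
            if a.shape[1] != 2 * b.shape[1] or a.shape[2] != 2 * b.shape[2]:
                raise ValueError("pyramid levels must halve in spatial size")
        lat = [l(m) for l, m in zip(self.laterals, maps)]
        # top-down: coarse information flows to finer levels
        td = [None] * len(lat)
        td[-1] = lat[-1]
        for i in range(len(lat) - 2, -1, -1):
            td[i] = self.td_proj[i](lat[i] + ad.upsample2x(td[i + 1]))
        # bottom-up: localisation detail flows back to coarser levels
        out = [None] * len(lat)
        out[0] = td[0]
        for i in range(1, len(lat)):
            out[i] = self.bu_proj[i - 1](td[i] + ad.avgpool2x(out[i - 1]))
        return out


class DetectionHead(Module):
    """Per-level predictor: width -> n_anchors * (5 + n_classes).

    With ``hidden`` > 0 a GELU hidden layer precedes the final projection."""

    def __init__(self, width: int, n_levels: int, n_anchors: int,
                 n_classes: int, rng: np.random.Generator, hidden: int = 0):
        self.n_anchors = n_anchors
        self.n_classes = n_classes
        self.hiddens = (
            [Linear(width, hidden, rng) for _ in range(n_levels)]
            if hidden > 0 else None
        )
        in_dim = hidden if hidden > 0 else width
        self.preds = [
            Linear(in_dim, n_anchors * (5 + n_classes), rng, scale=0.01)
            for _ in range(n_levels)
        ]

    def __call__(self, pyramid: list[Tensor]) -> list[Tensor]:
        """Each output has shape (B, h, w, A, 5 + K)."""
        outs = []
        for i, m in enumerate(pyramid):
            b, h, w, _ = m.shape
            if self.hiddens is not None:
                m = self.hiddens[i](m).gelu()
            outs.append(self.preds[i](m).reshape(b, h, w, self.n_anchors,
                                                 5 + self.n_classes))
        return outs


class WindowDetector:
    """Scikit-learn style single-stage detector with a window-attention backbone.

    ``fit(X, y)`` takes images (list of (H, W) float arrays in [0,1]) and
    per-image targets ``(boxes, labels)`` with half-open pixel boxes;
    ``predict(X)`` returns one list of :class:`Detection` per image.
    ``backbone_init`` may be a fitted :class:`~maskdet.reconstruction
    .MaskedAutoencoder` (or its model) whose patch projection and encoder
    blocks seed the backbone.
    """

    def __init__(
        self,
        patch_size: int = 8,
        base_channels: int = 32,
        stage_depths: tuple[int, ...] = (1, 1),
        n_heads: int = 4,
        window_size: int = 4,
        mlp_ratio: float = 2.0,
        neck_width: int = 32,
        head_hidden: int = 0,
        n_anchors: int = 3,
        epochs: int = 40,
        batch_size: int = 32,
        lr: float = 1e-4,
        lr_schedule: str = "cosine",
        weight_decay: float = 5e-4,
        dropout: float = 0.0,
        iou_weight: float = 1.0,
        cls_weight: float = 1.0,
        obj_weight: float = 1.0,
        noobj_weight: float = 0.5,
        obj_target_mode: str = "anchor_iou",
        ignore_thr: float = 0.5,
        multi_assign_thr: float | None = 0.5,
        conf_thr: float = 0.25,
        nms_iou: float = 0.45,
        box_fusion: bool = True,
        scale_mode: str = "sqrt",
        pos_embed: bool = False,
        augment_flips: bool = True,
        backbone_init=None,
        fixed_anchors: list | None = None,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.base_channels = base_channels
        self.stage_depths = tuple(stage_depths)
        self.n_heads = n_heads
        self.window_size = window_size
        self.mlp_ratio = mlp_ratio
        self.neck_width = neck_width
        self.head_hidden = head_hidden
        self.n_anchors = n_anchors
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.iou_weight = iou_weight
        self.cls_weight = cls_weight
        self.obj_weight = obj_weight
        self.noobj_weight = noobj_weight
        self.obj_target_mode = obj_target_mode
        self.ignore_thr = ignore_thr
        self.multi_assign_thr = multi_assign_thr
        self.conf_thr = conf_thr
        self.nms_iou = nms_iou
        self.box_fusion = box_fusion
        self.scale_mode = scale_mode
        self.pos_embed = pos_embed
        self.augment_flips = augment_flips
        self.backbone_init = backbone_init
        self.fixed_anchors = fixed_anchors
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self.__init__.__code__.co_varnames[1:]
                if hasattr(self, k)}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -------------------------------------------------------------------------
    @staticmethod
    def targets_from_images(images: list[AnnotatedImage]):
        return [im.pixels for im in images], [
            (im.boxes, im.labels) for im in images
        ]

    def _tokenize(self, X) -> np.ndarray:
        seqs = [patchify(np.asarray(im, dtype=float), self.patch_size)
                for im in X]
        grid = seqs[0].grid_shape
        if any(s.grid_shape != grid for s in seqs):
            raise ValueError("all images must share one size")
        self._grid = grid
        self._img_hw = seqs[0].orig_hw
        return np.stack([s.tokens for s in seqs])

    def _build(self, patch_dim: int, n_classes: int,
               rng: np.random.Generator) -> None:
        self.backbone_ = HierarchicalBackbone(
            patch_dim, self._grid, self.base_channels, self.stage_depths,
            self.n_heads, self.window_size, self.mlp_ratio, self.scale_mode,
            self.pos_embed, rng,
        )
        if self.backbone_init is not None:
            mae = getattr(self.backbone_init, "model_", self.backbone_init)
            self.backbone_.init_from_mae(mae)
        self.neck_ = Neck(self.backbone_.out_channels, self.neck_width, rng)
        self.head_ = DetectionHead(self.neck_width, len(self.stage_depths),
                                   self.n_anchors, n_classes, rng,
                                   self.head_hidden)
        self.strides_ = [self.patch_size * 2**s
                         for s in range(len(self.stage_depths))]
        h, w = self._grid
        self.grid_shapes_ = [(h // 2**s, w // 2**s)
                             for s in range(len(self.stage_depths))]

    def _flat_layout(self):
        """Flat anchor indexing: per level row-major cells, anchors innermost."""
        sizes = [gh * gw * self.n_anchors for gh, gw in self.grid_shapes_]
        return np.cumsum([0] + sizes)

    def _slot_flat_index(self, slot: AnchorSlot, offsets) -> int:
        gh, gw = self.grid_shapes_[slot.level]
        cx, cy = slot.cell
        return int(
            offsets[slot.level]
            + (cy * gw + cx) * self.n_anchors
            + slot.anchor
        )

    def _forward_raw(self, tokens: np.ndarray, rng=None,
                     training: bool = False) -> Tensor:
        """Images -> flat raw predictions (B, total_anchors, 5 + K)."""
        maps = self.backbone_(Tensor(tokens), self.dropout, rng, training)
        pyramid = self.neck_(maps)
        outs = self.head_(pyramid)
        flat = [o.reshape(o.shape[0], -1, o.shape[-1]) for o in outs]
        return ad.concatenate(flat, axis=1)

    def _decode_geometry(self):
        """Per flat anchor: cell x, cell y, prior w/h, stride (constant arrays)."""
        cells_x, cells_y, priors, strides = [], [], [], []
        for lvl, (gh, gw) in enumerate(self.grid_shapes_):
            ys, xs = np.mgrid[0:gh, 0:gw]
            cx = np.repeat(xs.reshape(-1), self.n_anchors)
            cy = np.repeat(ys.reshape(-1), self.n_anchors)
            pr = np.tile(self.anchors_[lvl], (gh * gw, 1))
            cells_x.append(cx)
            cells_y.append(cy)
            priors.append(pr)
            strides.append(np.full(gh * gw * self.n_anchors,
                                   float(self.strides_[lvl])))
        return (np.concatenate(cells_x), np.concatenate(cells_y),
                np.concatenate(priors), np.concatenate(strides))

    # -------------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, eval_every: int = 0):
        """Train; optionally evaluate AP50 on a validation set periodically."""
        from .metrics import evaluate_detections

        tokens = self._tokenize(X)
        n_imgs = len(tokens)
        if n_imgs == 0:
            raise ValueError("empty training set")
        with_boxes = [np.asarray(b, dtype=float).reshape(-1, 4)
                      for b, _ in y if len(b)]
        if not with_boxes and self.fixed_anchors is None:
            raise ValueError("no ground-truth boxes to estimate anchors from")
        all_boxes = (np.concatenate(with_boxes) if with_boxes
                     else np.zeros((0, 4)))
        n_classes = int(max((np.max(l) for _, l in y if len(l)), default=0)) + 1
        rng = np.random.default_rng(self.random_state)
        self.n_classes_ = n_classes
        if self.fixed_anchors is not None:
            self.anchors_ = [np.asarray(a, dtype=float)
                             for a in self.fixed_anchors]
        else:
            k = self.n_anchors * len(self.stage_depths)
            flat = kmeans_anchors(all_boxes, k, seed=self.random_state)
            self.anchors_ = [flat[l * self.n_anchors:(l + 1) * self.n_anchors]
                             for l in range(len(self.stage_depths))]
        self._build(tokens.shape[2], n_classes, rng)
        params = (self.backbone_.parameters() + self.neck_.parameters()
                  + self.head_.parameters())
        opt = Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        offsets = self._flat_layout()
        geo = self._decode_geometry()
        # horizontal/vertical flip augmentation: token-order and in-patch
        # pixel permutations plus flipped boxes, assignments precomputed
        tok_perms, pix_perms = self._flip_perms(tokens.shape[2])
        n_variants = self._n_aug_codes()
        y_var, assign_var = [], []
        for code in range(n_variants):
            y_f = [self._flip_targets(b, l, code) for b, l in y]
            y_var.append(y_f)
            assign_var.append([
                assign_targets(b, l, self.anchors_, self.strides_,
                               self.grid_shapes_, self.multi_assign_thr)
                for b, l in y_f
            ])
        self.loss_trace_ = []
        self.metrics_trace_ = []
        warmup = max(1, self.epochs // 10)
        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                if epoch < warmup:
                    opt.lr = self.lr * (epoch + 1) / warmup
                else:
                    opt.lr = self.lr * 0.5 * (1.0 + np.cos(
                        np.pi * (epoch - warmup) / max(self.epochs - warmup, 1)
                    ))
            order = rng.permutation(n_imgs)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_imgs, self.batch_size):
                idx = order[start:start + self.batch_size]
                codes = (rng.integers(0, n_variants, size=len(idx))
                         if self.augment_flips else np.zeros(len(idx), int))
                batch = np.stack([
                    tokens[i][tok_perms[c]][:, pix_perms[c]]
                    for i, c in zip(idx, codes)
                ])
                loss = self._batch_loss(batch,
                                        [y_var[c][i] for i, c in zip(idx, codes)],
                                        [assign_var[c][i] for i, c in zip(idx, codes)],
                                        offsets, geo, rng)
                opt.zero_grad()
                loss.backward()
                opt.step()
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"training diverged (loss={loss.item()}) at epoch {epoch}"
                    )
                epoch_loss += loss.item()
                n_batches += 1
            self.loss_trace_.append(epoch_loss / max(n_batches, 1))
            if eval_every and X_val is not None and (epoch + 1) % eval_every == 0:
                preds = self.predict(X_val)
                rep = evaluate_detections(preds, y_val)
                self.metrics_trace_.append(
                    {"epoch": epoch + 1, "ap50": rep.ap50}
                )
        return self

    def _flip_perms(self, patch_dim: int):
        """Index permutations realising the square's symmetries on patch
        tokens: bit 0 = horizontal flip, bit 1 = vertical flip, bit 2 =
        transpose (only used when image and grid are square)."""
        rows, cols = self._grid
        p = self.patch_size
        ch = patch_dim // (p * p)
        tok = np.arange(rows * cols).reshape(rows, cols)
        pix = np.arange(patch_dim).reshape(p, p, ch)
        tok_perms, pix_perms = [], []
        for code in range(self._n_aug_codes()):
            t, q = tok, pix
            if code & 4:
                t, q = t.T, q.transpose(1, 0, 2)
            if code & 1:
                t, q = t[:, ::-1], q[:, ::-1]
            if code & 2:
                t, q = t[::-1], q[::-1]
            tok_perms.append(t.reshape(-1).copy())
            pix_perms.append(q.reshape(-1).copy())
        return tok_perms, pix_perms

    def _n_aug_codes(self) -> int:
        if not self.augment_flips:
            return 1
        square = (self._grid[0] == self._grid[1]
                  and self._img_hw[0] == self._img_hw[1])
        return 8 if square else 4

    def _flip_targets(self, boxes, labels, code: int):
        boxes = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
        img_h, img_w = self._img_hw
        if code & 4:
            boxes = boxes[:, [1, 0, 3, 2]]
        if code & 1:
            boxes[:, [0, 2]] = img_w - boxes[:, [2, 0]]
        if code & 2:
            boxes[:, [1, 3]] = img_h - boxes[:, [3, 1]]
        return boxes, np.asarray(labels, dtype=int).reshape(-1)

    def _batch_loss(self, tokens, y_batch, assign_batch, offsets, geo, rng) -> Tensor:
        cells_x, cells_y, priors, strides = geo
        raw = self._forward_raw(tokens, rng, training=True)
        bsz, total, _ = raw.shape
        pos_b, pos_a, gt_boxes, gt_cls = [], [], [], []
        for bi, ((boxes, labels), slots) in enumerate(zip(y_batch, assign_batch)):
            boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
            for slot in slots:
                pos_b.append(bi)
                pos_a.append(self._slot_flat_index(slot, offsets))
                gt_boxes.append(boxes[slot.gt_index])
                gt_cls.append(int(labels[slot.gt_index]))
        obj_logits = raw[:, :, 4]
        if self.obj_target_mode == "anchor_iou":
            obj_target, soft_hot = self._static_obj_targets(y_batch, geo)
        else:
            obj_target, soft_hot = self._soft_obj_targets(raw.data, y_batch, geo)
        pos_mask = soft_hot.astype(float)
        loss = Tensor(0.0)
        if pos_b:
            pb = np.asarray(pos_b)
            pa = np.asarray(pos_a)
            gt_boxes = np.stack(gt_boxes)
            pos_raw = raw[pb, pa]                      # (P, 5+K)
            # decode differentiably (expanded centre offset)
            sx = pos_raw[:, 0].sigmoid() * 2.0 - 0.5
            sy = pos_raw[:, 1].sigmoid() * 2.0 - 0.5
            st = strides[pa]
            cx = (sx + cells_x[pa]) * st
            cy = (sy + cells_y[pa]) * st
            bw = pos_raw[:, 2].clip(-4.0, 4.0).exp() * priors[pa, 0]
            bh = pos_raw[:, 3].clip(-4.0, 4.0).exp() * priors[pa, 1]
            x0, x1 = cx - bw * 0.5, cx + bw * 0.5
            y0, y1 = cy - bh * 0.5, cy + bh * 0.5
            ix = ad.maximum(
                ad.minimum(x1, gt_boxes[:, 2]) - ad.maximum(x0, gt_boxes[:, 0]), 0.0
            )
            iy = ad.maximum(
                ad.minimum(y1, gt_boxes[:, 3]) - ad.maximum(y0, gt_boxes[:, 1]), 0.0
            )
            inter = ix * iy
            gt_area = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (
                gt_boxes[:, 3] - gt_boxes[:, 1]
            )
            union = bw * bh + gt_area - inter
            iou_t = inter / ad.maximum(union, _EPS)
            box_loss = (-(ad.maximum(iou_t, _EPS).log())).mean()
            # classification: per-class BCE on softmax probabilities
            probs = ad.softmax(pos_raw[:, 5:], axis=-1).clip(_EPS, 1 - _EPS)
            onehot = np.zeros(probs.shape)
            onehot[np.arange(len(gt_cls)), gt_cls] = 1.0
            cls_loss = (
                -(onehot * probs.log() + (1 - onehot) * (1 - probs).log())
                .sum(axis=-1).mean()
            )
            obj_target[pb, pa] = np.clip(iou_t.data, 0.0, 1.0)
            pos_mask[pb, pa] = 1.0
            loss = loss + self.iou_weight * box_loss + self.cls_weight * cls_loss
        # objectness BCE from logits: softplus(z) - t z; positives and
        # negatives normalized separately so the rare positives are not
        # drowned out by the anchor-grid background
        bce = obj_logits.softplus() - obj_logits * obj_target
        neg_mask = 1.0 - pos_mask
        obj_loss = (bce * pos_mask).sum() / max(pos_mask.sum(), 1.0) + (
            self.noobj_weight * (bce * neg_mask).sum() / max(neg_mask.sum(), 1.0)
        )
        return loss + self.obj_weight * obj_loss

    def _soft_obj_targets(self, raw: np.ndarray, y_batch, geo):
        """Soft objectness targets: every anchor whose decoded box overlaps
        some gt above ignore_thr is trained to predict that IoU (so the
        confidence ranking tracks actual box quality); the rest target 0."""
        cells_x, cells_y, priors, strides = geo
        bsz, total = raw.shape[0], raw.shape[1]
        target = np.zeros((bsz, total))
        soft = np.zeros((bsz, total), dtype=bool)
        for bi, (boxes, _labels) in enumerate(y_batch):
            boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
            if len(boxes) == 0:
                continue
            r = raw[bi]
            sx = 2 / (1 + np.exp(-r[:, 0])) - 0.5
            sy = 2 / (1 + np.exp(-r[:, 1])) - 0.5
            cx = (sx + cells_x) * strides
            cy = (sy + cells_y) * strides
            bw = priors[:, 0] * np.exp(np.clip(r[:, 2], -4, 4))
            bh = priors[:, 1] * np.exp(np.clip(r[:, 3], -4, 4))
            dec = np.stack([cx - bw / 2, cy - bh / 2,
                            cx + bw / 2, cy + bh / 2], axis=1)
            best = iou_matrix(dec, boxes).max(axis=1)
            hot = best > self.ignore_thr
            target[bi, hot] = best[hot]
            soft[bi, hot] = True
        return target, soft

    def _anchor_boxes(self, geo) -> np.ndarray:
        """Static reference boxes: each prior centered in its grid cell."""
        cells_x, cells_y, priors, strides = geo
        cx = (cells_x + 0.5) * strides
        cy = (cells_y + 0.5) * strides
        return np.stack([cx - priors[:, 0] / 2, cy - priors[:, 1] / 2,
                         cx + priors[:, 0] / 2, cy + priors[:, 1] / 2], axis=1)

    def _static_obj_targets(self, y_batch, geo):
        """Geometry-only objectness targets: the IoU each cell-centred prior
        has with its best ground truth (anchors below 0.3 are plain
        negatives).  Being stationary across training and comparable across
        images, these give the confidence ranking a stable regression
        target."""
        ab = self._anchor_boxes(geo)
        bsz, total = len(y_batch), ab.shape[0]
        target = np.zeros((bsz, total))
        for bi, (boxes, _labels) in enumerate(y_batch):
            boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
            if len(boxes) == 0:
                continue
            target[bi] = iou_matrix(ab, boxes).max(axis=1)
        hot = target >= 0.3
        target = target * hot
        return target, hot

    # -------------------------------------------------------------------------
    def predict(self, X) -> list[list[Detection]]:
        self._check_fitted()
        tokens = self._tokenize(X)
        geo = self._decode_geometry()
        cells_x, cells_y, priors, strides = geo
        img_h, img_w = self._img_hw
        results = []
        with ad.no_grad():
            for start in range(0, len(tokens), self.batch_size):
                raw = self._forward_raw(tokens[start:start + self.batch_size]).data
                for r in raw:
                    sx = 2 / (1 + np.exp(-r[:, 0])) - 0.5
                    sy = 2 / (1 + np.exp(-r[:, 1])) - 0.5
                    cx = (sx + cells_x) * strides
                    cy = (sy + cells_y) * strides
                    bw = priors[:, 0] * np.exp(np.clip(r[:, 2], -4, 4))
                    bh = priors[:, 1] * np.exp(np.clip(r[:, 3], -4, 4))
                    boxes = np.stack(
                        [np.clip(cx - bw / 2, 0, img_w),
                         np.clip(cy - bh / 2, 0, img_h),
                         np.clip(cx + bw / 2, 0, img_w),
                         np.clip(cy + bh / 2, 0, img_h)], axis=1,
                    )
                    obj = 1 / (1 + np.exp(-r[:, 4]))
                    logits = r[:, 5:] - r[:, 5:].max(axis=1, keepdims=True)
                    e = np.exp(logits)
                    probs = e / e.sum(axis=1, keepdims=True)
                    cls = probs.argmax(axis=1)
                    score = obj * probs[np.arange(len(cls)), cls]
                    keep = score >= self.conf_thr
                    dets = [
                        Detection(boxes[i], int(cls[i]), probs[i], float(obj[i]))
                        for i in np.nonzero(keep)[0]
                        if boxes[i, 0] < boxes[i, 2] and boxes[i, 1] < boxes[i, 3]
                    ]
                    if self.box_fusion:
                        dets = fuse_detections(dets, 0.3)
                    results.append(nms(dets, self.nms_iou, self.conf_thr))
        return results

    def _check_fitted(self):
        if not hasattr(self, "head_"):
            raise RuntimeError("estimator is not fitted")
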