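"""Anchor-based one-stage detection head over the pyramid features.

The head is a shared convolutional tower feeding per-level classification
(sigmoid per class) and box-regression branches.  Anchors are assigned to
ground truth by IoU (positives above ``iou_pos``, negatives below
``iou_neg``, the best anchor per ground-truth box force-matched), boxes are
regressed in the standard ``(dx, dy, log dw, log dh)`` parameterisation,
and inference applies score thresholding, clipping and per-class greedy
non-maximum suppression.

The "RCNN" naming of two-stage detectors notwithstanding, this is a
one-stage head: no proposal or RoI stage is specified anywhere in the
architecture this follows, and a single-stage head exercises every pyramid
component at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .backbone import Backbone
from .config import DetectorConfig
from .nn import Adam, Conv2d, Module
from .types import Box, CLASS_NAMES, Detection, LabeledImage, PyramidLevels

__all__ = [
    "AnchorSet", "generate_anchors", "match_anchors", "nms",
    "DetectionModel", "detect", "train_detector",
]

BOX_ENCODE_CLAMP = 4.0  # clamp on predicted log-size deltas at decode time


@dataclass
class AnchorSet:
    """Per-level anchor boxes as (N_level, 4) corner arrays."""

    per_level: list[np.ndarray]
    strides: list[int]

    @property
    def all(self) -> np.ndarray:
        return np.concatenate(self.per_level, axis=0)


def generate_anchors(levels: PyramidLevels, scales, aspects) -> AnchorSet:
    """Tile anchors over every level: one per (location, scale, aspect).

    ``scales`` holds one base size (pixels) per level; ``aspects`` are
    height/width ratios shared by all levels.  Centres sit at
    ``(i + 0.5) * stride`` — the half-pixel convention used throughout.
    """
    scales = list(np.atleast_1d(scales))
    aspects = list(np.atleast_1d(aspects))
    if len(scales) != len(levels.maps):
        raise ValueError(
            f"need one anchor scale per level ({len(levels.maps)}), "
            f"got {len(scales)}")
    if not aspects:
        raise ValueError("aspect list must be nonempty")
    per_level = []
    for fmap, stride, scale in zip(levels.maps, levels.strides, scales):
        h, w = fmap.shape[2], fmap.shape[3]
        ys = (np.arange(h) + 0.5) * stride
        xs = (np.arange(w) + 0.5) * stride
        cy, cx = np.meshgrid(ys, xs, indexing="ij")
        boxes = []
        for ar in aspects:
            bh = scale * np.sqrt(ar)
            bw = scale / np.sqrt(ar)
            boxes.append(np.stack([
                cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2,
            ], axis=-1).reshape(-1, 4))
        # interleave aspects per location to match head channel layout
        level_boxes = np.stack(boxes, axis=1).reshape(-1, 4)
        per_level.append(level_boxes)
    return AnchorSet(per_level=per_level, strides=list(levels.strides))


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU for (N,4) x (M,4) corner arrays."""
    if boxes_a.size == 0 or boxes_b.size == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    ax0, ay0, ax1, ay1 = boxes_a.T
    bx0, by0, bx1, by1 = boxes_b.T
    ix0 = np.maximum(ax0[:, None], bx0[None, :])
    iy0 = np.maximum(ay0[:, None], by0[None, :])
    ix1 = np.minimum(ax1[:, None], bx1[None, :])
    iy1 = np.minimum(ay1[:, None], by1[None, :])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = ((ax1 - ax0) * (ay1 - ay0))[:, None]
    area_b = ((bx1 - bx0) * (by1 - by0))[None, :]
    return inter / (area_a + area_b - inter)


def encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Regression targets (dx, dy, dw, dh) of gt relative to anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack([
        (gcx - acx) / aw, (gcy - acy) / ah, np.log(gw / aw), np.log(gh / ah),
    ], axis=1)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    d = np.clip(deltas, -BOX_ENCODE_CLAMP, BOX_ENCODE_CLAMP)
    cx = acx + d[:, 0] * aw
    cy = acy + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


@dataclass
class AnchorTargets:
    """Per-anchor assignment: class index (-1 = background), regression
    targets, and a mask (1 positive, 0 negative, -1 ignored)."""

    class_index: np.ndarray        # (N,) int, -1 for background
    regression: np.ndarray         # (N, 4)
    mask: np.ndarray               # (N,) int in {1, 0, -1}


def match_anchors(anchors: np.ndarray, gt_boxes: np.ndarray,
                  gt_classes: np.ndarray, iou_pos: float = 0.5,
                  iou_neg: float = 0.4) -> AnchorTargets:
    """IoU assignment with force-matching of the best anchor per GT box."""
    if iou_neg > iou_pos:
        raise ValueError("iou_neg must not exceed iou_pos")
    n = len(anchors)
    class_index = np.full(n, -1, dtype=int)
    regression = np.zeros((n, 4))
    if len(gt_boxes) == 0:
        return AnchorTargets(class_index, regression, np.zeros(n, dtype=int))
    ious = iou_matrix(anchors, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]
    mask = np.full(n, -1, dtype=int)
    mask[best_iou <= iou_neg] = 0
    pos = best_iou >= iou_pos
    # every GT gets at least one positive: its highest-IoU anchor
    force = ious.argmax(axis=0)
    pos[force] = True
    best_gt[force] = np.arange(len(gt_boxes))
    mask[pos] = 1
    class_index[pos] = gt_classes[best_gt[pos]]
    regression[pos] = encode_boxes(anchors[pos], gt_boxes[best_gt[pos]])
    return AnchorTargets(class_index, regression, mask)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices.

    Ties in score are broken by input order (earlier wins), making results
    deterministic.
    """
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        ious = iou_matrix(boxes[idx:idx + 1], boxes).ravel()
        suppressed |= ious > iou_thresh
        suppressed[idx] = True
    return np.array(keep, dtype=int)


class DetectionModel(Module):
    """Backbone + shared tower + class/box branches."""

    def __init__(self, cfg: DetectorConfig, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.backbone = Backbone(
            in_channels=in_channels, stem_channels=cfg.stem_channels,
            body_widths=cfg.body_widths, body_depths=cfg.body_depths,
            pyramid_channels=cfg.pyramid_channels,
            second_pass_direction=cfg.second_pass_direction, rng=rng)
        n_aspects = len(cfg.anchor_aspects)
        k = len(CLASS_NAMES)
        self.tower = Conv2d(cfg.pyramid_channels, cfg.head_channels, 3,
                            padding=1, rng=rng)
        self.cls_head = Conv2d(cfg.head_channels, n_aspects * k, 3,
                               padding=1, rng=rng)
        self.box_head = Conv2d(cfg.head_channels, n_aspects * 4, 3,
                               padding=1, rng=rng)
        # prior-probability bias so initial class scores are low (focal init)
        if self.cls_head.bias is not None:
            self.cls_head.bias.data[...] = -np.log((1 - 0.01) / 0.01)
        self.n_aspects = n_aspects
        self.n_classes = k

    def forward(self, x: Tensor):
        """Returns (levels, cls_logits (B,N,K), box_deltas (B,N,4))."""
        levels = self.backbone(x)
        cls_all, box_all = [], []
        b = x.shape[0]
        for fmap in levels.maps:
            t = self.tower(fmap).relu()
            cls = self.cls_head(t)          # (B, A*K, H, W)
            box = self.box_head(t)          # (B, A*4, H, W)
            h, w = cls.shape[2], cls.shape[3]
            cls = cls.reshape(b, self.n_aspects, self.n_classes, h, w) \
                .transpose(0, 3, 4, 1, 2).reshape(b, h * w * self.n_aspects,
                                                  self.n_classes)
            box = box.reshape(b, self.n_aspects, 4, h, w) \
                .transpose(0, 3, 4, 1, 2).reshape(b, h * w * self.n_aspects, 4)
            cls_all.append(cls)
            box_all.append(box)
        return levels, concatenate(cls_all, axis=1), concatenate(box_all, axis=1)

    def anchors_for(self, levels: PyramidLevels) -> AnchorSet:
        return generate_anchors(levels, self.cfg.anchor_scales,
                                self.cfg.anchor_aspects)


def _detection_loss(model: DetectionModel, cls_logits: Tensor,
                    box_deltas: Tensor, targets: list[AnchorTargets]):
    """Focal/BCE classification + smooth-L1 regression over matched anchors."""
    cfg = model.cfg
    b, n, k = cls_logits.shape
    onehot = np.zeros((b, n, k))
    cls_mask = np.zeros((b, n, 1))
    box_mask = np.zeros((b, n, 1))
    box_tgt = np.zeros((b, n, 4))
    n_pos = 0
    for i, t in enumerate(targets):
        valid = t.mask >= 0
        cls_mask[i, valid, 0] = 1.0
        pos = t.mask == 1
        onehot[i, pos, :] = np.eye(k)[t.class_index[pos]]
        box_mask[i, pos, 0] = 1.0
        box_tgt[i, pos] = t.regression[pos]
        n_pos += int(pos.sum())
    norm = max(n_pos, 1)
    y = Tensor(onehot)
    # stable BCE-with-logits: softplus(x) - x*y
    bce = cls_logits.softplus() - cls_logits * y
    if cfg.loss == "focal":
        p = cls_logits.sigmoid()
        p_t = p * y + (1.0 - p) * (1.0 - y)
        alpha_t = cfg.focal_alpha * onehot + (1 - cfg.focal_alpha) * (1 - onehot)
        focal = ((1.0 - p_t) ** cfg.focal_gamma) * alpha_t * bce
        cls_loss = (focal * cls_mask).sum() / norm
    else:
        cls_loss = (bce * cls_mask).sum() / norm
    reg = ((box_deltas - box_tgt).smooth_l1(1.0 / 9.0) * box_mask).sum() / norm
    return cls_loss + reg, n_pos


def detect(model: DetectionModel, image: np.ndarray, image_id: str = "img",
           score_thresh: float | None = None,
           nms_iou: float | None = None) -> list[Detection]:
    """Run inference on one grey image -> sorted, NMS-filtered detections."""
    cfg = model.cfg
    score_thresh = cfg.score_thresh if score_thresh is None else score_thresh
    nms_iou = cfg.nms_iou if nms_iou is None else nms_iou
    model.eval()
    x = Tensor(image[None, None, :, :])
    levels, cls_logits, box_deltas = model(x)
    anchors = model.anchors_for(levels).all
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))     # (N, K)
    deltas = box_deltas.data[0]
    h, w = image.shape
    out: list[Detection] = []
    for ci, cname in enumerate(CLASS_NAMES):
        sel = scores[:, ci] >= score_thresh
        if not sel.any():
            continue
        boxes = decode_boxes(anchors[sel], deltas[sel])
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
        boxes, s = boxes[ok], scores[sel, ci][ok]
        keep = nms(boxes, s, nms_iou)[:cfg.max_detections]
        for j in keep:
            out.append(Detection(
                image_id=image_id, class_name=cname,
                box=Box(*boxes[j]), confidence=float(s[j])))
    out.sort(key=lambda d: -d.confidence)
    return out


def train_detector(dataset: list[LabeledImage], cfg: DetectorConfig,
                   seed: int = 0, steps: int | None = None,
                   model: DetectionModel | None = None):
    """Train the one-stage detector; returns (model, per-step losses).

    Deterministic given ``seed``: initialisation, batching order and every
    arithmetic step derive from one ``default_rng``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    if model is None:
        model = DetectionModel(cfg, rng=rng)
    steps = cfg.steps if steps is None else steps
    model.train()

    # pre-compute anchors and targets once per image (fixed image size)
    probe = Tensor(dataset[0].pixels[None, None])
    levels, _, _ = model(probe)
    anchor_set = model.anchors_for(levels)
    anchors = anchor_set.all
    class_to_idx = {c: i for i, c in enumerate(CLASS_NAMES)}
    targets = []
    any_pos = False
    for img in dataset:
        gt = np.array([g.box.as_array() for g in img.boxes]).reshape(-1, 4)
        gc = np.array([class_to_idx[g.class_name] for g in img.boxes], dtype=int)
        t = match_anchors(anchors, gt, gc, cfg.iou_pos, cfg.iou_neg)
        any_pos = any_pos or (t.mask == 1).any()
        targets.append(t)
    if not any_pos:
        raise ValueError(
            "no anchor matched any ground-truth box; rescale anchor_scales / "
            "anchor_aspects toward the target box sizes")

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    losses = []
    n = len(dataset)
    order = rng.permutation(n)
    cursor = 0
    for _ in range(steps):
        if cursor + cfg.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + cfg.batch_size]
        cursor += cfg.batch_size
        batch = np.stack([dataset[i].pixels for i in idx])[:, None]
        _, cls_logits, box_deltas = model(Tensor(batch))
        loss, _ = _detection_loss(model, cls_logits, box_deltas,
                                  [targets[i] for i in idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    model.eval()
    return model, losses
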