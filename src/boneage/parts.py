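"""Attention-driven bone-part proposal: stretch, anchor scoring, NMS, crops.

The predicted-class activation channel, resized to a square working frame
(576 x 576 by default), is contrast-stretched

    S = z(exp(eta * z(A_c))),      z(x) = (x - min x) / (max x - min x)

so that local peaks dominate their surroundings (larger ``eta`` = stronger
stretching).  A dense lattice of anchor boxes (3 aspect ratios x 5 scales) is
scored by the mean of ``S`` inside each box, overlapping candidates are
removed by greedy non-maximum suppression, and the top-N survivors are cropped
from the hand image and resampled to 288 x 288.  Scoring by mean activation
replaces a learned objectness head: no part-level annotation is ever used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .localization import RoIBox, minmax_normalize, resize_bilinear

__all__ = [
    "AnchorConfig", "ScoredRegion", "minmax_normalize", "stretch_map",
    "generate_anchors", "score_regions", "nms", "top_n_parts", "extract_parts",
]

#: the square frame the activation map is resized to before anchoring
CANONICAL_FRAME = 576


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor lattice: aspect ratios (w:h), scales (box side, px), grid stride.

    Scales and stride are expressed in the 576 x 576 canonical frame and are
    rescaled proportionally when anchors are generated on a smaller map.
    """

    ratios: tuple[float, ...] = (2 / 3, 1.0, 3 / 2)
    scales: tuple[int, ...] = (128, 160, 224, 288, 384)
    stride: int = 32

    @property
    def anchors_per_point(self) -> int:
        return len(self.ratios) * len(self.scales)


@dataclass(frozen=True)
class ScoredRegion:
    box: RoIBox
    score: float


def stretch_map(channel: np.ndarray, eta: float) -> np.ndarray:
    """Contrast-stretch an activation channel into [0, 1].

    ``S = z(exp(eta * z(channel)))`` with ``z`` the min-max normaliser; the
    transform is monotone, so the peak location is preserved, while larger
    ``eta`` suppresses mid-range values relative to the peak.
    """
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    return minmax_normalize(np.exp(eta * minmax_normalize(channel)))


def generate_anchors(map_hw: tuple[int, int], cfg: AnchorConfig | None = None
                     ) -> list[RoIBox]:
    """Enumerate anchor boxes on a stride-spaced lattice over the map.

    Each lattice point emits one box per (ratio, scale) pair, centered there,
    with area ``scale**2`` and width/height ratio as configured.  Boxes that
    would extend outside the map are discarded, never clipped, so every later
    mean-activation score is computed on a full box.
    """
    cfg = cfg or AnchorConfig()
    h, w = map_hw
    rescale = min(h, w) / CANONICAL_FRAME
    stride = max(1, int(round(cfg.stride * rescale)))
    boxes: list[RoIBox] = []
    for cy in range(stride // 2, h, stride):
        for cx in range(stride // 2, w, stride):
            for ratio in cfg.ratios:
                for scale in cfg.scales:
                    side = scale * rescale
                    # area = side^2, width/height = ratio
                    bw = side * np.sqrt(ratio)
                    bh = side / np.sqrt(ratio)
                    x0 = int(round(cx - bw / 2))
                    y0 = int(round(cy - bh / 2))
                    x1 = int(round(cx + bw / 2))
                    y1 = int(round(cy + bh / 2))
                    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                        continue
                    boxes.append(RoIBox(x0, y0, x1, y1, frame="activation-grid"))
    return boxes


def _integral_image(values: np.ndarray) -> np.ndarray:
    ii = np.zeros((values.shape[0] + 1, values.shape[1] + 1))
    ii[1:, 1:] = values.cumsum(axis=0).cumsum(axis=1)
    return ii


def score_regions(stretched: np.ndarray, boxes: list[RoIBox]) -> list[ScoredRegion]:
    """Score each box by the mean of the stretched map under it.

    Uses a summed-area table, which is exact for box sums (no approximation).
    """
    stretched = np.asarray(stretched, dtype=float)
    ii = _integral_image(stretched)
    regions = []
    for b in boxes:
        if b.area <= 0:
            raise ValueError(f"empty box {b}")
        total = ii[b.y1, b.x1] - ii[b.y0, b.x1] - ii[b.y1, b.x0] + ii[b.y0, b.x0]
        regions.append(ScoredRegion(box=b, score=float(total / b.area)))
    return regions


def iou(a: RoIBox, b: RoIBox) -> float:
    """Intersection-over-union of two half-open boxes."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def nms(regions: list[ScoredRegion], iou_threshold: float = 0.25
        ) -> list[ScoredRegion]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining region and drops every
    region overlapping it with IoU above the threshold.  Ties in score break
    toward the earlier region (stable sort).  Output is in descending score.
    """
    if not regions:
        return []
    n = len(regions)
    x0 = np.array([r.box.x0 for r in regions], dtype=float)
    y0 = np.array([r.box.y0 for r in regions], dtype=float)
    x1 = np.array([r.box.x1 for r in regions], dtype=float)
    y1 = np.array([r.box.y1 for r in regions], dtype=float)
    areas = (x1 - x0) * (y1 - y0)
    scores = np.array([r.score for r in regions])
    # descending score, earlier index first on ties
    order = np.lexsort((np.arange(n), -scores))
    suppressed = np.zeros(n, dtype=bool)
    kept: list[ScoredRegion] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append(regions[i])
        ix = np.minimum(x1[i], x1) - np.maximum(x0[i], x0)
        iy = np.minimum(y1[i], y1) - np.maximum(y0[i], y0)
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        overlap = inter / (areas[i] + areas - inter)
        suppressed |= overlap > iou_threshold
        suppressed[i] = True  # already kept; never revisited
    return kept


def top_n_parts(regions: list[ScoredRegion], n: int) -> list[ScoredRegion]:
    """First ``n`` regions by descending score (the NMS survivors' order).

    Fewer than ``n`` survivors are returned as-is with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(regions, key=lambda r: -r.score)
    if len(ordered) < n:
        warnings.warn(f"only {len(ordered)} regions available, requested {n}",
                      stacklevel=2)
        return ordered
    return ordered[:n]


def extract_parts(
    image: np.ndarray,
    regions: list[ScoredRegion],
    out_size: tuple[int, int] = (288, 288),
) -> list[np.ndarray]:
    """Crop each scored region from the hand image, resampled to ``out_size``.

    Regions are expected in the image's own frame; out-of-bounds regions are
    clamped with a warning.  ``out_size`` is (width, height).
    """
    from .localization import crop_and_resize

    return [crop_and_resize(image, r.box, out_size) for r in regions]


def save_regions_csv(regions: list[ScoredRegion], path) -> None:
    """Debug dump: one ``part_index, x0, y0, x1, y1, score`` row per region."""
    with open(path, "w") as f:
        f.write("part_index,x0,y0,x1,y1,score\n")
        for i, r in enumerate(regions):
            f.write(f"{i},{r.box.x0},{r.box.y0},{r.box.x1},{r.box.y1},"
                    f"{r.score:.6f}\n")


def _nms_indices(coords: np.ndarray, scores: np.ndarray, iou_threshold: float
                 ) -> list[int]:
    """Greedy-NMS survivor indices (descending score, earlier index on ties)."""
    n = len(scores)
    x0, y0, x1, y1 = coords.T.astype(float)
    areas = (x1 - x0) * (y1 - y0)
    order = np.lexsort((np.arange(n), -scores))
    suppressed = np.zeros(n, dtype=bool)
    kept: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append(int(i))
        ix = np.minimum(x1[i], x1) - np.maximum(x0[i], x0)
        iy = np.minimum(y1[i], y1) - np.maximum(y0[i], y0)
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        suppressed |= inter / (areas[i] + areas - inter) > iou_threshold
        suppressed[i] = True
    return kept


@lru_cache(maxsize=16)
def _cached_anchors(map_hw: tuple[int, int], cfg: AnchorConfig
                    ) -> tuple[tuple[RoIBox, ...], np.ndarray]:
    """Anchor lattice is static per (map size, config); cache boxes + coords."""
    boxes = tuple(generate_anchors(map_hw, cfg))
    coords = np.array([[b.x0, b.y0, b.x1, b.y1] for b in boxes], dtype=np.intp)
    return boxes, coords


def propose_parts(
    channel: np.ndarray,
    eta: float = 4.0,
    n_parts: int = 4,
    iou_threshold: float = 0.25,
    frame: int = CANONICAL_FRAME,
    cfg: AnchorConfig | None = None,
) -> tuple[list[ScoredRegion], np.ndarray]:
    """Full proposal chain on one activation channel.

    Resizes the channel to ``frame x frame`` (bilinear), stretches it, scores
    the anchor lattice by mean stretched activation, suppresses overlaps, and
    returns the top-N regions (boxes in the resized frame) together with the
    stretched map.  Vectorised; semantics identical to composing
    :func:`generate_anchors`, :func:`score_regions`, :func:`nms`,
    :func:`top_n_parts`.
    """
    resized = resize_bilinear(np.asarray(channel, dtype=float), (frame, frame))
    stretched = stretch_map(resized, eta)
    boxes, coords = _cached_anchors((frame, frame), cfg or AnchorConfig())
    ii = _integral_image(stretched)
    x0, y0, x1, y1 = coords.T
    sums = ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]
    scores = sums / ((x1 - x0) * (y1 - y0))
    kept = _nms_indices(coords, scores, iou_threshold)
    survivors = [ScoredRegion(box=boxes[i], score=float(scores[i])) for i in kept]
    return top_n_parts(survivors, n_parts), stretched
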