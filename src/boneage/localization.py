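"""Hand object location from class activation maps (weak localization).

A backbone feature map ``F`` (H x W x K) is projected by a bias-free 1x1
convolution into per-class activations ``A`` (H x W x C), one channel per
monthly age bin.  Global average pooling of ``A`` gives class scores whose
softmax is the predicted age distribution, so the activation channel of the
predicted class marks the pixels that drove the prediction.  Thresholding the
min-max-normalised channel at ``tau`` yields a binary mask whose largest
connected component bounds the hand; the box is rescaled to image pixels and
the crop resampled to the working resolution.

No box supervision is involved anywhere: localization is a by-product of the
classification head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RoIBox:
    """Axis-aligned box, 0-based, half-open: ``[x0, x1) x [y0, y1)``.

    ``frame`` names the coordinate frame ("activation-grid" or "source-image").
    """

    x0: int
    y0: int
    x1: int
    y1: int
    frame: str = "activation-grid"

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def scaled(self, sy: float, sx: float, frame: str) -> "RoIBox":
        """Rescale into another frame, rounding outward to keep coverage."""
        return RoIBox(
            x0=int(np.floor(self.x0 * sx)),
            y0=int(np.floor(self.y0 * sy)),
            x1=int(np.ceil(self.x1 * sx)),
            y1=int(np.ceil(self.y1 * sy)),
            frame=frame,
        )

    def clipped(self, height: int, width: int) -> "RoIBox":
        b = replace(
            self,
            x0=max(0, min(self.x0, width - 1)),
            y0=max(0, min(self.y0, height - 1)),
            x1=max(1, min(self.x1, width)),
            y1=max(1, min(self.y1, height)),
        )
        return b


@dataclass
class BinaryMask:
    """Thresholded activation mask; ``degenerate`` flags a constant channel."""

    values: np.ndarray  # H x W of {0, 1}
    tau: float
    degenerate: bool = False


def project_features(features: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """1x1 convolution without bias: ``A[i,j,c] = sum_k W[k,c] * F[i,j,k]``.

    Parameters
    ----------
    features : H x W x K array.
    weights : K x C array.
    """
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.ndim != 3 or weights.ndim != 2:
        raise ValueError("features must be HxWxK and weights KxC")
    if features.shape[2] != weights.shape[0]:
        raise ValueError(
            f"channel mismatch: F has K={features.shape[2]}, W has K={weights.shape[0]}"
        )
    return features @ weights


def global_pool(activation: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel spatial mean of an H x W x C map."""
    activation = np.asarray(activation, dtype=float)
    if activation.ndim != 3:
        raise ValueError("activation must be HxWxC")
    return activation.mean(axis=(0, 1))


def softmax_probs(scores: np.ndarray) -> np.ndarray:
    """Numerically safe softmax (max-subtracted) over the class axis."""
    scores = np.asarray(scores, dtype=float)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def select_channel(probs: np.ndarray) -> int:
    """Index of the most probable class; ties break toward the lower index."""
    return int(np.argmax(probs))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map an array affinely onto [0, 1]; a constant array maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def make_mask(channel: np.ndarray, tau: float = 0.6) -> BinaryMask:
    """Binary RoI mask: min-max normalise the channel, then threshold at ``tau``.

    A smaller ``tau`` grows the RoI.  A constant channel cannot be normalised;
    it yields an all-zero mask flagged ``degenerate`` (with a warning).
    """
    if not (0 < tau < 1):
        raise ValueError(f"tau must be in (0,1), got {tau}")
    channel = np.asarray(channel, dtype=float)
    if channel.min() == channel.max():
        warnings.warn("constant activation channel: mask is empty", stacklevel=2)
        return BinaryMask(np.zeros(channel.shape, dtype=np.uint8), tau, degenerate=True)
    norm = minmax_normalize(channel)
    return BinaryMask((norm >= tau).astype(np.uint8), tau)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def mask_to_box(mask: BinaryMask) -> RoIBox | None:
    """Tight bounding box of the largest 8-connected component of the mask.

    Returns ``None`` for an empty mask (callers fall back to the full image).
    Equal-sized components tie-break toward the first in scan order.
    """
    values = np.asarray(mask.values)
    if not values.any():
        return None
    labeled, n = ndimage.label(values, structure=_EIGHT_CONNECTED)
    sizes = ndimage.sum_labels(values, labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax keeps the lowest label on ties
    ys, xs = np.nonzero(labeled == best)
    return RoIBox(
        x0=int(xs.min()), y0=int(ys.min()),
        x1=int(xs.max()) + 1, y1=int(ys.max()) + 1,
        frame="activation-grid",
    )


def resize_bilinear(image: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resample with half-pixel centers and edge clamping."""
    image = np.asarray(image, dtype=float)
    in_h, in_w = image.shape
    out_h, out_w = out_hw
    ys = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    grid = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(image, grid, order=1, mode="nearest")


def crop_and_resize(
    image: np.ndarray,
    box: RoIBox,
    out_size: tuple[int, int] = (576, 576),
) -> np.ndarray:
    """Crop ``box`` (source-image frame) and bilinearly resample to ``out_size``.

    ``out_size`` is (width, height).  A box reaching outside the image is
    clamped to it, with a warning.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if box.x0 < 0 or box.y0 < 0 or box.x1 > w or box.y1 > h:
        warnings.warn(f"box {box} exceeds image bounds {h}x{w}; clamping", stacklevel=2)
        box = box.clipped(h, w)
    crop = image[box.y0:box.y1, box.x0:box.x1]
    out_w, out_h = out_size
    return resize_bilinear(crop, (out_h, out_w))


def save_heatmap(channel: np.ndarray, image_hw: tuple[int, int],
                 path) -> None:
    """Dump a normalised activation channel as an 8-bit grayscale PNG.

    The channel is min-max normalised and nearest-neighbour upscaled to the
    source image size, for eyeballing what drove a prediction.
    """
    from PIL import Image

    norm = minmax_normalize(np.asarray(channel, dtype=float))
    h, w = image_hw
    ys = (np.arange(h) * norm.shape[0] // h).clip(0, norm.shape[0] - 1)
    xs = (np.arange(w) * norm.shape[1] // w).clip(0, norm.shape[1] - 1)
    up = norm[np.ix_(ys, xs)]
    Image.fromarray((up * 255).astype(np.uint8)).save(path)


def activation_to_image_box(
    box: RoIBox, map_hw: tuple[int, int], image_hw: tuple[int, int]
) -> RoIBox:
    """Rescale an activation-grid box into source-image pixels."""
    sy = image_hw[0] / map_hw[0]
    sx = image_hw[1] / map_hw[1]
    return box.scaled(sy, sx, frame="source-image").clipped(*image_hw)
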