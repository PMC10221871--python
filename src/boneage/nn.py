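"""Compact NumPy convolutional backbone with manual backpropagation.

The classification head of the pipeline is a bias-free 1x1 projection from
backbone features to one channel per monthly age bin, followed by global
average pooling and a softmax — the class-activation-map construction, so the
same head both predicts the age distribution and localises the evidence.

The backbone is pluggable: anything exposing ``forward``/``backward``/
``params`` with a declared channel count works.  The bundled
:class:`TinyBackbone` (4 strided 3x3 conv + ReLU blocks, x16 downsampling,
32 output channels) is sized for CPU training on small images; a large
pretrained network can be substituted through the same interface.

Everything here operates on a single image at a time ((H, W) grayscale in,
(H', W', K) features out); minibatching is done by accumulating gradients
across images before an optimiser step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import N_BINS


def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, tuple[int, int]]:
    """(C, H, W) -> (C*k*k, oh*ow) patch matrix."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (C, oh, ow, k, k)
    oh, ow = windows.shape[1], windows.shape[2]
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, oh * ow)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, int, int], k: int,
            stride: int, pad: int, out_hw: tuple[int, int]) -> np.ndarray:
    c, h, w = x_shape
    oh, ow = out_hw
    dxp = np.zeros((c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(c, k, k, oh, ow)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki:ki + oh * stride:stride, kj:kj + ow * stride:stride] += d[:, ki, kj]
    if pad:
        return dxp[:, pad:-pad, pad:-pad]
    return dxp


class Conv2d:
    """3x3 (or kxk) convolution with bias; stores grads for minibatch SGD."""

    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_c * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, in_c * k * k))
        self.b = np.zeros(out_c)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_c = in_c
        self.zero_grad()
        self._cache = None

    def zero_grad(self):
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        out = (self.w @ cols + self.b[:, None]).reshape(-1, oh, ow)
        self._cache = (cols, x.shape, (oh, ow))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, out_hw = self._cache
        flat = dout.reshape(dout.shape[0], -1)
        self.dw += flat @ cols.T
        self.db += flat.sum(axis=1)
        dcols = self.w.T @ flat
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class InstanceNorm:
    """Per-channel spatial standardisation (no learned affine).

    Keeps inter-image feature differences from being swamped by the large
    shared component every image produces — the role batch normalisation
    plays in full-size backbones, without cross-image state.
    """

    eps = 1e-5

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        std = np.sqrt(x.var(axis=(1, 2), keepdims=True) + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std)
        return xhat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        return (dout - dout.mean(axis=(1, 2), keepdims=True)
                - xhat * (dout * xhat).mean(axis=(1, 2), keepdims=True)) / std


class TinyBackbone:
    """Four strided conv -> instance-norm -> ReLU blocks: 1 -> 8 -> 16 -> 24 -> 32.

    Spatial downsampling x16; a 96x96 input yields a 6x6x32 feature map.
    """

    out_channels = 32
    downsample = 16

    def __init__(self, rng: np.random.Generator, normalize: bool = True):
        chans = [1, 8, 16, 24, 32]
        self.layers = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            self.layers.append(Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng))
            if normalize:
                self.layers.append(InstanceNorm())
            self.layers.append(ReLU())

    def forward(self, image: np.ndarray) -> np.ndarray:
        """(H, W) grayscale in [0,1] -> (H', W', K) feature map."""
        x = np.asarray(image, dtype=float)[None]
        for layer in self.layers:
            x = layer.forward(x)
        return x.transpose(1, 2, 0)  # -> (H', W', K)

    def backward(self, dfeatures: np.ndarray) -> None:
        dx = dfeatures.transpose(2, 0, 1)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    def zero_grad(self):
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                layer.zero_grad()

    @property
    def params(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                out.extend(layer.params)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        i = 0
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                out[f"conv{i}_w"] = layer.w
                out[f"conv{i}_b"] = layer.b
                i += 1
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                layer.w = arrays[f"conv{i}_w"].copy()
                layer.b = arrays[f"conv{i}_b"].copy()
                i += 1


@dataclass
class HeadOutputs:
    """One branch forward pass: features, activation map, scores, probabilities."""

    features: np.ndarray    # (H', W', K)
    activation: np.ndarray  # (H', W', C)
    scores: np.ndarray      # (C,)
    probs: np.ndarray       # (C,)


class CAMModel:
    """Shared backbone + bias-free 1x1 projection head over ``N_BINS`` classes."""

    def __init__(self, rng: np.random.Generator, n_bins: int = N_BINS,
                 backbone: TinyBackbone | None = None):
        self.backbone = backbone or TinyBackbone(rng)
        k = self.backbone.out_channels
        self.w_head = rng.normal(0.0, np.sqrt(1.0 / k), size=(k, n_bins))
        self.dw_head = np.zeros_like(self.w_head)
        self.n_bins = n_bins

    def forward(self, image: np.ndarray) -> HeadOutputs:
        from .localization import global_pool, project_features, softmax_probs

        features = self.backbone.forward(image)
        activation = project_features(features, self.w_head)
        scores = global_pool(activation)
        probs = softmax_probs(scores)
        return HeadOutputs(features, activation, scores, probs)

    def backward(self, out: HeadOutputs, dprobs: np.ndarray) -> None:
        """Backprop from dL/dprobs through softmax, pooling, projection, backbone.

        Must be called immediately after the matching :meth:`forward` (conv
        caches hold that pass's activations).
        """
        p = out.probs
        dscores = p * (dprobs - float(p @ dprobs))  # softmax Jacobian-vector
        h, w, _ = out.features.shape
        # GAP spreads dscores uniformly; head grad collapses to an outer product
        fmean = out.features.mean(axis=(0, 1))  # (K,)
        self.dw_head += np.outer(fmean, dscores)
        dfeat_vec = self.w_head @ dscores / (h * w)  # (K,), same at every pixel
        dfeatures = np.broadcast_to(dfeat_vec, (h, w, dfeat_vec.size)).copy()
        self.backbone.backward(dfeatures)

    def zero_grad(self):
        self.backbone.zero_grad()
        self.dw_head[:] = 0.0

    @property
    def params(self):
        return self.backbone.params + [(self.w_head, self.dw_head)]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = self.backbone.state_arrays()
        out["w_head"] = self.w_head
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        self.backbone.load_state(arrays)
        self.w_head = arrays["w_head"].copy()
        self.dw_head = np.zeros_like(self.w_head)


class MomentumSGD:
    """SGD with classical momentum and stepwise learning-rate decay."""

    def __init__(self, model: CAMModel, lr: float = 1e-3, momentum: float = 0.9,
                 decay_every: int = 30, decay_factor: float = 0.1,
                 head_lr_mult: float = 1.0):
        self.model = model
        self.base_lr = lr
        self.momentum = momentum
        self.decay_every = decay_every
        self.decay_factor = decay_factor
        # the projection head must grow much larger weights than the convs to
        # sharpen 240-bin softmax outputs; give it its own lr scale
        self.head_lr_mult = head_lr_mult
        self.velocities = [np.zeros_like(w) for w, _ in model.params]
        self._lr_scales = self._per_param_scales()

    def _per_param_scales(self) -> list[float]:
        params = self.model.params
        heads = {id(getattr(m, "dw_head", None))
                 for m in getattr(self.model, "unique", [self.model])}
        return [self.head_lr_mult if id(g) in heads else 1.0
                for _, g in params]

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch (decayed every ``decay_every``)."""
        return self.base_lr * self.decay_factor ** ((epoch - 1) // self.decay_every)

    def step(self, epoch: int, scale: float = 1.0) -> None:
        """One update from the accumulated gradients (scaled e.g. by 1/batch)."""
        lr = self.lr_at(epoch)
        for (w, g), v, s in zip(self.model.params, self.velocities,
                                self._lr_scales):
            v *= self.momentum
            v -= lr * s * scale * g
            w += v
        self.model.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"vel{i}": v for i, v in enumerate(self.velocities)}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        self.velocities = [arrays[f"vel{i}"].copy()
                           for i in range(len(self.velocities))]
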