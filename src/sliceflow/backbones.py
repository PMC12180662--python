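"""Backbone adapters: pluggable 2D feature extractors with tapped layers.

Two adapters are provided:

* ``TinyCNNAdapter`` — a small seeded CNN pyramid meant for CPU-scale runs and
  tests; it is trainable (used by the encoder-decoder fine-tuning stage).
* ``WideResNet50Adapter`` — the wide 50-layer residual network (width factor
  2) whose ImageNet-pretrained variant is the reference extractor at full
  scale. Weights are randomly initialized unless a ``.npz`` weights file is
  supplied; the architecture itself (channel/stride layout and the 68.88M
  parameter count) is what the package depends on.

Adapters declare per-tap channel counts and strides so downstream code can do
shape arithmetic without running a forward pass.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "BackboneAdapter",
    "TinyCNNAdapter",
    "WideResNet50Adapter",
    "wide_resnet50_parameter_count",
    "get_backbone",
]


class BackboneAdapter:
    """Interface: tapped intermediate feature maps of a 2D CNN."""

    name: str = "base"
    in_channels: int = 3
    tap_layers: tuple[int, ...] = (2, 3)
    channels: dict[int, int] = {}
    strides: dict[int, int] = {}
    frozen: bool = True

    def feature_shape(self, layer: int, hw: tuple[int, int]) -> tuple[int, int, int]:
        """(C, H_l, W_l) for an input of spatial size hw, by stride arithmetic."""
        s = self.strides[layer]
        return (self.channels[layer], hw[0] // s, hw[1] // s)

    def min_input_size(self) -> int:
        return max(self.strides[l] for l in self.tap_layers)

    def extract(self, img: np.ndarray) -> dict[int, np.ndarray]:
        """Evaluation-mode forward; img is (H, W), (C, H, W) or (N, C, H, W)."""
        x = self._prepare(img)
        if min(x.shape[2], x.shape[3]) < self.min_input_size():
            raise ValueError(
                f"input spatial size {x.shape[2:]} too small for the deepest tap; "
                f"minimum is {self.min_input_size()}x{self.min_input_size()}"
            )
        feats = self.forward_tensors(Tensor(x))
        out = {l: feats[l].data for l in self.tap_layers}
        if img.ndim < 4:  # drop the synthetic batch axis
            out = {l: v[0] for l, v in out.items()}
        return out

    def forward_tensors(self, x: Tensor) -> dict[int, Tensor]:
        raise NotImplementedError

    def _prepare(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 2:  # grayscale slice -> replicate to the expected channels
            img = np.repeat(img[None, :, :], self.in_channels, axis=0)
        if img.ndim == 3:
            if img.shape[0] == 1:
                img = np.repeat(img, self.in_channels, axis=0)
            img = img[None]
        if img.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {img.shape[1]}")
        return img


def _he_conv(rng: np.random.Generator, o: int, c: int, k: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(o, c, k, k))


class TinyCNNAdapter(BackboneAdapter):
    """Small conv+ReLU pyramid; taps at layers 1-3 with strides 2/4/8."""

    name = "tiny"
    channels = {1: 16, 2: 32, 3: 64}
    strides = {1: 2, 2: 4, 3: 8}
    _layer_strides = (2, 1, 2, 2)  # stem, layer1, layer2, layer3

    def __init__(self, seed: int = 0, tap_layers=(2, 3), trainable: bool = False):
        self.tap_layers = tuple(tap_layers)
        self.frozen = not trainable
        rng = np.random.default_rng([int(seed), 7])
        chans = [self.in_channels, 8, 16, 32, 64]
        self._weights = []
        self._biases = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            self._weights.append(Tensor(_he_conv(rng, cout, cin, 3), requires_grad=trainable))
            self._biases.append(Tensor(np.zeros(cout), requires_grad=trainable))

    def parameters(self) -> list[Tensor]:
        return list(self._weights) + list(self._biases)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward_tensors(self, x: Tensor) -> dict[int, Tensor]:
        feats: dict[int, Tensor] = {}
        h = conv2d(x, self._weights[0], self._biases[0],
                   stride=self._layer_strides[0], padding=1).relu()  # stem
        for layer in (1, 2, 3):
            h = conv2d(h, self._weights[layer], self._biases[layer],
                       stride=self._layer_strides[layer], padding=1).relu()
            feats[layer] = h
        return feats

    # -- weights persistence (used by the fine-tuning CLI) ---------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self._weights, self._biases)):
            out[f"w{i}"] = w.data.copy()
            out[f"b{i}"] = b.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (w, b) in enumerate(zip(self._weights, self._biases)):
            w.data = np.asarray(state[f"w{i}"], dtype=np.float64)
            b.data = np.asarray(state[f"b{i}"], dtype=np.float64)

    def copy(self) -> "TinyCNNAdapter":
        dup = TinyCNNAdapter(tap_layers=self.tap_layers, trainable=not self.frozen)
        dup.load_state_dict(self.state_dict())
        return dup


# -- wide 50-layer residual network (width factor 2) -----------------------------

_RESNET50_BLOCKS = (3, 4, 6, 3)
_PLANES = (64, 128, 256, 512)


def _wrn_layer_shapes(width_factor: int = 2):
    """Yield (kind, shape) for every parameter of the architecture."""
    yield "conv", (64, 3, 7, 7)
    yield "bn", (64,)
    inplanes = 64
    for planes, blocks in zip(_PLANES, _RESNET50_BLOCKS):
        width = planes * width_factor
        out = planes * 4
        for b in range(blocks):
            cin = inplanes if b == 0 else out
            yield "conv", (width, cin, 1, 1)
            yield "bn", (width,)
            yield "conv", (width, width, 3, 3)
            yield "bn", (width,)
            yield "conv", (out, width, 1, 1)
            yield "bn", (out,)
            if b == 0:
                yield "conv", (out, cin, 1, 1)  # downsample projection
                yield "bn", (out,)
        inplanes = out
    yield "fc", (1000, 512 * 4)
    yield "fc_bias", (1000,)


def wide_resnet50_parameter_count() -> int:
    """Total parameter count of the wide 50-layer residual network (x2 width).

    Batch-norm layers contribute an affine weight and bias each; running
    statistics are buffers, not parameters.
    """
    total = 0
    for kind, shape in _wrn_layer_shapes():
        n = int(np.prod(shape))
        total += 2 * n if kind == "bn" else n
    return total


class WideResNet50Adapter(BackboneAdapter):
    """Wide ResNet-50 (width factor 2); taps the four residual stages.

    Weights default to seeded He initialization; pass ``weights`` (an .npz
    path or a dict) to use trained parameters. Only the stages up to the
    deepest tap are instantiated for the forward pass.
    """

    name = "wide_resnet50_2"
    channels = {1: 256, 2: 512, 3: 1024, 4: 2048}
    strides = {1: 4, 2: 8, 3: 16, 4: 32}

    def __init__(self, seed: int = 0, tap_layers=(2, 3), weights=None):
        self.tap_layers = tuple(tap_layers)
        self.seed = int(seed)
        self._params: dict[str, np.ndarray] | None = None
        self._weights_src = weights

    def num_parameters(self) -> int:
        return wide_resnet50_parameter_count()

    # weights are built lazily: parameter counting must not allocate 69M floats
    def _ensure_params(self):
        if self._params is not None:
            return
        if self._weights_src is not None:
            src = self._weights_src
            self._params = dict(np.load(src)) if isinstance(src, str) else dict(src)
            return
        rng = np.random.default_rng([self.seed, 50])
        params: dict[str, np.ndarray] = {}
        deepest = max(self.tap_layers)
        params["conv1"] = _he_conv(rng, 64, 3, 7)
        inplanes = 64
        for li, (planes, blocks) in enumerate(zip(_PLANES, _RESNET50_BLOCKS), start=1):
            if li > deepest:
                break
            width = planes * 2
            out = planes * 4
            for b in range(blocks):
                cin = inplanes if b == 0 else out
                pre = f"l{li}b{b}"
                params[f"{pre}c1"] = _he_conv(rng, width, cin, 1)
                params[f"{pre}c2"] = _he_conv(rng, width, width, 3)
                params[f"{pre}c3"] = _he_conv(rng, out, width, 1)
                if b == 0:
                    params[f"{pre}ds"] = _he_conv(rng, out, cin, 1)
            inplanes = out
        self._params = params

    @staticmethod
    def _maxpool3x3s2(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        return win[:, :, ::2, ::2].max(axis=(4, 5))

    def forward_tensors(self, x: Tensor) -> dict[int, Tensor]:
        # numpy-only inference path (the adapter is always frozen downstream)
        self._ensure_params()
        p = self._params

        def conv_np(h, w_key, stride, padding):
            return conv2d(Tensor(h), Tensor(p[w_key]), None, stride=stride, padding=padding).data

        h = np.maximum(conv_np(x.data, "conv1", 2, 3), 0.0)
        h = self._maxpool3x3s2(h)
        feats: dict[int, Tensor] = {}
        deepest = max(self.tap_layers)
        for li, (planes, blocks) in enumerate(zip(_PLANES, _RESNET50_BLOCKS), start=1):
            if li > deepest:
                break
            stride = 1 if li == 1 else 2
            for b in range(blocks):
                pre = f"l{li}b{b}"
                s = stride if b == 0 else 1
                identity = h
                out = np.maximum(conv_np(h, f"{pre}c1", 1, 0), 0.0)
                out = np.maximum(conv_np(out, f"{pre}c2", s, 1), 0.0)
                out = conv_np(out, f"{pre}c3", 1, 0)
                if b == 0:
                    identity = conv_np(identity, f"{pre}ds", s, 0)
                h = np.maximum(out + identity, 0.0)
            feats[li] = Tensor(h)
        return feats


def get_backbone(name: str, seed: int = 0, tap_layers=(2, 3), **kw) -> BackboneAdapter:
    if name == "tiny":
        return TinyCNNAdapter(seed=seed, tap_layers=tap_layers, **kw)
    if name == "wide_resnet50_2":
        return WideResNet50Adapter(seed=seed, tap_layers=tap_layers, **kw)
    raise ValueError(f"unknown backbone '{name}' (expected 'tiny' or 'wide_resnet50_2')")
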