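"""Slice encoder: backbone taps -> neighborhood aggregation -> multi-layer
fusion -> channel reduction.

A 2D slice is mapped to a single low-resolution feature grid: each tapped
backbone layer is locally averaged over a p x p neighborhood, all layers are
bilinearly upscaled to the resolution of the first (shallowest) tap and
concatenated, and the concatenated channels are mean-pooled down to the
target embedding dimension (default 512). The encoder is a pure function of
(slice, backbone weights, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .backbones import BackboneAdapter

__all__ = [
    "EncoderConfig",
    "SliceFeatureMap",
    "extract_layer_features",
    "patch_aggregate",
    "fuse_layers",
    "reduce_channels",
    "encode_slice",
]


@dataclass(frozen=True)
class EncoderConfig:
    patch_size: int = 3     # p: odd neighborhood size for local aggregation
    target_dim: int = 512   # embedding dimension after channel reduction

    def __post_init__(self):
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 1, got {self.patch_size}")
        if self.target_dim < 1:
            raise ValueError("target_dim must be >= 1")


@dataclass
class SliceFeatureMap:
    """Fused, channel-reduced feature grid for one slice."""

    values: np.ndarray  # (C, H0, W0)
    layers: tuple[int, ...] = ()
    patch_size: int = 3
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


def extract_layer_features(slice_img: np.ndarray, backbone: BackboneAdapter) -> dict[int, np.ndarray]:
    """Tapped intermediate feature grids (C_l, H_l, W_l) for one slice."""
    return backbone.extract(np.asarray(slice_img))


def patch_aggregate(grid: np.ndarray, p: int) -> np.ndarray:
    """Mean over each p x p neighborhood (stride 1, replicate-padded borders)."""
    if p % 2 == 0:
        raise ValueError(f"patch size must be odd, got {p}")
    if p == 1:
        return np.asarray(grid, dtype=np.float64)
    grid = np.asarray(grid, dtype=np.float64)
    return ndimage.uniform_filter(grid, size=(1, p, p), mode="nearest")


def fuse_layers(grids: dict[int, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Upscale every grid to the first grid's resolution and concatenate.

    Grids are taken in layer order (shallowest first); the shallowest layer
    defines the fused resolution (H0, W0). Channel count of the output is the
    sum of the inputs' channel counts.
    """
    if isinstance(grids, dict):
        ordered = [np.asarray(grids[k]) for k in sorted(grids)]
    else:
        ordered = [np.asarray(g) for g in grids]
    if not ordered:
        raise ValueError("fuse_layers requires at least one feature grid")
    h0, w0 = ordered[0].shape[1], ordered[0].shape[2]
    up = []
    for g in ordered:
        if g.shape[1:] == (h0, w0):
            up.append(g.astype(np.float64))
        else:
            up.append(
                _sk_resize(g.astype(np.float64), (g.shape[0], h0, w0), order=1,
                           preserve_range=True, anti_aliasing=False)
            )
    return np.concatenate(up, axis=0)


def reduce_channels(fused: np.ndarray, target_dim: int) -> np.ndarray:
    """Adaptive mean pooling along the channel axis down to target_dim.

    Channel i of the output averages input channels
    [floor(i*C/t), ceil((i+1)*C/t)); with C == target_dim this is the identity.
    """
    c = fused.shape[0]
    if target_dim > c:
        raise ValueError(
            f"target_dim {target_dim} exceeds channel count {c}; no up-projection is defined"
        )
    if target_dim == c:
        return np.asarray(fused, dtype=np.float64)
    fused = np.asarray(fused, dtype=np.float64)
    out = np.empty((target_dim,) + fused.shape[1:], dtype=np.float64)
    for i in range(target_dim):
        lo = (i * c) // target_dim
        hi = -(-((i + 1) * c) // target_dim)  # ceil division
        out[i] = fused[lo:hi].mean(axis=0)
    return out


def encode_slice(
    slice_img: np.ndarray, backbone: BackboneAdapter, config: EncoderConfig | None = None
) -> SliceFeatureMap:
    """Full slice encoding: extract -> patch-aggregate -> fuse -> reduce."""
    config = config or EncoderConfig()
    feats = extract_layer_features(slice_img, backbone)
    aggregated = {l: patch_aggregate(g, config.patch_size) for l, g in feats.items()}
    fused = fuse_layers(aggregated)
    reduced = reduce_channels(fused, config.target_dim)
    return SliceFeatureMap(
        values=reduced, layers=tuple(sorted(feats)), patch_size=config.patch_size,
        meta={"backbone": backbone.name},
    )
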