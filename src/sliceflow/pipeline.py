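"""Volume-level scoring: per-slice encoding, depth aggregation, per-voxel
flow likelihoods, and anomaly-map construction.

Each axial slice is encoded to a (C, H0, W0) feature grid; grids are stacked
along depth and every voxel's feature vector is replaced by the mean over a
centered depth window of w slices (replicated at the volume ends; w = 1 is
plain stacking, the no-aggregation ablation). Every voxel's vector is then
scored by the conditional flow with the positional code of its (h, w)
location, converted to an anomaly score

    s(x) = 1 - exp(log p(x)),

and the low-resolution score grid is bilinearly upscaled within each slice to
the input resolution (the depth axis is already at slice resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import cnf
from .backbones import BackboneAdapter
from .encoder import EncoderConfig, SliceFeatureMap, encode_slice
from .volio import Volume

__all__ = [
    "VolumeFeatureGrid",
    "AnomalyMap",
    "aggregate_volume",
    "anomaly_score",
    "score_volume",
    "image_level_scores",
    "normalize_scores",
]


@dataclass
class VolumeFeatureGrid:
    """Depth-aggregated per-voxel feature vectors, shape (D, C, H0, W0)."""

    values: np.ndarray
    window: int = 3
    meta: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]


@dataclass
class AnomalyMap:
    """Per-voxel anomaly scores at input resolution, plus the low-res source.

    ``scores`` holds 1 - exp(log p) per voxel. ``logp`` (when available)
    carries the underlying log-likelihood map: the exponentiated score spans
    hundreds of orders of magnitude, so every rank-based computation
    downstream works in log space, which orders voxels identically.
    """

    scores: np.ndarray              # (D, H, W)
    low_res: np.ndarray             # (D, H0, W0)
    logp: np.ndarray | None = None  # (D, H, W) log-likelihoods (rank-safe)
    normalization: str = "raw"      # raw | per_volume | dataset
    meta: dict = field(default_factory=dict)


def aggregate_volume(slice_maps: list[SliceFeatureMap] | list[np.ndarray], w: int = 3) -> VolumeFeatureGrid:
    """Depth-window mean of per-slice feature grids (permutation-invariant
    within the window); window ends replicate the boundary slices."""
    if not slice_maps:
        raise ValueError("aggregate_volume requires at least one slice feature map")
    if w < 1 or w % 2 == 0:
        raise ValueError(f"aggregation window must be odd and >= 1, got {w}")
    grids = [m.values if isinstance(m, SliceFeatureMap) else np.asarray(m) for m in slice_maps]
    shape0 = grids[0].shape
    for i, g in enumerate(grids):
        if g.shape != shape0:
            raise ValueError(f"slice {i} feature shape {g.shape} != slice 0 shape {shape0}")
    stacked = np.stack(grids, axis=0).astype(np.float64)  # (D, C, H0, W0)
    if w > 1:
        stacked = ndimage.uniform_filter1d(stacked, size=w, axis=0, mode="nearest")
    return VolumeFeatureGrid(values=stacked, window=w)


def anomaly_score(logp: np.ndarray) -> np.ndarray:
    """Eq. s(x) = 1 - exp(log p); strictly decreasing in log p, range (-inf, 1]."""
    logp = np.asarray(logp, dtype=np.float64)
    if np.isnan(logp).any():
        raise ValueError("log-likelihoods contain NaN")
    # cap only where exp would overflow float64; affects voxels that are
    # overwhelmingly normal, whose relative ranking is immaterial
    return 1.0 - np.exp(np.minimum(logp, 700.0))


def score_volume(
    volume: Volume | np.ndarray,
    backbone: BackboneAdapter,
    flow: "cnf.FlowModel",
    config: EncoderConfig | None = None,
    w: int = 3,
    smooth_sigma: float = 1.0,
    feature_loc: float = 0.0,
    feature_scale: float = 1.0,
    features: VolumeFeatureGrid | None = None,
) -> AnomalyMap:
    """Score every voxel of a volume; returns a raw (unnormalized) AnomalyMap.

    The log-likelihood grid is (optionally) Gaussian-smoothed within each
    slice (``smooth_sigma``, in low-resolution cells) and upscaled bilinearly
    to the input resolution *in log-likelihood space*; the anomaly score
    1 - exp(log p) is applied per voxel afterwards. Interpolating log p rather
    than the exponentiated score keeps the upscaling numerically meaningful —
    scores span hundreds of orders of magnitude.

    ``feature_loc``/``feature_scale`` apply the global standardization the
    flow was trained with (see SliceFlowDetector). ``features`` may carry
    precomputed aggregated features for this volume (e.g. when scoring the
    same volume under several flows).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if flow is None:
        raise ValueError("score_volume requires a trained flow (none given)")
    if features is None:
        maps = [encode_slice(data[j], backbone, config) for j in range(data.shape[0])]
        features = aggregate_volume(maps, w=w)
    grid = features.values  # (D, C, H0, W0)
    d_slices, c, h0, w0 = grid.shape
    cond = cnf.positional_condition(h0, w0, flow.condition_dim)  # (H0*W0, cond)
    vectors = (grid.transpose(0, 2, 3, 1).reshape(-1, c) - feature_loc) / feature_scale
    cond_full = np.tile(cond, (d_slices, 1))
    logp = cnf.log_likelihood(vectors, cond_full, flow).reshape(d_slices, h0, w0)
    if smooth_sigma > 0:
        logp = ndimage.gaussian_filter(logp, sigma=(0.0, smooth_sigma, smooth_sigma))
    low = anomaly_score(logp)
    logp_full = np.stack(
        [
            _sk_resize(logp[j], data.shape[1:], order=1, preserve_range=True, anti_aliasing=False)
            for j in range(d_slices)
        ],
        axis=0,
    )
    return AnomalyMap(scores=anomaly_score(logp_full), low_res=low, logp=logp_full,
                      normalization="raw")


def image_level_scores(amap: AnomalyMap) -> np.ndarray:
    """One scalar per axial slice: the maximum pixel anomaly score in it."""
    if amap.scores.size == 0:
        raise ValueError("empty anomaly map")
    return amap.scores.max(axis=(1, 2))


def _minmax(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def normalize_scores(maps: list[AnomalyMap], mode: str = "per_volume") -> list[AnomalyMap]:
    """Min-max normalize score maps to [0, 1].

    mode='per_volume': extrema computed within each volume (pixel-level
    protocol); mode='dataset': joint extrema over all volumes (image-level
    protocol). Constant input maps to all zeros. Rank order within a volume
    is preserved by both modes.
    """
    if not maps:
        raise ValueError("normalize_scores requires at least one map")
    if mode not in ("per_volume", "dataset"):
        raise ValueError(f"unknown normalization mode '{mode}'")
    out = []
    if mode == "dataset":
        lo = min(float(m.scores.min()) for m in maps)
        hi = max(float(m.scores.max()) for m in maps)
    for m in maps:
        if mode == "per_volume":
            lo, hi = float(m.scores.min()), float(m.scores.max())
        out.append(
            AnomalyMap(
                scores=_minmax(m.scores, lo, hi),
                low_res=_minmax(m.low_res, lo, hi),
                logp=m.logp,
                normalization=mode,
                meta=dict(m.meta),
            )
        )
    return out
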