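"""Synthetic 3D brain-like phantoms with known lesion masks.

Generates "normal" volumes — a smooth ellipsoidal head with per-subject
structural variation (a smooth random warp plus low-frequency intensity
texture) and voxel noise — and "anomalous" counterparts carrying compact
hyper-/hypo-intense ellipsoidal lesions with exact ground-truth masks.
Intensities are clipped to [0, 1]; axial slices run along the first axis.

Every volume is a deterministic function of ``(spec.seed, index)``: each
volume draws from its own RNG substreams (structure / noise / lesions), so a
dataset can be extended without changing earlier volumes and switching one
randomness source off never changes the draws of another.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "generate_normal_volume",
    "generate_anomalous_volume",
    "write_phantom_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom cohort.

    shape is (D, H, W): axial slices stacked along the first axis.
    lesion_contrast is an additive intensity offset in [-1, 1] (positive =
    hyperintense). deformation_scale controls both the smooth warp magnitude
    (voxels) and the amplitude of the low-frequency per-subject texture.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    n_normal: int = 20
    n_anomalous: int = 10
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    lesion_contrast: float = 0.35
    n_lesions_range: tuple[int, int] = (1, 3)
    deformation_scale: float = 1.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for ax, dim in zip("DHW", self.shape):
            if dim < 8:
                raise ValueError(f"phantom shape dimension {ax}={dim} must be >= 8")
        if not -1.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(spec: PhantomSpec, index: int, stream: int) -> np.random.Generator:
    # one substream per (volume, purpose); keeps structure draws independent
    # of whether noise/lesions are enabled
    return np.random.default_rng([int(spec.seed), int(index), stream])


def _smooth_field(rng: np.random.Generator, shape, coarse: int = 6) -> np.ndarray:
    """Low-frequency random field in roughly [-1, 1] via coarse-grid upsampling."""
    coarse_shape = tuple(max(2, s // coarse) for s in shape)
    field = rng.normal(size=coarse_shape)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    up = ndimage.zoom(field, zoom, order=3, mode="nearest", grid_mode=True)
    return up[: shape[0], : shape[1], : shape[2]]


def _base_head(shape) -> tuple[np.ndarray, np.ndarray]:
    """Template intensity volume and smooth interior weight (no randomness)."""
    d, h, w = shape
    zz, yy, xx = np.meshgrid(
        np.linspace(-1, 1, d), np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij"
    )
    r = np.sqrt((zz / 0.85) ** 2 + (yy / 0.8) ** 2 + (xx / 0.8) ** 2)
    interior = 1.0 / (1.0 + np.exp((r - 1.0) / 0.05))  # soft brain boundary
    # concentric structure: brighter cortex ring, dimmer center ("ventricles")
    intensity = 0.65 - 0.25 * np.exp(-(r**2) / 0.08) + 0.1 * np.cos(3.0 * np.pi * r)
    return np.clip(intensity, 0.05, 0.95) * interior, interior


def generate_normal_volume(spec: PhantomSpec, index: int) -> np.ndarray:
    """Generate one normal phantom volume, deterministic in (spec.seed, index)."""
    shape = tuple(spec.shape)
    base, interior = _base_head(shape)
    rng_struct = _rng(spec, index, 0)

    if spec.deformation_scale > 0:
        # smooth per-subject warp of the template
        disp = [
            _smooth_field(rng_struct, shape) * spec.deformation_scale for _ in range(3)
        ]
        grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
        coords = [g + dx for g, dx in zip(grids, disp)]
        vol = ndimage.map_coordinates(base, coords, order=1, mode="nearest")
        interior_w = ndimage.map_coordinates(interior, coords, order=1, mode="nearest")
        # low-frequency per-subject texture, confined to the brain
        texture = _smooth_field(rng_struct, shape) * 0.04 * spec.deformation_scale
        vol = vol + texture * interior_w
    else:
        _ = rng_struct  # structure stream unused when variation is off
        vol = base.copy()

    if spec.noise_sd > 0:
        vol = vol + _rng(spec, index, 1).normal(0.0, spec.noise_sd, size=shape)

    return np.clip(vol, 0.0, 1.0).astype(np.float32)


def _lesion_field(spec: PhantomSpec, index: int, shape) -> np.ndarray:
    """Additive lesion intensity field (before clipping), smooth borders."""
    rng = _rng(spec, index, 2)
    lo, hi = spec.lesion_radius_range
    if lo <= 0 or hi <= 0:
        raise ValueError("lesion_radius_range must be positive")
    if 2 * hi >= min(shape):
        raise ValueError(
            f"lesion diameter {2 * hi} does not fit in volume of shape {shape}"
        )
    n_lo, n_hi = spec.n_lesions_range
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    blob = np.zeros(shape, dtype=np.float64)
    for _ in range(n_lesions):
        radii = rng.uniform(lo, hi, size=3)
        # centers kept inside the head interior (central 50% per axis)
        center = [rng.uniform(0.3 * s, 0.7 * s) for s in shape]
        r2 = sum(((g - c) / rad) ** 2 for g, c, rad in zip(grids, center, radii))
        blob = np.maximum(blob, (r2 <= 1.0).astype(np.float64))
    blob = ndimage.gaussian_filter(blob, sigma=1.0)  # smooth transition zone
    return blob * spec.lesion_contrast


def generate_anomalous_volume(spec: PhantomSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Normal volume with 1-3 additive ellipsoidal lesions plus its binary mask.

    The mask marks voxels whose intensity was shifted by more than half the
    lesion contrast (measured on the additive field, before clipping).
    """
    normal = generate_normal_volume(spec, index).astype(np.float64)
    field = _lesion_field(spec, index, tuple(spec.shape))
    vol = np.clip(normal + field, 0.0, 1.0).astype(np.float32)
    if spec.lesion_contrast == 0:
        mask = np.zeros(spec.shape, dtype=np.uint8)
    else:
        mask = (np.abs(field) > abs(spec.lesion_contrast) / 2.0).astype(np.uint8)
    return vol, mask


def lesion_fraction(mask: np.ndarray) -> float:
    return float(np.count_nonzero(mask)) / mask.size


def write_phantom_dataset(spec: PhantomSpec, out_dir: str) -> pd.DataFrame:
    """Write the cohort as NIfTI volumes/masks plus a CSV manifest.

    Returns the manifest (path, label, mask_path, seed, index, lesion_fraction).
    """
    from . import volio

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(spec.n_normal):
        vol = generate_normal_volume(spec, i)
        path = os.path.join(out_dir, f"normal_{i:03d}.nii.gz")
        volio.write_volume(volio.Volume(vol), path)
        rows.append(
            dict(path=path, label="normal", mask_path="", seed=spec.seed, index=i,
                 lesion_fraction=0.0)
        )
    for i in range(spec.n_anomalous):
        idx = spec.n_normal + i
        vol, mask = generate_anomalous_volume(spec, idx)
        path = os.path.join(out_dir, f"anomalous_{idx:03d}.nii.gz")
        mask_path = os.path.join(out_dir, f"anomalous_{idx:03d}_mask.nii.gz")
        volio.write_volume(volio.Volume(vol), path)
        volio.write_volume(volio.Volume(mask.astype(np.uint8)), mask_path)
        rows.append(
            dict(path=path, label="anomalous", mask_path=mask_path, seed=spec.seed,
                 index=idx, lesion_fraction=lesion_fraction(mask))
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    return dataclasses.asdict(spec)
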