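"""Volume I/O and array-level preprocessing.

Volumes are stored as (D, H, W) arrays with axial slices along the first
axis. NIfTI files are read through nibabel and reoriented to the closest
canonical (RAS) orientation so the inferior-superior axis always maps to
axis 0, regardless of how the file was stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "center_crop",
    "rescale_intensity",
    "resize_pad",
]


@dataclass
class Volume:
    """A 3D intensity grid (D axial slices x H x W) with its spatial affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def read_volume(path: str) -> Volume:
    """Load a NIfTI volume; axis 0 of the result stacks axial slices."""
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(
            f"expected a 3D volume, got {len(img.shape)}D data of shape {img.shape} in {path}"
        )
    img = nib.as_closest_canonical(img)  # RAS: axes (L-R, P-A, I-S)
    data = np.asanyarray(img.dataobj)
    data = np.transpose(data, (2, 1, 0))  # (S-I stacking first)
    return Volume(data=data, affine=np.asarray(img.affine), meta={"path": path, "original_shape": img.shape})


def write_volume(vol: Volume, path: str) -> None:
    """Write a Volume to NIfTI, inverting the axis convention of read_volume."""
    data = np.transpose(np.asarray(vol.data), (2, 1, 0))
    if np.issubdtype(data.dtype, np.integer) or data.dtype == np.uint8:
        data = data.astype(np.uint8) if data.max(initial=0) < 256 and data.min(initial=0) >= 0 else data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    try:
        nib.save(nib.Nifti1Image(data, vol.affine), path)
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed to write volume to {path}: {exc}") from exc


def _as_dhw(target_hwd) -> tuple[int, int, int]:
    h, w, d = target_hwd
    return int(d), int(h), int(w)


def center_crop(vol: Volume, target: tuple[int, int, int]) -> Volume:
    """Center-crop to target (H, W, D); odd remainders drop the high-index side."""
    td, th, tw = _as_dhw(target)
    src = vol.data.shape
    for name, t, s in zip(("D", "H", "W"), (td, th, tw), src):
        if t > s:
            raise ValueError(f"crop target {name}={t} exceeds source {name}={s} (cropping never pads)")
    starts = [(s - t) // 2 for s, t in zip(src, (td, th, tw))]
    sl = tuple(slice(st, st + t) for st, t in zip(starts, (td, th, tw)))
    return Volume(vol.data[sl].copy(), vol.affine.copy(), dict(vol.meta))


def rescale_intensity(vol: Volume) -> Volume:
    """Min-max rescale intensities to [0, 1]; a constant volume maps to zeros."""
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("volume contains NaN or Inf; cannot rescale intensities")
    lo, hi = data.min(), data.max()
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return Volume(out.astype(np.float32), vol.affine.copy(), dict(vol.meta))


def resize_pad(vol: Volume, target: tuple[int, int, int]) -> Volume:
    """Isotropically scale to fit within target (H, W, D), then zero-pad to it."""
    td, th, tw = _as_dhw(target)
    if min(td, th, tw) <= 0:
        raise ValueError("resize target dimensions must be positive")
    src = vol.data.shape
    factor = min(t / s for t, s in zip((td, th, tw), src))
    new_shape = tuple(min(t, int(round(s * factor))) for s, t in zip(src, (td, th, tw)))
    if new_shape == tuple(src):
        scaled = np.asarray(vol.data, dtype=np.float64)
    else:
        scaled = _sk_resize(
            np.asarray(vol.data, dtype=np.float64), new_shape, order=1,
            preserve_range=True, anti_aliasing=False,
        )
    pads = []
    for s, t in zip(scaled.shape, (td, th, tw)):
        extra = t - s
        pads.append((extra // 2, extra - extra // 2))
    out = np.pad(scaled, pads, mode="constant")
    return Volume(out.astype(np.float32), vol.affine.copy(), dict(vol.meta))
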