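"""NIfTI case I/O and in-scope preprocessing (z-score normalization, resizing).

A "case" on disk is a path prefix with one ``.nii.gz`` file per modality
(``<prefix>_t1.nii.gz``, ``_t1ce``, ``_t2``, ``_flair``) plus an optional
``_seg`` binary mask; a missing mask is the lesion-free convention and reads
back as all zeros. Heavy preprocessing (MNI reorientation, co-registration,
bias-field correction, brain extraction) is delegated to the standard
external neuroimaging tools and is out of scope here — volumes are assumed
already skull-stripped with zero background.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CHANNELS",
    "read_case",
    "write_case",
    "normalize_volume",
    "resize_case",
    "preprocess_case",
]

CHANNELS = ("t1", "t1ce", "t2", "flair")


def write_case(
    prefix: str | Path,
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> None:
    """Write a 4-channel volume (and optional mask) as per-channel NIfTI files."""
    prefix = Path(prefix)
    volume = np.asarray(volume)
    if volume.ndim != 4 or volume.shape[0] != len(CHANNELS):
        raise ValueError(f"expected (4, D, H, W) volume, got {volume.shape}")
    if affine is None:
        affine = np.eye(4)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(CHANNELS):
        img = nib.Nifti1Image(np.asarray(volume[c], dtype=np.float32), affine)
        nib.save(img, f"{prefix}_{name}.nii.gz")
    if mask is not None:
        if mask.shape != volume.shape[1:]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {volume.shape[1:]}"
            )
        img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
        nib.save(img, f"{prefix}_seg.nii.gz")


def read_case(prefix: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a case back as ``(volume (4,D,H,W), mask (D,H,W), affine)``.

    Channels are stacked in the fixed (t1, t1ce, t2, flair) order and brought
    to the closest canonical axis orientation. A missing ``_seg`` file yields
    an all-zero mask; a mask with labels outside {0, 1} is rejected.
    """
    prefix = Path(prefix)
    channels = []
    affine = None
    for name in CHANNELS:
        path = Path(f"{prefix}_{name}.nii.gz")
        if not path.exists():
            raise FileNotFoundError(f"missing modality {name!r}: {path}")
        img = nib.as_closest_canonical(nib.load(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if not np.isfinite(data).all():
            raise ValueError(f"non-finite intensities in {path}")
        if channels and data.shape != channels[0].shape:
            raise ValueError(
                f"channel shape mismatch: {name} is {data.shape}, "
                f"expected {channels[0].shape}"
            )
        channels.append(data)
        if affine is None:
            affine = img.affine
    volume = np.stack(channels)

    seg_path = Path(f"{prefix}_seg.nii.gz")
    if seg_path.exists():
        seg = nib.as_closest_canonical(nib.load(seg_path))
        mask = np.asarray(seg.dataobj)
        if mask.shape != volume.shape[1:]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {volume.shape[1:]}"
            )
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask is not binary; found labels {vals}")
        mask = mask.astype(np.uint8)
    else:
        mask = np.zeros(volume.shape[1:], dtype=np.uint8)
    return volume, mask, affine


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Z-score each channel over the brain region; background stays zero.

    The brain region is the set of voxels that are nonzero in any channel.
    Each channel's brain voxels are shifted to mean 0 and scaled to unit
    standard deviation (so the operation is idempotent up to float error).
    A channel that is constant over the region carries no signal and is
    rejected.
    """
    volume = np.asarray(volume, dtype=np.float64)
    region = (volume != 0).any(axis=0)
    if not region.any():
        raise ValueError("volume has no nonzero (brain) region")
    out = np.zeros_like(volume)
    for c in range(volume.shape[0]):
        vals = volume[c][region]
        sd = vals.std()
        if sd == 0:
            raise ValueError(
                f"channel {c} is constant over the brain region (degenerate)"
            )
        out[c][region] = (vals - vals.mean()) / sd
    return out.astype(np.float32)


def resize_case(
    volume: np.ndarray,
    mask: np.ndarray | None,
    target_size: int,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resample to a cubic ``target_size`` grid.

    Intensities use trilinear interpolation; the mask uses nearest-neighbor
    so labels remain strictly binary.
    """
    if not isinstance(target_size, (int, np.integer)):
        raise ValueError("target_size must be a single integer (cubic grid)")
    if target_size < 16:
        raise ValueError(f"target_size must be >= 16, got {target_size}")
    volume = np.asarray(volume)
    if volume.shape[1:] == (target_size,) * 3:
        return volume, mask
    factors = [target_size / s for s in volume.shape[1:]]
    out = np.stack(
        [
            ndimage.zoom(volume[c], factors, order=1, mode="nearest",
                         grid_mode=True)
            for c in range(volume.shape[0])
        ]
    ).astype(np.float32)
    new_mask = None
    if mask is not None:
        new_mask = ndimage.zoom(
            mask.astype(np.uint8), factors, order=0, mode="nearest",
            grid_mode=True
        ).astype(np.uint8)
    return out, new_mask


def preprocess_case(
    volume: np.ndarray,
    mask: np.ndarray | None,
    target_size: int,
    normalize_after_resize: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resize to the network grid and z-score normalize (order configurable)."""
    if normalize_after_resize:
        volume, mask = resize_case(volume, mask, target_size)
        volume = normalize_volume(volume)
    else:
        volume = normalize_volume(volume)
        volume, mask = resize_case(volume, mask, target_size)
    return volume, mask
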