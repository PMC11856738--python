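"""Volume I/O and the preprocessing chain.

Volumes are rank-3 scalar grids with per-axis voxel spacing (mm) and a 4x4
affine, stored as gzipped NIfTI. The preprocessing chain mirrors standard
practice for anisotropic prostate T2W scans: resample to a fixed target
spacing (default [0.66, 0.66, 5] mm), Z-score normalise over the whole
volume, then slice along the axial (third) axis to fixed-size 2D inputs or
crop a 3D patch centred on the organ.

Interpolation: order-3 spline in-plane, nearest-neighbour along the slice
axis (the through-plane spacing is far coarser than in-plane, so smooth
interpolation between slices would invent structure); masks always
nearest-neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

TARGET_SPACING = (0.66, 0.66, 5.0)


@dataclass
class Volume:
    """A rank-3 scalar grid with voxel spacing (mm) and world affine."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"volume must be rank 3, got rank {self.grid.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self):
        return self.grid.shape


def read_volume(path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj)
    if grid.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {grid.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume(grid=grid, spacing=tuple(float(z) for z in zooms),
                  affine=np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.grid, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample(vol: Volume, target_spacing=TARGET_SPACING, is_mask: bool = False) -> Volume:
    """Resample to ``target_spacing``; shape_k = round(shape_k * sp_k / target_k).

    Images use an order-3 spline in-plane and nearest-neighbour along the
    slice axis; masks use nearest-neighbour on every axis.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    in_shape = np.array(vol.shape, dtype=float)
    in_sp = np.array(vol.spacing)
    out_shape = np.maximum(1, np.rint(in_shape * in_sp / np.array(target))).astype(int)
    factors = out_shape / in_shape

    grid = vol.grid
    if is_mask:
        out = ndimage.zoom(grid.astype(np.float32), factors, order=0, mode="nearest")
        out = np.rint(out).astype(vol.grid.dtype)
    else:
        # in-plane smooth interpolation ...
        out = ndimage.zoom(grid.astype(np.float32), (factors[0], factors[1], 1.0),
                           order=3, mode="nearest")
        # ... then nearest along the slice axis
        if out_shape[2] != grid.shape[2]:
            idx = np.clip(np.rint(np.arange(out_shape[2]) / factors[2]).astype(int),
                          0, grid.shape[2] - 1)
            out = out[:, :, idx]

    # keep direction, rescale column lengths to the new spacing
    affine = vol.affine.copy()
    for k in range(3):
        col = affine[:3, k]
        norm = np.linalg.norm(col)
        if norm > 0:
            affine[:3, k] = col / norm * target[k]
    return Volume(grid=out, spacing=target, affine=affine)


def znorm(vol: Volume) -> Volume:
    """Z-score normalise intensities over the whole volume."""
    g = vol.grid.astype(np.float32)
    std = g.std()
    if std == 0:
        raise ValueError("zero intensity variance: Z-score normalisation undefined")
    return Volume(grid=(g - g.mean()) / std, spacing=vol.spacing, affine=vol.affine)


def _pad_crop_2d(plane: np.ndarray, size: int) -> np.ndarray:
    """Symmetrically pad/crop a 2-D array to (size, size)."""
    out = plane
    for ax in (0, 1):
        n = out.shape[ax]
        if n < size:
            lo = (size - n) // 2
            pad = [(0, 0), (0, 0)]
            pad[ax] = (lo, size - n - lo)
            out = np.pad(out, pad)
        elif n > size:
            lo = (n - size) // 2
            sl = [slice(None), slice(None)]
            sl[ax] = slice(lo, lo + size)
            out = out[tuple(sl)]
    return out


def make_slices_2d(vol: Volume, mask: Volume | None = None, size: int = 512):
    """Axial slices padded/cropped symmetrically to (size, size).

    Returns a list of (image_slice, mask_slice) pairs (mask_slice is None
    when no mask is given), one per slice along the third axis.
    """
    pairs = []
    for k in range(vol.shape[2]):
        img = _pad_crop_2d(vol.grid[:, :, k], size)
        msk = _pad_crop_2d(mask.grid[:, :, k], size) if mask is not None else None
        pairs.append((img, msk))
    return pairs


def crop_patch_3d(vol: Volume, mask: Volume, patch_size=(320, 320, 16)):
    """3-D patch centred on the mask centroid, zero-padded at borders."""
    if mask is None or not np.any(mask.grid):
        raise ValueError("a nonempty mask is required to centre the 3-D patch")
    centroid = np.rint(ndimage.center_of_mass(mask.grid.astype(bool))).astype(int)
    out_img = np.zeros(patch_size, dtype=np.float32)
    out_msk = np.zeros(patch_size, dtype=mask.grid.dtype)
    src_lo = [c - p // 2 for c, p in zip(centroid, patch_size)]
    for arr, out in ((vol.grid, out_img), (mask.grid, out_msk)):
        sl_src, sl_dst = [], []
        for ax in range(3):
            lo, hi = src_lo[ax], src_lo[ax] + patch_size[ax]
            sl_src.append(slice(max(lo, 0), min(hi, arr.shape[ax])))
            sl_dst.append(slice(max(-lo, 0), max(-lo, 0) + sl_src[-1].stop - sl_src[-1].start))
        out[tuple(sl_dst)] = arr[tuple(sl_src)]
    return out_img, out_msk


def restore_to_grid(mask2d_stack: np.ndarray, original_shape, size: int) -> np.ndarray:
    """Undo the symmetric pad/crop of :func:`make_slices_2d` on a stack of
    predicted slices (H, W, K) back to ``original_shape``."""
    out = np.zeros(original_shape, dtype=mask2d_stack.dtype)
    h, w = original_shape[:2]

    def offsets(n):
        if n < size:  # slices were padded; crop back
            lo = (size - n) // 2
            return slice(lo, lo + n), slice(0, n)
        lo = (n - size) // 2  # slices were cropped; paste into centre
        return slice(0, size), slice(lo, lo + size)
    s0, d0 = offsets(h)
    s1, d1 = offsets(w)
    out[d0, d1, :] = mask2d_stack[s0, s1, :]
    return out
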