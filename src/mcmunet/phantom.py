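"""Synthetic prostate-like T2W phantoms.

Each phantom is a bright ellipsoidal organ on a darker background, with
three deliberately modelled nuisance features of real prostate T2W MRI:

* anisotropic voxel spacing (default [0.66, 0.66, 5] mm);
* boundary blur that is strongest on the first/last slices the organ
  occupies — the analogue of the apex and base of the gland, where real
  boundaries are blurriest — and mildest at mid-gland;
* additive Gaussian noise.

The label mask is the *clean* ellipsoid (blur and noise only affect the
image), so ground truth is exact. Everything is deterministic per seed.
No attempt is made at physics-accurate MR simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import Volume, write_volume
from .metrics import LabelMask


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic case.

    Semi-axes are in mm and jittered per seed by up to ``semi_axes_jitter``
    (relative); the organ centre is jittered by up to ``center_jitter_mm``.
    ``blur_sigma_mid`` / ``blur_sigma_apex`` are in-plane Gaussian widths in
    voxels applied at mid-gland and at the apex/base slices respectively.
    """

    grid_size: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.66, 0.66, 5.0)
    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 12.5)
    semi_axes_jitter: float = 0.2
    center_jitter_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    organ_intensity: float = 1.0
    background_intensity: float = 0.3
    blur_sigma_mid: float = 0.5
    blur_sigma_apex: float = 2.5
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.blur_sigma_mid < 0 or self.blur_sigma_apex < 0:
            raise ValueError("blur strengths must be >= 0")
        half_fov = 0.5 * np.array(self.grid_size) * np.array(self.spacing)
        worst = (np.array(self.semi_axes_mm) * (1 + self.semi_axes_jitter)
                 + np.array(self.center_jitter_mm))
        if np.any(worst >= half_fov):
            raise ValueError(
                f"organ (worst case {worst} mm) does not fit inside the grid "
                f"(half FOV {half_fov} mm)")

    @property
    def volume_fraction_bounds(self) -> tuple[float, float]:
        """Analytic bounds on the organ voxel-volume fraction over seeds."""
        voxel = float(np.prod(self.spacing))
        total = float(np.prod(self.grid_size)) * voxel
        lo = 4 / 3 * np.pi * np.prod(np.array(self.semi_axes_mm)
                                     * (1 - self.semi_axes_jitter)) / total
        hi = 4 / 3 * np.pi * np.prod(np.array(self.semi_axes_mm)
                                     * (1 + self.semi_axes_jitter)) / total
        # voxelisation of a small ellipsoid is coarse along the 5 mm axis
        return 0.5 * lo, 1.5 * hi


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Deterministically generate one (image volume, clean mask) pair."""
    rng = np.random.default_rng(spec.seed)
    axes = np.array(spec.semi_axes_mm) * (
        1 + rng.uniform(-spec.semi_axes_jitter, spec.semi_axes_jitter, 3))
    center = rng.uniform(-1, 1, 3) * np.array(spec.center_jitter_mm)

    nx, ny, nz = spec.grid_size
    sp = np.array(spec.spacing)
    coords = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(spec.grid_size, sp)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    mask = ((xx - center[0]) ** 2 / axes[0] ** 2
            + (yy - center[1]) ** 2 / axes[1] ** 2
            + (zz - center[2]) ** 2 / axes[2] ** 2) <= 1.0
    if not mask.any():
        raise ValueError("degenerate phantom: organ occupies no voxel")

    img = np.full(spec.grid_size, spec.background_intensity, dtype=np.float32)
    img[mask] = spec.organ_intensity

    occupied = np.flatnonzero(mask.any(axis=(0, 1)))
    k0, k1 = occupied[0], occupied[-1]
    kmid = 0.5 * (k0 + k1)
    half = max((k1 - k0) / 2.0, 0.5)
    for k in range(nz):
        t = min(abs(k - kmid) / half, 1.0)  # 0 at mid-gland, 1 at apex/base
        sigma = spec.blur_sigma_mid + t * (spec.blur_sigma_apex - spec.blur_sigma_mid)
        if sigma > 0:
            img[:, :, k] = ndimage.gaussian_filter(img[:, :, k], sigma)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)

    affine = np.diag([*sp, 1.0])
    vol = Volume(grid=img, spacing=tuple(sp), affine=affine)
    return vol, LabelMask(mask.astype(np.uint8), tuple(sp))


def boundary_gradient_by_slice(vol: Volume, mask: LabelMask) -> dict[int, float]:
    """Mean in-plane intensity-gradient magnitude on the organ's in-plane
    boundary, per occupied slice. Used to verify the apex/base blur ramp."""
    out: dict[int, float] = {}
    for k in range(vol.shape[2]):
        m = mask.grid[:, :, k].astype(bool)
        if not m.any():
            continue
        interior = ndimage.binary_erosion(m, border_value=0)
        edge = m & ~interior
        gx, gy = np.gradient(vol.grid[:, :, k].astype(float))
        out[k] = float(np.hypot(gx, gy)[edge].mean())
    return out


def apex_base_gradient_contrast(vol: Volume, mask: LabelMask) -> tuple[float, float]:
    """(mean gradient on the first/last occupied slices, mean over the
    middle third of occupied slices)."""
    grads = boundary_gradient_by_slice(vol, mask)
    ks = sorted(grads)
    apex_base = [grads[ks[0]], grads[ks[-1]]]
    n = len(ks)
    mid = [grads[k] for k in ks[n // 3: n - n // 3]] or [grads[ks[n // 2]]]
    return float(np.mean(apex_base)), float(np.mean(mid))


def write_phantom_dataset(out_dir, n_cases: int, seed: int = 0,
                          spec: PhantomSpec | None = None,
                          splits=(0.6, 0.2, 0.2)) -> pd.DataFrame:
    """Generate a train/val/test phantom dataset with a manifest.

    Writes ``<case>_img.nii.gz`` / ``<case>_msk.nii.gz`` per case and a
    ``manifest.csv`` with columns case_id, image, mask, seed, split.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    n_train = int(round(splits[0] * n_cases))
    n_val = int(round(splits[1] * n_cases))
    rows = []
    for i, cs in enumerate(case_seeds):
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        case_id = f"case_{i:03d}"
        s = PhantomSpec(**{**base.__dict__, "seed": int(cs)})
        vol, msk = generate_phantom(s)
        img_path = out_dir / f"{case_id}_img.nii.gz"
        msk_path = out_dir / f"{case_id}_msk.nii.gz"
        write_volume(vol, img_path)
        write_volume(Volume(msk.grid, msk.spacing, vol.affine), msk_path)
        rows.append({"case_id": case_id, "image": img_path.name,
                     "mask": msk_path.name, "seed": int(cs), "split": split})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_phantom_cases(n_cases: int, seed: int = 0,
                       spec: PhantomSpec | None = None,
                       splits=(0.6, 0.2, 0.2)):
    """In-memory variant of :func:`write_phantom_dataset`: returns a dict
    split -> list of (case_id, Volume, LabelMask)."""
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    n_train = int(round(splits[0] * n_cases))
    n_val = int(round(splits[1] * n_cases))
    out = {"train": [], "val": [], "test": []}
    for i, cs in enumerate(case_seeds):
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        s = PhantomSpec(**{**base.__dict__, "seed": int(cs)})
        vol, msk = generate_phantom(s)
        out[split].append((f"case_{i:03d}", vol, msk))
    return out
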