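"""Surface-distance and overlap metrics for binary segmentation masks.

The evaluation layer used throughout the package: boundary (edge voxel)
extraction under 6-connectivity, the average symmetric surface distance
(ASSD), the 95th-percentile Hausdorff distance (HD95), Jaccard index and
Dice similarity coefficient (DSC, both in percent), and the Pearson
correlation coefficient used to quantify inter-annotator agreement.

Distances default to voxel units; pass ``units="mm"`` to weight coordinates
by the mask's voxel spacing. HD95 uses the linear-interpolation percentile
(:func:`numpy.percentile` default) over the sorted directed-distance list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


class EmptyMaskError(ValueError):
    """Raised when a metric needs a surface but a mask has no foreground."""


@dataclass
class LabelMask:
    """Binary rank-3 mask with per-axis voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask must be rank 3, got rank {self.grid.ndim}")
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, got {vals}")
        self.grid = self.grid.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


def _as_mask(m) -> LabelMask:
    return m if isinstance(m, LabelMask) else LabelMask(np.asarray(m))


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_boundary(mask: LabelMask | np.ndarray) -> np.ndarray:
    """Edge voxels of a binary mask: foreground voxels with at least one
    face-adjacent neighbour that is background or outside the grid.

    Returns an (K, 3) array of 0-based integer coordinates in lexicographic
    order.
    """
    mask = _as_mask(mask)
    fg = mask.grid.astype(bool)
    if not fg.any():
        raise EmptyMaskError("mask has no foreground: no surface to extract")
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(fg & ~interior)


def _surface_distances(a: LabelMask, b: LabelMask, units: str) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-boundary distance lists (A->B, B->A)."""
    sa = extract_boundary(a).astype(float)
    sb = extract_boundary(b).astype(float)
    if units == "mm":
        sa = sa * np.asarray(a.spacing)
        sb = sb * np.asarray(b.spacing)
    elif units != "voxel":
        raise ValueError(f"units must be 'voxel' or 'mm', got {units!r}")
    d_ab = cKDTree(sb).query(sa, k=1)[0]
    d_ba = cKDTree(sa).query(sb, k=1)[0]
    return d_ab, d_ba


def assd(a, b, units: str = "voxel") -> float:
    """Average symmetric surface distance between two masks.

    Sums, over each edge voxel of each mask, the Euclidean distance to the
    nearest edge voxel of the other mask, and divides by the total number of
    edge voxels |S(A)| + |S(B)|. Symmetric in its arguments.
    """
    d_ab, d_ba = _surface_distances(_as_mask(a), _as_mask(b), units)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def hd95(a, b, units: str = "voxel") -> float:
    """95th-percentile Hausdorff distance: the larger of the two directed
    95th percentiles of nearest-boundary distances."""
    d_ab, d_ba = _surface_distances(_as_mask(a), _as_mask(b), units)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def jaccard(a, b) -> float:
    """Intersection over union, in percent."""
    a, b = _as_mask(a), _as_mask(b)
    ga, gb = a.grid.astype(bool), b.grid.astype(bool)
    union = np.logical_or(ga, gb).sum()
    if union == 0:
        raise EmptyMaskError("both masks empty: Jaccard undefined")
    return 100.0 * np.logical_and(ga, gb).sum() / union


def dsc(a, b) -> float:
    """Dice similarity coefficient 2TP / (FP + FN + 2TP), in percent."""
    a, b = _as_mask(a), _as_mask(b)
    ga, gb = a.grid.astype(bool), b.grid.astype(bool)
    tp = np.logical_and(ga, gb).sum()
    fp = np.logical_and(~ga, gb).sum()
    fn = np.logical_and(ga, ~gb).sum()
    if tp + fp + fn == 0:
        raise EmptyMaskError("both masks empty: DSC undefined")
    return 100.0 * 2.0 * tp / (fp + fn + 2.0 * tp)


def annotation_cc(x, y) -> float:
    """Pearson correlation between two annotators' per-slice series.

    Used to quantify inter-annotator agreement on paired slice annotations
    (e.g. per-slice delineated areas).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D series of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise ValueError("zero variance in an annotation series: CC undefined")
    return float((dx * dy).sum() / denom)


@dataclass
class MetricReport:
    """Per-case metric rows plus their aggregate (arithmetic) means.

    Empty predictions get 0% overlap and missing (NaN) distances; missing
    distances are excluded from the aggregate means.
    """

    per_case: pd.DataFrame
    aggregate: pd.Series = field(init=False)

    COLUMNS = ["case_id", "assd_voxel", "hd95_voxel", "jaccard_pct", "dsc_pct"]

    def __post_init__(self):
        numeric = self.per_case[self.COLUMNS[1:]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.aggregate = numeric.mean(skipna=True)

    def to_csv(self, path) -> None:
        agg = pd.DataFrame([{"case_id": "mean", **self.aggregate.to_dict()}])
        pd.concat([self.per_case, agg], ignore_index=True).to_csv(path, index=False)


def case_metrics(pred: LabelMask, gt: LabelMask, units: str = "voxel") -> dict:
    """All four metrics for one case, applying the empty-prediction policy."""
    if gt.foreground_count == 0:
        raise EmptyMaskError("ground-truth mask has no foreground")
    if pred.foreground_count == 0:
        warnings.warn("empty prediction: distance metrics reported as missing")
        return {"assd_voxel": np.nan, "hd95_voxel": np.nan,
                "jaccard_pct": 0.0, "dsc_pct": 0.0}
    return {
        "assd_voxel": assd(pred, gt, units=units),
        "hd95_voxel": hd95(pred, gt, units=units),
        "jaccard_pct": jaccard(pred, gt),
        "dsc_pct": dsc(pred, gt),
    }


def pooled_overlap(pairs: list[tuple[LabelMask, LabelMask]]) -> dict:
    """Dataset-pooled Jaccard/DSC: voxel counts summed over all cases before
    forming the ratios (the alternative reading of the dataset-level sums)."""
    tp = fp = fn = un = 0
    for pred, gt in pairs:
        gp, gg = pred.grid.astype(bool), gt.grid.astype(bool)
        tp += np.logical_and(gp, gg).sum()
        fp += np.logical_and(gp, ~gg).sum()
        fn += np.logical_and(~gp, gg).sum()
        un += np.logical_or(gp, gg).sum()
    return {"jaccard_pct": 100.0 * tp / un, "dsc_pct": 100.0 * 2 * tp / (fp + fn + 2 * tp)}


def evaluate_cases(pred_dir, gt_dir, units: str = "voxel") -> MetricReport:
    """Evaluate every ``<case_id>.nii.gz`` prediction against its ground truth.

    Case identifiers are the file stems; every ground-truth case must have a
    matching prediction.
    """
    from .data import read_volume  # local import: avoid cycle at module load

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    gt_files = sorted(gt_dir.glob("*.nii.gz"))
    if not gt_files:
        raise FileNotFoundError(f"no .nii.gz ground-truth masks in {gt_dir}")
    missing = [f.name for f in gt_files if not (pred_dir / f.name).exists()]
    if missing:
        raise FileNotFoundError(f"predictions missing for cases: {missing}")

    rows = []
    for f in gt_files:
        case_id = f.name[: -len(".nii.gz")]
        gt_v = read_volume(f)
        pr_v = read_volume(pred_dir / f.name)
        gt_m = LabelMask(np.rint(gt_v.grid).astype(np.uint8), gt_v.spacing)
        pr_m = LabelMask(np.rint(pr_v.grid).astype(np.uint8), pr_v.spacing)
        rows.append({"case_id": case_id, **case_metrics(pr_m, gt_m, units=units)})
    return MetricReport(pd.DataFrame(rows, columns=MetricReport.COLUMNS))
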