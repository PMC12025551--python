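"""Segmentation evaluation metrics for binary masks.

Implements the standard suite used to score spinal-cord and lesion
segmentations: overlap (Dice similarity coefficient, volume overlap
error), volume (relative volume difference), surface distance (average
symmetric surface distance, Hausdorff distance and its 95th-percentile
variant) and pixel-detection (recall, precision) metrics between a
predicted mask (PM) and a ground-truth mask (GT).

Overlap/volume/detection metrics are reported in percent; surface
distances in millimetres, using the per-axis physical pixel spacing of
the masks.  Degenerate cases (empty masks) follow explicit conventions
and are flagged so that aggregated tables remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask",
    "ConfusionCounts",
    "SurfacePointSet",
    "MetricReport",
    "UndefinedMetricError",
    "dice",
    "voe",
    "rvd",
    "extract_surface",
    "asd",
    "directed_hd",
    "hausdorff",
    "hd95",
    "confusion",
    "recall",
    "precision",
    "evaluate_pair",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is mathematically undefined for its inputs."""


@dataclass(frozen=True)
class BinaryMask:
    """A 2D binary segmentation mask with physical pixel spacing.

    Parameters
    ----------
    grid : ndarray of {0, 1}
        Foreground pixels are 1, background 0.
    spacing : (row_mm, col_mm)
        Physical size of one pixel along rows and columns, in mm.
    """

    grid: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {g.shape}")
        u = np.unique(g)
        if not np.isin(u, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be two positive floats, got {self.spacing}")
        object.__setattr__(self, "grid", g.astype(np.uint8))
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def volume(self) -> int:
        """Foreground pixel count (the 2D analogue of volume)."""
        return int(self.grid.sum())

    @property
    def diagonal_mm(self) -> float:
        """Physical image diagonal; the penalty distance for empty-mask cases."""
        return float(np.hypot(self.height * self.spacing[0], self.width * self.spacing[1]))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts between a prediction and ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class SurfacePointSet:
    """Boundary pixels of a mask, as (row, col) coordinates plus spacing."""

    points: np.ndarray  # (n, 2) integer pixel coordinates
    spacing: tuple[float, float] = (1.0, 1.0)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def points_mm(self) -> np.ndarray:
        """Coordinates scaled to physical millimetres."""
        return np.asarray(self.points, dtype=float) * np.asarray(self.spacing)


@dataclass(frozen=True)
class MetricReport:
    """One evaluated prediction/ground-truth pair (one table row)."""

    dsc: float
    voe: float
    rvd: float
    asd: float
    hd: float
    hd95: float
    rec: float
    pre: float
    degenerate_flag: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "DSC": self.dsc,
            "VOE": self.voe,
            "RVD": self.rvd,
            "ASD": self.asd,
            "HD": self.hd,
            "HD95": self.hd95,
            "REC": self.rec,
            "PRE": self.pre,
            "degenerate": self.degenerate_flag,
        }


def _check_compatible(pm: BinaryMask, gt: BinaryMask, spacing_too: bool = True) -> None:
    if pm.grid.shape != gt.grid.shape:
        raise ValueError(f"mask shapes differ: {pm.grid.shape} vs {gt.grid.shape}")
    if spacing_too and pm.spacing != gt.spacing:
        raise ValueError(f"mask spacings differ: {pm.spacing} vs {gt.spacing}")


def dice(pm: BinaryMask, gt: BinaryMask) -> float:
    """Dice similarity coefficient, percent: 2|PM∩GT| / (|PM| + |GT|) × 100.

    Both masks empty is scored as perfect agreement (100)."""
    _check_compatible(pm, gt)
    inter = int(np.logical_and(pm.grid, gt.grid).sum())
    denom = pm.volume + gt.volume
    if denom == 0:
        return 100.0
    return 200.0 * inter / denom


def voe(pm: BinaryMask, gt: BinaryMask) -> float:
    """Volume overlap error, percent: (1 − |PM∩GT| / |PM∪GT|) × 100."""
    _check_compatible(pm, gt, spacing_too=False)
    inter = int(np.logical_and(pm.grid, gt.grid).sum())
    union = int(np.logical_or(pm.grid, gt.grid).sum())
    if union == 0:
        return 0.0
    return 100.0 * (1.0 - inter / union)


def rvd(pm: BinaryMask, gt: BinaryMask) -> float:
    """Relative volume difference, percent, signed: (|PM| − |GT|) / |GT| × 100.

    Positive values indicate over-segmentation."""
    _check_compatible(pm, gt, spacing_too=False)
    if gt.volume == 0:
        raise UndefinedMetricError("RVD is undefined for an empty ground-truth mask")
    return 100.0 * (pm.volume - gt.volume) / gt.volume


def extract_surface(mask: BinaryMask) -> SurfacePointSet:
    """Boundary pixels: foreground pixels with a background 4-neighbour.

    Pixels on the image border count as boundary.  Empty masks yield an
    empty point set.
    """
    g = mask.grid.astype(bool)
    padded = np.pad(g, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = g & ~interior
    pts = np.argwhere(boundary)
    return SurfacePointSet(points=pts, spacing=mask.spacing)


def _directed_distances(a: SurfacePointSet, b: SurfacePointSet) -> np.ndarray:
    """Min Euclidean distance (mm) from every point of ``a`` to the set ``b``."""
    tree = cKDTree(b.points_mm)
    d, _ = tree.query(a.points_mm, k=1)
    return np.atleast_1d(d)


def directed_hd(a: SurfacePointSet, b: SurfacePointSet) -> float:
    """Directed Hausdorff distance max_{x∈a} min_{y∈b} ‖x−y‖, in mm."""
    if len(a) == 0 or len(b) == 0:
        raise UndefinedMetricError("directed Hausdorff distance needs non-empty point sets")
    return float(_directed_distances(a, b).max())


def _surface_pair(pm: BinaryMask, gt: BinaryMask):
    _check_compatible(pm, gt)
    return extract_surface(pm), extract_surface(gt)


def asd(pm: BinaryMask, gt: BinaryMask) -> float:
    """Average symmetric surface distance in mm.

    Sum of directed boundary distances in both directions divided by the
    total number of boundary points.  Conventions: both masks empty → 0;
    exactly one empty → the image diagonal (a worst-case penalty).
    """
    s_pm, s_gt = _surface_pair(pm, gt)
    if len(s_pm) == 0 and len(s_gt) == 0:
        return 0.0
    if len(s_pm) == 0 or len(s_gt) == 0:
        return pm.diagonal_mm
    d_pg = _directed_distances(s_pm, s_gt)
    d_gp = _directed_distances(s_gt, s_pm)
    return float((d_pg.sum() + d_gp.sum()) / (len(s_pm) + len(s_gt)))


def _hd_at_percentile(pm: BinaryMask, gt: BinaryMask, q: float) -> float:
    s_pm, s_gt = _surface_pair(pm, gt)
    if len(s_pm) == 0 and len(s_gt) == 0:
        return 0.0
    if len(s_pm) == 0 or len(s_gt) == 0:
        return pm.diagonal_mm
    d_pg = _directed_distances(s_pm, s_gt)
    d_gp = _directed_distances(s_gt, s_pm)
    # max of the two directed percentiles; linear interpolation between
    # order statistics keeps results bit-stable across runs
    return float(max(np.percentile(d_pg, q), np.percentile(d_gp, q)))


def hausdorff(pm: BinaryMask, gt: BinaryMask) -> float:
    """Symmetric Hausdorff distance in mm (max of the two directed distances)."""
    return _hd_at_percentile(pm, gt, 100.0)


def hd95(pm: BinaryMask, gt: BinaryMask) -> float:
    """95th-percentile Hausdorff distance in mm, robust to boundary outliers."""
    return _hd_at_percentile(pm, gt, 95.0)


def confusion(pm: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Pixelwise confusion counts of a prediction against ground truth."""
    _check_compatible(pm, gt, spacing_too=False)
    p = pm.grid.astype(bool)
    g = gt.grid.astype(bool)
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def recall(c: ConfusionCounts) -> float:
    """Pixel recall TP/(TP+FN) × 100."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive ground-truth pixels")
    return 100.0 * c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """Pixel precision TP/(TP+FP) × 100."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positive pixels")
    return 100.0 * c.tp / (c.tp + c.fp)


def evaluate_pair(pm: BinaryMask, gt: BinaryMask) -> MetricReport:
    """Compute all eight metrics for one prediction/ground-truth pair.

    Degenerate conventions (kept so that per-image tables aggregate
    without dropping rows, with a flag for auditability):

    * both masks empty: perfect scores, flag set;
    * exactly one mask empty: DSC 0, VOE 100, surface metrics equal to the
      image diagonal, REC/PRE 0 where defined, flag set;
    * empty GT additionally makes RVD undefined → NaN with flag.
    """
    _check_compatible(pm, gt)
    c = confusion(pm, gt)
    empty_pm = pm.volume == 0
    empty_gt = gt.volume == 0
    degenerate = empty_pm or empty_gt

    dsc_v = dice(pm, gt)
    voe_v = voe(pm, gt)
    rvd_v = float("nan") if empty_gt else rvd(pm, gt)
    asd_v = asd(pm, gt)
    hd_v = hausdorff(pm, gt)
    hd95_v = hd95(pm, gt)
    rec_v = float("nan") if empty_gt else recall(c)
    pre_v = float("nan") if empty_pm else precision(c)
    if empty_pm and empty_gt:
        rec_v = pre_v = 100.0
        rvd_v = 0.0
    elif empty_pm:
        pre_v = 0.0
    elif empty_gt:
        rec_v = 0.0
        rvd_v = float("nan")

    return MetricReport(
        dsc=dsc_v,
        voe=voe_v,
        rvd=rvd_v,
        asd=asd_v,
        hd=hd_v,
        hd95=hd95_v,
        rec=rec_v,
        pre=pre_v,
        degenerate_flag=degenerate,
        extras={"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
    )
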