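"""Per-cell boundary morphometry and the three-feature blebbing classifier.

The boundary of each segmented cell is traced at the 0.5 iso-level, smoothed
with a circular Savitzky–Golay filter, and its unsigned curvature estimated
at every point as the reciprocal circumradius 1/r of the circle through the
point and two neighbors ``step`` samples away.  Cells are called "blebbing"
when mean curvature, nuclear/cytoplasmic adhesion-marker intensity ratio and
cell/nucleus area ratio jointly pass their cutoffs; outlier cells (tiny
DAPI-positive area, huge cell area) are filtered out first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.measure import find_contours

from .config import BlebbingThresholds, MorphometryConfig

__all__ = [
    "BoundaryTrace",
    "CellFeatures",
    "trace_boundary",
    "smooth_boundary",
    "point_curvature",
    "mean_cell_curvature",
    "intensity_ratio",
    "classify_blebbing",
    "apply_cell_filters",
    "extract_features",
]


@dataclass
class BoundaryTrace:
    """Ordered closed boundary of one cell; optionally with curvatures."""

    points: np.ndarray  # (n, 2) sub-pixel (row, col), closed implicitly
    curvatures: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 8:
            raise ValueError("a boundary trace needs at least 8 points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellFeatures:
    """Feature record of one segmented cell."""

    cell_id: int
    cell_area: float
    nucleus_area: float
    mean_curvature: float
    intensity_ratio_nuc_cyto: float
    area_ratio_cell_nuc: float
    fa_count: int = 0
    blebbing: bool = False
    excluded_by: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Boundary extraction and smoothing
# ---------------------------------------------------------------------------

def trace_boundary(cell_mask: np.ndarray) -> BoundaryTrace:
    """Sub-pixel outer boundary of a single 8-connected mask, CCW ordered.

    The contour is extracted at the 0.5 iso-level of the binary mask (pixel
    centers at integer coordinates).  Masks with multiple components, masks
    touching the array border, or degenerate masks without interior (1-px
    lines) are rejected.
    """
    mask = np.asarray(cell_mask).astype(bool)
    if mask.sum() < 20:
        raise ValueError("mask area must be >= 20 px")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ValueError(f"mask must be one 8-connected component, found {n_comp}")
    if (
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    ):
        raise ValueError("mask touches the array border; cannot close the contour")
    if not ndimage.binary_erosion(mask).any():
        raise ValueError("degenerate mask (no interior)")
    contours = find_contours(mask.astype(np.float64), 0.5)
    outer = max(contours, key=len)
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    # drop duplicated consecutive points, if any
    keep = np.ones(len(outer), dtype=bool)
    keep[1:] = np.any(np.diff(outer, axis=0) != 0.0, axis=1)
    outer = outer[keep]
    # enforce counter-clockwise orientation in (x=col, y=-row) convention
    if _signed_area(outer) < 0:
        outer = outer[::-1]
    return BoundaryTrace(points=outer)


def _signed_area(points: np.ndarray) -> float:
    x = points[:, 1]
    y = -points[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    return abs(_signed_area(np.asarray(points, dtype=np.float64)))


def smooth_boundary(trace: BoundaryTrace, window: int = 9, polyorder: int = 3) -> BoundaryTrace:
    """Circular Savitzky–Golay smoothing of both coordinate sequences."""
    if window % 2 != 1:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(
            f"window ({window}) must exceed polyorder ({polyorder})"
        )
    if window >= len(trace):
        raise ValueError(
            f"window ({window}) must be smaller than the number of points ({len(trace)})"
        )
    rows = savgol_filter(trace.points[:, 0], window, polyorder, mode="wrap")
    cols = savgol_filter(trace.points[:, 1], window, polyorder, mode="wrap")
    return BoundaryTrace(points=np.column_stack([rows, cols]))


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def point_curvature(p_a, p_b, p_c) -> float:
    """Unsigned curvature 1/r from the circumradius of three points.

    ``r = abc / 4A`` with a, b, c the side lengths and A the triangle area;
    collinear points give curvature 0.
    """
    p_a = np.asarray(p_a, dtype=np.float64)
    p_b = np.asarray(p_b, dtype=np.float64)
    p_c = np.asarray(p_c, dtype=np.float64)
    a = np.linalg.norm(p_b - p_c)
    b = np.linalg.norm(p_a - p_c)
    c = np.linalg.norm(p_a - p_b)
    if min(a, b, c) == 0.0:
        raise ValueError("coincident points have no circumcircle")
    area2 = abs(
        (p_b[0] - p_a[0]) * (p_c[1] - p_a[1]) - (p_c[0] - p_a[0]) * (p_b[1] - p_a[1])
    )  # = 2A
    return float(2.0 * area2 / (a * b * c))


def _curvature_series(points: np.ndarray, step: int) -> np.ndarray:
    prev = np.roll(points, step, axis=0)
    nxt = np.roll(points, -step, axis=0)
    a = np.linalg.norm(points - nxt, axis=1)
    b = np.linalg.norm(prev - nxt, axis=1)
    c = np.linalg.norm(prev - points, axis=1)
    area2 = np.abs(
        (points[:, 0] - prev[:, 0]) * (nxt[:, 1] - prev[:, 1])
        - (nxt[:, 0] - prev[:, 0]) * (points[:, 1] - prev[:, 1])
    )
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return kappa


def mean_cell_curvature(trace: BoundaryTrace, step: int = 2) -> float:
    """Mean of per-point circumradius curvatures with circular indexing."""
    n = len(trace)
    if not 1 <= step < n / 3:
        raise ValueError(f"step must satisfy 1 <= step < n/3 (n={n})")
    kappa = _curvature_series(trace.points, step)
    trace.curvatures = kappa
    return float(kappa.mean())


# ---------------------------------------------------------------------------
# Intensity / classification / filters
# ---------------------------------------------------------------------------

def intensity_ratio(adhesion_channel, nucleus_mask, cell_mask) -> float:
    """Mean adhesion-marker intensity over the nucleus / over the cytoplasm."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus mask must lie inside the cell mask")
    cyto = cell_mask & ~nucleus_mask
    if not cyto.any():
        raise ValueError("empty cytoplasm (cell minus nucleus)")
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    img = np.asarray(adhesion_channel, dtype=np.float64)
    return float(img[nucleus_mask].mean() / img[cyto].mean())


def classify_blebbing(
    features: CellFeatures, thresholds: BlebbingThresholds | None = None
) -> bool:
    """Three-feature blebbing rule; all comparisons strict."""
    t = thresholds or BlebbingThresholds()
    return (
        features.mean_curvature > t.curvature_min
        and features.intensity_ratio_nuc_cyto < t.intensity_ratio_max
        and features.area_ratio_cell_nuc < t.area_ratio_max
    )


def apply_cell_filters(
    records: list[CellFeatures], thresholds: BlebbingThresholds | None = None
) -> tuple[list[CellFeatures], list[CellFeatures]]:
    """Outlier filters on nucleus and cell area; returns (retained, excluded).

    Excluded records are annotated with the name of the triggering rule
    (``nucleus_area_min`` and/or ``cell_area_max``).
    """
    t = thresholds or BlebbingThresholds()
    retained, excluded = [], []
    for rec in records:
        rules = []
        if rec.nucleus_area < t.nucleus_area_min:
            rules.append("nucleus_area_min")
        if rec.cell_area > t.cell_area_max:
            rules.append("cell_area_max")
        if rules:
            for r in rules:
                if r not in rec.excluded_by:
                    rec.excluded_by.append(r)
            excluded.append(rec)
        else:
            retained.append(rec)
    return retained, excluded


# ---------------------------------------------------------------------------
# Whole-image feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    adhesion_channel: np.ndarray,
    config: MorphometryConfig | None = None,
    thresholds: BlebbingThresholds | None = None,
) -> list[CellFeatures]:
    """Per-cell features for every label in ``cell_labels``.

    Each cell's nucleus is the nucleus label with the largest area inside the
    cell.  Curvature is measured on the Savitzky–Golay-smoothed boundary.
    """
    config = config or MorphometryConfig()
    thresholds = thresholds or BlebbingThresholds()
    records = []
    for cell_id in range(1, int(cell_labels.max()) + 1):
        cmask = cell_labels == cell_id
        if not cmask.any():
            continue
        inside = nucleus_labels[cmask]
        inside = inside[inside > 0]
        if inside.size == 0:
            continue
        nuc_id = np.bincount(inside).argmax()
        nmask = (nucleus_labels == nuc_id) & cmask
        trace = smooth_boundary(
            trace_boundary(cmask), config.savgol_window, config.savgol_polyorder
        )
        kappa = mean_cell_curvature(trace, config.curvature_step)
        cell_area = float(cmask.sum())
        nucleus_area = float(nmask.sum())
        rec = CellFeatures(
            cell_id=cell_id,
            cell_area=cell_area,
            nucleus_area=nucleus_area,
            mean_curvature=kappa,
            intensity_ratio_nuc_cyto=intensity_ratio(adhesion_channel, nmask, cmask),
            area_ratio_cell_nuc=cell_area / nucleus_area,
        )
        rec.blebbing = classify_blebbing(rec, thresholds)
        records.append(rec)
    return records


def features_to_frame(records: list[CellFeatures]) -> pd.DataFrame:
    """Tabulate feature records; exclusions flagged, not deleted."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "cell_area": [r.cell_area for r in records],
            "nucleus_area": [r.nucleus_area for r in records],
            "mean_curvature": [r.mean_curvature for r in records],
            "intensity_ratio_nuc_cyto": [r.intensity_ratio_nuc_cyto for r in records],
            "area_ratio_cell_nuc": [r.area_ratio_cell_nuc for r in records],
            "fa_count": [r.fa_count for r in records],
            "blebbing": [r.blebbing for r in records],
            "excluded_by": [";".join(r.excluded_by) for r in records],
        }
    )
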