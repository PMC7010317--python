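"""Focal-adhesion segmentation, per-cell counting, and count cutoffs.

Puncta are segmented from the adhesion channel with the PST "fa" preset and
then filtered with the rules of the quantification pipeline: components
mostly outside any cell or inside a nucleus are discarded, as are components
smaller than ``min_fa_area`` pixels or with a mean adhesion-channel intensity
not above the mean over their assigned cell.  Per-dataset cutoffs remove
cells above the pooled 99th-percentile count (segmentation blow-ups) and
cells with four or fewer adhesions (out-of-focus cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FAConfig, PSTParams, get_pst_preset
from .pst import pst_segment

__all__ = [
    "segment_fas",
    "filter_fas",
    "count_fas",
    "apply_fa_cutoffs",
    "FACutoffResult",
]


def segment_fas(
    adhesion_channel: np.ndarray,
    config: FAConfig | None = None,
    pst_params: PSTParams | None = None,
) -> np.ndarray:
    """Label map of adhesion-channel puncta (PST preset, no hole context)."""
    config = config or FAConfig()
    params = pst_params or get_pst_preset(config.fa_preset)
    return pst_segment(adhesion_channel, params)


def filter_fas(
    fa_labels: np.ndarray,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    adhesion_channel: np.ndarray,
    config: FAConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the masking, size and intensity filters to FA candidates.

    Keeps components whose majority area lies inside a cell and not inside a
    nucleus, with area >= ``min_fa_area`` and mean intensity strictly above
    the mean over the assigned cell's whole mask.  Components straddling two
    cells go to the larger-overlap cell (ties to the lower label).

    Returns the filtered, relabeled map and a table with one row per
    surviving component (``fa_id``, ``cell_id``, ``area``,
    ``mean_intensity``).
    """
    config = config or FAConfig()
    img = np.asarray(adhesion_channel, dtype=np.float64)
    fa_labels = np.asarray(fa_labels)
    out = np.zeros_like(fa_labels)
    # per-cell mean adhesion intensity (the comparison baseline)
    cell_means = {}
    for cid in np.unique(cell_labels[cell_labels > 0]):
        cell_means[int(cid)] = img[cell_labels == cid].mean()

    rows = []
    next_id = 1
    for fid in np.unique(fa_labels[fa_labels > 0]):
        comp = fa_labels == fid
        area = int(comp.sum())
        cells_here = cell_labels[comp]
        in_cell = cells_here > 0
        if in_cell.sum() * 2 <= area:  # majority outside all cells
            continue
        if (nucleus_labels[comp] > 0).sum() * 2 > area:  # majority in a nucleus
            continue
        counts = np.bincount(cells_here[in_cell])
        cell_id = int(counts.argmax())  # argmax takes the lower label on ties
        if area < config.min_fa_area:
            continue
        mean_int = float(img[comp].mean())
        if mean_int <= cell_means[cell_id]:
            continue
        out[comp] = next_id
        rows.append(
            {"fa_id": next_id, "cell_id": cell_id, "area": area, "mean_intensity": mean_int}
        )
        next_id += 1
    table = pd.DataFrame(rows, columns=["fa_id", "cell_id", "area", "mean_intensity"])
    return out, table


def count_fas(fa_table: pd.DataFrame, cell_labels: np.ndarray) -> pd.Series:
    """Per-cell FA counts; cells with no adhesions get 0, not missing."""
    cell_ids = np.unique(cell_labels[cell_labels > 0]).astype(int)
    counts = pd.Series(0, index=pd.Index(cell_ids, name="cell_id"), dtype=int)
    if len(fa_table):
        got = fa_table.groupby("cell_id").size()
        counts.loc[got.index] = got
    return counts


@dataclass
class FACutoffResult:
    """Outcome of the per-dataset count cutoffs."""

    retained: pd.DataFrame
    excluded: pd.DataFrame
    upper_cutoff: float  # realized pooled percentile value, frozen


def apply_fa_cutoffs(records: pd.DataFrame, config: FAConfig | None = None) -> FACutoffResult:
    """Pooled upper-percentile and low-count cutoffs on ``fa_count``.

    The upper cutoff is the ``upper_percentile`` (linear-interpolation)
    percentile of ``fa_count`` over the whole dataset, computed once and
    recorded; cells strictly above it are removed, as are cells with
    ``fa_count <= lower_count_max``.  Exclusions are annotated in an
    ``excluded_by`` column.
    """
    config = config or FAConfig()
    if "fa_count" not in records:
        raise KeyError("records must carry an 'fa_count' column")
    counts = records["fa_count"].to_numpy(dtype=float)
    upper = float(np.percentile(counts, config.upper_percentile))
    flags = []
    for c in counts:
        rules = []
        if c > upper:
            rules.append("fa_count_upper_percentile")
        if c <= config.lower_count_max:
            rules.append("fa_count_lower_max")
        flags.append(";".join(rules))
    records = records.copy()
    if "excluded_by" in records:
        prev_flags = ["" if pd.isna(p) else str(p) for p in records["excluded_by"]]
    else:
        prev_flags = [""] * len(records)
    records["excluded_by"] = [
        ";".join(p for p in (prev, new) if p) for prev, new in zip(prev_flags, flags)
    ]
    keep = np.array([f == "" for f in flags])
    return FACutoffResult(
        retained=records[keep].reset_index(drop=True),
        excluded=records[~keep].reset_index(drop=True),
        upper_cutoff=upper,
    )
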