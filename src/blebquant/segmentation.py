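"""Cell-body and nucleus segmentation with nuclei-seeded under-segmentation
resolution.

Cell bodies come from the cytoplasm channel: Gaussian pre-smoothing, then a
global threshold set to ``threshold_factor`` times the mean intensity of the
dimmest ``dim_fraction`` of pixels (those pixels are taken to be background).
Nuclei come from the PST operator.  Connected cytoplasm components are kept
only if they contain exactly one nucleus; components holding two or more
nuclei are re-thresholded at a higher level and split by synchronized
region growing from nucleus-assigned seeds.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .config import PSTParams, SegmentationConfig, get_pst_preset
from .pst import pst_segment

__all__ = [
    "background_threshold",
    "segment_nuclei",
    "segment_cell_bodies",
    "resolve_undersegmentation",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def background_threshold(
    image: np.ndarray, dim_fraction: float = 0.20, threshold_factor: float = 2.0
) -> float:
    """Threshold = factor × mean of the dimmest ``dim_fraction`` of pixels.

    The dimmest ``floor(dim_fraction * N)`` pixels are selected by a stable
    sort (value ties broken by flattened pixel order), so the result is
    deterministic.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if not 0.0 < dim_fraction < 1.0:
        raise ValueError("dim_fraction must be in (0, 1)")
    k = int(dim_fraction * image.size)
    if k == 0:
        raise ValueError(
            f"dim_fraction {dim_fraction} selects zero of {image.size} pixels"
        )
    flat = image.ravel()
    dimmest = flat[np.argsort(flat, kind="stable")[:k]]
    return float(threshold_factor * dimmest.mean())


def segment_nuclei(
    nuclei_channel: np.ndarray,
    config: SegmentationConfig | None = None,
    pst_params: PSTParams | None = None,
) -> np.ndarray:
    """Label map of nuclei via the PST nuclei preset (hole-filled, size-filtered)."""
    config = config or SegmentationConfig()
    params = pst_params or get_pst_preset(config.nuclei_preset)
    return pst_segment(nuclei_channel, params)


def _nucleus_ids_in(region_mask: np.ndarray, nucleus_labels: np.ndarray,
                    majority: float) -> list[int]:
    """Nuclei whose area lies mostly (> ``majority``) inside the region."""
    ids = []
    inside = nucleus_labels[region_mask]
    candidates = np.unique(inside[inside > 0])
    if candidates.size == 0:
        return ids
    full = np.bincount(nucleus_labels.ravel())
    part = np.bincount(inside, minlength=full.size)
    for nid in candidates:
        if part[nid] > majority * full[nid]:
            ids.append(int(nid))
    return ids


def segment_cell_bodies(
    cytoplasm_channel: np.ndarray,
    nuclei_labels: np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Label map of single cells, one nucleus each.

    Components with no (majority-contained) nucleus are dropped as debris;
    components with two or more are split by
    :func:`resolve_undersegmentation`; with ``border_policy='drop'`` cells
    touching the image border are removed.
    """
    config = config or SegmentationConfig()
    image = np.asarray(cytoplasm_channel, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(image, config.smooth_sigma)
    thr = background_threshold(smoothed, config.dim_fraction, config.threshold_factor)
    mask = smoothed > thr
    comps = cc_label(mask, connectivity=2)

    out = np.zeros_like(comps)
    next_label = 1
    n_dropped_nuclei_rule = 0
    for cid in range(1, comps.max() + 1):
        region = comps == cid
        if region.sum() < config.min_cell_area:
            continue
        nuc_ids = _nucleus_ids_in(region, nuclei_labels, config.nucleus_majority_fraction)
        if len(nuc_ids) == 0:
            n_dropped_nuclei_rule += 1
            continue
        if len(nuc_ids) == 1:
            pieces = region.astype(np.int32)
        else:
            sub_nuclei = np.where(np.isin(nuclei_labels, nuc_ids), nuclei_labels, 0)
            pieces = resolve_undersegmentation(
                region, sub_nuclei, smoothed, config, base_threshold=thr
            )
        for pid in range(1, int(pieces.max()) + 1):
            pmask = pieces == pid
            if not pmask.any():
                continue
            piece_nuclei = _nucleus_ids_in(
                pmask, nuclei_labels, config.nucleus_majority_fraction
            )
            if len(piece_nuclei) != 1:
                n_dropped_nuclei_rule += 1
                continue
            if config.border_policy == "drop" and _touches_border(pmask):
                continue
            out[pmask] = next_label
            next_label += 1
    if n_dropped_nuclei_rule:
        logger.info(
            "segment_cell_bodies: dropped %d region(s) by the 0/multiple-nuclei rule",
            n_dropped_nuclei_rule,
        )
    return out


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def resolve_undersegmentation(
    region_mask: np.ndarray,
    contained_nuclei: np.ndarray,
    cytoplasm_channel: np.ndarray,
    config: SegmentationConfig | None = None,
    base_threshold: float | None = None,
) -> np.ndarray:
    """Split a multi-nucleus region into one label per nucleus.

    The region is re-thresholded at ``reseg_factor`` × the original
    threshold; each resulting sub-component becomes the seed of the nucleus
    it overlaps most.  Seeds then grow by synchronized breadth-first geodesic
    dilation restricted to the region: a frontier claims unvisited pixels
    each iteration; pixels reached by several frontiers in the same iteration
    go to the seed with the nearer nucleus centroid (Euclidean), remaining
    ties to the lower label.  The output labels partition ``region_mask``.
    """
    config = config or SegmentationConfig()
    region_mask = np.asarray(region_mask, dtype=bool)
    nuc_ids = np.unique(contained_nuclei[region_mask])
    nuc_ids = nuc_ids[nuc_ids > 0]
    if nuc_ids.size < 2:
        raise ValueError("resolve_undersegmentation needs a region with >= 2 nuclei")
    image = np.asarray(cytoplasm_channel, dtype=np.float64)
    if base_threshold is None:
        base_threshold = background_threshold(
            image, config.dim_fraction, config.threshold_factor
        )
    high = config.reseg_factor * base_threshold

    centroids = {}
    for nid in nuc_ids:
        rows, cols = np.nonzero((contained_nuclei == nid) & region_mask)
        centroids[int(nid)] = (rows.mean(), cols.mean())

    # seeds from the higher threshold, assigned to their majority nucleus
    sub = cc_label((image > high) & region_mask, connectivity=2)
    seeds = np.zeros(region_mask.shape, dtype=np.int32)
    seeded = set()
    for sid in range(1, sub.max() + 1):
        smask = sub == sid
        overlap = contained_nuclei[smask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        nid = int(np.bincount(overlap).argmax())
        seeds[smask] = nid
        seeded.add(nid)
    if len(seeded) < nuc_ids.size:
        logger.warning(
            "resolve_undersegmentation: higher threshold seeded %d of %d nuclei; "
            "falling back to nucleus masks as seeds",
            len(seeded),
            nuc_ids.size,
        )
        seeds = np.where(region_mask, contained_nuclei, 0).astype(np.int32)

    labels = np.where(region_mask, seeds, 0).astype(np.int32)
    order = [int(n) for n in nuc_ids]  # ascending; lower label wins final ties
    for _ in range(config.max_grow_iters):
        free = region_mask & (labels == 0)
        if not free.any():
            break
        claims = []  # (label, proposal mask) for this synchronized step
        for nid in order:
            grown = ndimage.binary_dilation(labels == nid, structure=_STRUCT8)
            claims.append((nid, grown & free))
        n_claims = np.zeros(region_mask.shape, dtype=np.int16)
        for _, prop in claims:
            n_claims += prop
        newly = n_claims > 0
        if not newly.any():
            # seeds cannot reach remaining pixels (disconnected remnant):
            # assign them by nearest nucleus centroid
            rows, cols = np.nonzero(free)
            best = _nearest_centroid(rows, cols, order, centroids)
            labels[rows, cols] = best
            break
        unique = n_claims == 1
        for nid, prop in claims:
            labels[prop & unique] = nid
        contested = n_claims > 1
        if contested.any():
            rows, cols = np.nonzero(contested)
            cand = np.zeros((len(order), rows.size), dtype=bool)
            for i, (_, prop) in enumerate(claims):
                cand[i] = prop[rows, cols]
            best = _nearest_centroid(rows, cols, order, centroids, cand)
            labels[rows, cols] = best
    # map nucleus ids to sequential labels 1..n
    remap = {nid: i + 1 for i, nid in enumerate(order)}
    out = np.zeros_like(labels)
    for nid, new in remap.items():
        out[labels == nid] = new
    return out


def _nearest_centroid(rows, cols, order, centroids, cand=None):
    """Per-pixel nearest nucleus centroid among candidate labels."""
    dists = np.full((len(order), rows.size), np.inf)
    for i, nid in enumerate(order):
        cy, cx = centroids[nid]
        d = np.hypot(rows - cy, cols - cx)
        if cand is not None:
            d = np.where(cand[i], d, np.inf)
        dists[i] = d
    # argmin returns the first (lowest label index) on ties
    return np.array([order[i] for i in np.argmin(dists, axis=0)], dtype=np.int32)
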