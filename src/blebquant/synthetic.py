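"""Seeded synthetic 3-channel fluorescence scenes with full ground truth.

The generator emulates the geometry the downstream pipeline assumes: smooth
ellipse-like fibroblasts versus "blebby" cells whose outline carries bead-like
semicircular membrane protrusions; one nucleus per cell; punctate focal
adhesions in the cytoplasm over a diffuse background; Gaussian and optional
Poisson (shot) noise.  Every stochastic draw flows through a single
``numpy.random.Generator`` seeded from ``SceneParams.seed``, so a parameter
set is a pure specification of its scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .config import SceneParams

__all__ = ["SceneTruth", "make_cell_outline", "generate_scene", "add_noise"]


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``cell_masks``/``nucleus_masks`` are per-cell boolean images (full frame);
    ``fa_masks[i]`` lists the spot masks of cell ``i``.  ``touching_pairs``
    are index pairs rendered adjacent so that plain thresholding merges them.
    """

    cell_masks: list = field(default_factory=list)
    nucleus_masks: list = field(default_factory=list)
    blebbing_labels: list = field(default_factory=list)
    fa_masks: list = field(default_factory=list)
    touching_pairs: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_masks)


# ---------------------------------------------------------------------------
# Outline geometry
# ---------------------------------------------------------------------------

def _radial_outline(
    radius: float,
    blebbing: bool,
    n_blebs: int,
    amplitude_fraction: float,
    rng: np.random.Generator,
    n_points: int,
    aspect: float,
    wobble_amplitude: float,
    wobble_max_freq: int,
) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    # elliptical base with equal-area normalization: a*b = radius^2
    a = radius * np.sqrt(aspect)
    b = radius / np.sqrt(aspect)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    r_base = a * b / np.sqrt(
        (b * np.cos(theta + phase)) ** 2 + (a * np.sin(theta + phase)) ** 2
    )
    if blebbing:
        rho = amplitude_fraction * radius  # bead radius, px
        centers = (np.arange(n_blebs) + rng.uniform(-0.2, 0.2, n_blebs)) * (
            2.0 * np.pi / n_blebs
        ) + rng.uniform(0.0, 2.0 * np.pi)
        bump = np.zeros_like(theta)
        for c in centers:
            # angular half-width such that the arc subtends the bead diameter
            half = rho / radius
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped angular distance
            sel = np.abs(d) < half
            # semicircular (bead) radial profile in the small-angle limit
            bump[sel] = np.maximum(
                bump[sel], np.sqrt(np.maximum(rho**2 - (radius * d[sel]) ** 2, 0.0))
            )
        r = r_base + bump
    else:
        r = r_base.copy()
        if wobble_amplitude > 0:
            for k in range(2, wobble_max_freq + 1):
                amp = rng.uniform(0.0, wobble_amplitude) * radius
                r += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
    return np.column_stack([r * np.sin(theta), r * np.cos(theta)])  # (row, col)


def _is_simple(poly: np.ndarray) -> bool:
    # outlines are radial functions r(theta) about the origin; they are
    # simple iff r stays strictly positive
    return bool(np.all(np.hypot(poly[:, 0], poly[:, 1]) > 1.0))


def make_cell_outline(
    radius: float,
    blebbing: bool,
    n_blebs: int = 0,
    amplitude_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    n_points: int = 720,
    aspect: float = 1.0,
    wobble_amplitude: float = 0.0,
    wobble_max_freq: int = 4,
    max_retries: int = 5,
) -> np.ndarray:
    """Closed simple polygon (rows, cols about the origin) for one cell.

    Blebbing outlines superpose ``n_blebs`` semicircular bead protrusions of
    radius ``amplitude_fraction * radius`` on an equal-area elliptical base;
    smooth outlines are ellipses with an optional mild low-frequency radial
    wobble.  With ``aspect=1`` and ``wobble_amplitude=0`` a non-blebbing
    outline is an exact circle.
    """
    if radius < 10:
        raise ValueError("radius must be >= 10 px")
    if blebbing:
        if n_blebs < 3:
            raise ValueError("blebbing outlines need n_blebs >= 3")
        if not 0.0 < amplitude_fraction < 1.0:
            raise ValueError("amplitude_fraction must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    amp = amplitude_fraction
    wob = wobble_amplitude
    for _ in range(max_retries):
        poly = _radial_outline(
            radius, blebbing, n_blebs, amp, rng, n_points, aspect, wob, wobble_max_freq
        )
        if _is_simple(poly):
            return poly
        amp *= 0.5
        wob *= 0.5
    raise RuntimeError("could not generate a simple outline within retry budget")


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def add_noise(
    image: np.ndarray,
    gaussian_sd: float,
    poisson: bool,
    rng: np.random.Generator,
    *,
    clip_max: float = 65535.0,
) -> np.ndarray:
    """Additive Gaussian and optional Poisson shot noise, clipped to range.

    ``gaussian_sd == 0`` with ``poisson=False`` is the identity.
    """
    if gaussian_sd < 0:
        raise ValueError("gaussian_sd must be >= 0")
    out = np.asarray(image, dtype=np.float64)
    if poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    if poisson or gaussian_sd > 0:
        out = np.clip(out, 0.0, clip_max)
    return out


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr * rr + cc * cc <= radius * radius


def _place_centers(params: SceneParams, radii, rng):
    """Rejection-sample cell centers; touching pairs are placed as units."""
    h, w = params.image_height, params.image_width
    # conservative outer extent: elliptical semi-major axis plus bead and
    # wobble excursions, so non-touching masks stay >= 2 px apart
    outer = [
        r * np.sqrt(params.aspect_max) * (1.0 + params.bleb_amplitude_fraction)
        + 3.0 * params.smooth_wobble_amplitude * r
        + 2.0
        for r in radii
    ]
    n = len(radii)
    n_pairs = int(round(params.touching_pair_fraction * n / 2.0))
    pair_members = set()
    pairs = []
    for k in range(n_pairs):
        pairs.append((2 * k, 2 * k + 1))
        pair_members.update((2 * k, 2 * k + 1))
    centers: list[np.ndarray | None] = [None] * n

    def ok(idx, cand):
        margin = outer[idx] + 8.0
        if not (margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin):
            return False
        for j, c in enumerate(centers):
            if c is None or j == idx:
                continue
            if (idx, j) in pairs or (j, idx) in pairs:
                continue
            if np.hypot(*(cand - c)) < outer[idx] + outer[j] + 4.0:
                return False
        return True

    for i, j in pairs:
        placed = False
        for _ in range(3000):
            cand_i = rng.uniform([0, 0], [h, w])
            ang = rng.uniform(0.0, 2.0 * np.pi)
            d = 0.92 * (radii[i] + radii[j])
            cand_j = cand_i + d * np.array([np.sin(ang), np.cos(ang)])
            centers[i], centers[j] = cand_i, cand_j
            if ok(i, cand_i) and ok(j, cand_j):
                placed = True
                break
            centers[i] = centers[j] = None
        if not placed:
            raise RuntimeError(
                f"could not place touching pair {i},{j}: cell density too high "
                f"for a {h}x{w} image"
            )
    for i in range(n):
        if i in pair_members:
            continue
        placed = False
        for _ in range(3000):
            cand = rng.uniform([0, 0], [h, w])
            if ok(i, cand):
                centers[i] = cand
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i}: {n} cells of radius ~{params.cell_radius_mean:.0f}"
                f" px exceed the density limit of a {h}x{w} image"
            )
    return centers, pairs


def _place_fas(cell_mask, nucleus_mask, n_fas, area_range, min_sep, rng, shape):
    """Sample non-overlapping FA disks inside the cell, outside the nucleus."""
    from scipy import ndimage

    placed = []
    radii = []
    centers = []
    rows, cols = np.nonzero(cell_mask)
    # pad the crop so the distance transform sees background on every side
    r0, r1 = max(rows.min() - 1, 0), min(rows.max() + 2, shape[0])
    c0, c1 = max(cols.min() - 1, 0), min(cols.max() + 2, shape[1])
    interior = cell_mask[r0:r1, c0:c1] & ~ndimage.binary_dilation(
        nucleus_mask[r0:r1, c0:c1], iterations=3
    )
    dist_in = ndimage.distance_transform_edt(interior)
    for _ in range(n_fas):
        area = rng.uniform(*area_range)
        r = float(np.sqrt(area / np.pi))
        cand_rows, cand_cols = np.nonzero(dist_in > r + 2.0)
        if cand_rows.size == 0:
            break
        for _attempt in range(200):
            k = rng.integers(cand_rows.size)
            c = np.array([cand_rows[k] + r0, cand_cols[k] + c0], dtype=float)
            if all(
                np.hypot(*(c - pc)) >= r + pr + min_sep for pc, pr in zip(centers, radii)
            ):
                mask = _disk_mask(shape, c, r)
                placed.append(mask)
                centers.append(c)
                radii.append(r)
                break
    return placed


def generate_scene(params: SceneParams):
    """Render one field of view; returns ``(channels, truth)``.

    ``channels`` is a dict with float64 images ``cytoplasm``, ``nuclei`` and
    ``adhesion``; ``truth`` the matching :class:`SceneTruth`.  Noise (set by
    ``params.noise_sd`` / ``params.poisson_noise``) is applied last, so a
    noise-free render is piecewise-constant at the configured intensities.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    shape = (h, w)
    ci = params.channel_intensities
    truth = SceneTruth()

    cyto = np.full(shape, ci.cyto_background, dtype=np.float64)
    nuc = np.full(shape, ci.nuclei_background, dtype=np.float64)
    adh = np.full(shape, ci.adhesion_background, dtype=np.float64)

    n = params.n_cells
    if n == 0:
        for img, sd in ((cyto, params.noise_sd), (nuc, params.noise_sd), (adh, params.noise_sd)):
            img[:] = add_noise(img, sd, params.poisson_noise, rng)
        return {"cytoplasm": cyto, "nuclei": nuc, "adhesion": adh}, truth

    radii = np.clip(
        rng.normal(params.cell_radius_mean, params.cell_radius_sd, n),
        params.cell_radius_min,
        params.cell_radius_max,
    )
    n_bleb = int(round(params.blebbing_fraction * n))
    bleb_flags = np.zeros(n, dtype=bool)
    bleb_flags[rng.permutation(n)[:n_bleb]] = True

    centers, pairs = _place_centers(params, radii, rng)
    truth.touching_pairs = list(pairs)

    cell_masks = []
    for i in range(n):
        n_blebs = int(rng.integers(params.n_blebs_range[0], params.n_blebs_range[1] + 1))
        poly = make_cell_outline(
            float(radii[i]),
            bool(bleb_flags[i]),
            n_blebs,
            params.bleb_amplitude_fraction,
            rng,
            aspect=rng.uniform(1.0, params.aspect_max),
            wobble_amplitude=params.smooth_wobble_amplitude,
            wobble_max_freq=params.smooth_wobble_max_freq,
        )
        cell_masks.append(polygon2mask(shape, poly + centers[i]))

    # touching pairs may overlap: assign contested pixels to the nearer center
    for i, j in pairs:
        overlap = cell_masks[i] & cell_masks[j]
        if overlap.any():
            rows, cols = np.nonzero(overlap)
            di = np.hypot(rows - centers[i][0], cols - centers[i][1])
            dj = np.hypot(rows - centers[j][0], cols - centers[j][1])
            to_j = dj < di
            cell_masks[i][rows[to_j], cols[to_j]] = False
            cell_masks[j][rows[~to_j], cols[~to_j]] = False

    for i in range(n):
        mask = cell_masks[i]
        nucleus = _disk_mask(
            shape, centers[i], params.nucleus_radius_fraction * radii[i]
        )
        nucleus &= mask  # nucleus stays inside the (possibly clipped) cell
        n_fas = int(rng.integers(params.n_fas_range[0], params.n_fas_range[1] + 1))
        fas = _place_fas(
            mask, nucleus, n_fas, params.fa_area_range, params.fa_min_separation, rng, shape
        )
        truth.cell_masks.append(mask)
        truth.nucleus_masks.append(nucleus)
        truth.blebbing_labels.append(bool(bleb_flags[i]))
        truth.fa_masks.append(fas)

        cyto[mask] = ci.cyto_foreground
        nuc[nucleus] = ci.nuclei_foreground
        adh[mask] = ci.adhesion_cytoplasm
        adh[nucleus] = (
            ci.adhesion_nucleus_blebby if bleb_flags[i] else ci.adhesion_nucleus_smooth
        )
        for fa in fas:
            adh[fa] = ci.adhesion_fa

    cyto = add_noise(cyto, params.noise_sd, params.poisson_noise, rng)
    nuc = add_noise(nuc, params.noise_sd, params.poisson_noise, rng)
    adh = add_noise(adh, params.noise_sd, params.poisson_noise, rng)
    return {"cytoplasm": cyto, "nuclei": nuc, "adhesion": adh}, truth
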