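"""Phase stretch transform (PST) feature operator and segmentation.

The PST applies, in the 2-D frequency domain, a radially symmetric warped
phase kernel

    phi(r) ∝ W·r·arctan(W·r) − ½·ln(1 + (W·r)²)

normalized so that max phi equals ``phase_strength``, after Gaussian
frequency-domain localization (low-pass) of width ``lpf_sigma``.  The angle of
the inverse transform highlights edges and small features; thresholding the
phase followed by morphological cleanup yields a label map.  Thresholds are
phase quantiles by default, making the segmentation invariant to linear
intensity scaling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, opening, thin

from .config import PSTParams, get_pst_preset

__all__ = ["pst_phase", "pst_segment", "apply_morphology"]


def _freq_radius(shape) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.hypot(fy, fx)


def pst_phase(image: np.ndarray, params: PSTParams) -> np.ndarray:
    """Phase image (radians, in (−π, π]) of the PST operator."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("pst_phase expects a 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("pst_phase requires finite pixel values")
    r = _freq_radius(image.shape)
    # Gaussian frequency-domain localization (low-pass)
    lpf = np.exp(-0.5 * (r / params.lpf_sigma) ** 2)
    wr = params.warp_strength * r / r.max() if r.max() > 0 else r
    phi = wr * np.arctan(wr) - 0.5 * np.log1p(wr**2)
    peak = phi.max()
    if peak > 0:
        phi = phi * (params.phase_strength / peak)
    spectrum = np.fft.fft2(image) * lpf * np.exp(-1j * phi)
    return np.angle(np.fft.ifft2(spectrum))


def apply_morphology(mask: np.ndarray, ops) -> np.ndarray:
    """Apply an ordered list of (op, radius) cleanup steps to a binary mask."""
    out = mask.astype(bool)
    for op, radius in ops:
        if op == "open":
            out = opening(out, disk(radius))
        elif op == "close":
            out = closing(out, disk(radius))
        elif op == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        elif op == "thin":
            out = thin(out)
        else:  # pragma: no cover - validated upstream
            raise ValueError(f"unknown morphology op {op!r}")
    return out


def pst_segment(image: np.ndarray, params: PSTParams | str) -> np.ndarray:
    """Segment features via PST phase thresholding; returns a label map.

    Pixels whose phase exceeds the high threshold (or falls below the low
    threshold, when set) are kept, cleaned by ``params.morphology_ops``,
    labeled with 8-connectivity, and components smaller than
    ``min_region_area`` are removed.  An all-background result is a valid
    empty label map.
    """
    if isinstance(params, str):
        params = get_pst_preset(params)
    phase = pst_phase(image, params)
    mask = np.zeros(phase.shape, dtype=bool)
    if params.threshold_mode == "quantile":
        if params.phase_threshold_high is not None:
            hi = np.quantile(phase, params.phase_threshold_high)
            mask |= phase > max(hi, params.min_phase_floor)
        if params.phase_threshold_low is not None:
            lo = np.quantile(phase, params.phase_threshold_low)
            mask |= phase < min(lo, -params.min_phase_floor)
    else:
        if params.phase_threshold_high is not None:
            mask |= phase > params.phase_threshold_high
        if params.phase_threshold_low is not None:
            mask |= phase < params.phase_threshold_low
    mask = apply_morphology(mask, params.morphology_ops)
    labels = cc_label(mask, connectivity=2)
    if labels.max() > 0 and params.min_region_area > 1:
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < params.min_region_area)[0]
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = _relabel_sequential(labels)
    return labels


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    values = np.unique(labels)
    values = values[values > 0]
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    lut[values] = np.arange(1, values.size + 1)
    return lut[labels]
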