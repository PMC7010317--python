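"""Parameter containers for every pipeline stage, plus YAML config loading.

All tunables live here so that a single YAML file fully determines a run.
Each dataclass validates its own invariants on construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml


# ---------------------------------------------------------------------------
# Synthetic scenes
# ---------------------------------------------------------------------------

@dataclass
class ChannelIntensities:
    """Mean rendered intensities (arbitrary 16-bit-range units) per channel.

    The adhesion channel distinguishes the nuclear level of smooth vs blebby
    cells: blebby cells carry a cytoplasm-dominant adhesion-marker signal
    (nuc/cyto ratio well below 1), smooth cells a nucleus-dominant one, so the
    intensity-ratio criterion of the blebbing classifier is exercised.
    """

    cyto_background: float = 200.0
    cyto_foreground: float = 1000.0
    nuclei_background: float = 150.0
    nuclei_foreground: float = 3000.0
    adhesion_background: float = 150.0
    adhesion_cytoplasm: float = 300.0
    adhesion_nucleus_smooth: float = 800.0
    adhesion_nucleus_blebby: float = 250.0
    adhesion_fa: float = 2000.0


@dataclass
class SceneParams:
    """Parameters of one synthetic 3-channel field of view.

    Identical parameters (including ``seed``) always produce an identical
    scene: all randomness flows through one ``numpy.random.Generator``.
    """

    image_height: int = 1024
    image_width: int = 1024
    n_cells: int = 10
    blebbing_fraction: float = 0.5
    cell_radius_mean: float = 55.0
    cell_radius_sd: float = 6.0
    cell_radius_min: float = 42.0
    cell_radius_max: float = 70.0
    nucleus_radius_fraction: float = 0.55
    n_blebs_range: tuple[int, int] = (8, 14)
    bleb_amplitude_fraction: float = 0.15
    smooth_wobble_amplitude: float = 0.03
    smooth_wobble_max_freq: int = 4
    aspect_max: float = 1.25
    n_fas_range: tuple[int, int] = (6, 12)
    fa_area_range: tuple[float, float] = (60.0, 150.0)
    fa_min_separation: float = 10.0
    touching_pair_fraction: float = 0.0
    channel_intensities: ChannelIntensities = field(default_factory=ChannelIntensities)
    noise_sd: float = 25.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.blebbing_fraction <= 1.0:
            raise ValueError("blebbing_fraction must be in [0, 1]")
        if not 0.0 <= self.touching_pair_fraction <= 1.0:
            raise ValueError("touching_pair_fraction must be in [0, 1]")
        if self.cell_radius_mean <= 0 or self.cell_radius_min <= 0:
            raise ValueError("cell radii must be positive")
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if not 0.0 <= self.bleb_amplitude_fraction < 1.0:
            raise ValueError("bleb_amplitude_fraction must be in [0, 1)")
        if self.n_blebs_range[0] > self.n_blebs_range[1] or self.n_blebs_range[0] < 0:
            raise ValueError("n_blebs_range must be a non-negative interval")
        if self.n_fas_range[0] > self.n_fas_range[1] or self.n_fas_range[0] < 0:
            raise ValueError("n_fas_range must be a non-negative interval")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Phase stretch transform
# ---------------------------------------------------------------------------

@dataclass
class PSTParams:
    """Tuning of the phase-stretch-transform feature operator.

    ``lpf_sigma`` is the width (cycles/pixel) of the Gaussian frequency-domain
    localization kernel applied before the warped-phase kernel; smaller values
    smooth more.  Thresholds are phase quantiles by default (``threshold_mode
    == 'quantile'``), which makes the segmentation invariant to intensity
    scaling; ``'absolute'`` interprets them as radians.
    """

    lpf_sigma: float = 0.1
    phase_strength: float = 0.5
    warp_strength: float = 12.0
    phase_threshold_low: Optional[float] = 0.02
    phase_threshold_high: Optional[float] = None
    threshold_mode: str = "quantile"
    min_phase_floor: float = 1e-4
    min_region_area: int = 50
    morphology_ops: Sequence[tuple[str, int]] = field(
        default_factory=lambda: (("close", 2), ("fill_holes", 0), ("open", 2))
    )

    def __post_init__(self) -> None:
        if self.lpf_sigma <= 0:
            raise ValueError("lpf_sigma must be > 0")
        if self.phase_strength <= 0:
            raise ValueError("phase_strength must be > 0")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")
        if self.threshold_mode not in ("quantile", "absolute"):
            raise ValueError("threshold_mode must be 'quantile' or 'absolute'")
        if self.phase_threshold_low is None and self.phase_threshold_high is None:
            raise ValueError("at least one phase threshold must be set")
        if (
            self.phase_threshold_low is not None
            and self.phase_threshold_high is not None
            and self.phase_threshold_low > self.phase_threshold_high
        ):
            raise ValueError("phase thresholds must be ordered low <= high")
        for op, radius in self.morphology_ops:
            if op not in ("open", "close", "fill_holes", "thin"):
                raise ValueError(f"unknown morphology op {op!r}")
            if radius < 0:
                raise ValueError("structuring-element radius must be >= 0")


#: Named PST presets.  The source method leaves these operator settings as
#: empirical per-target optimizations; the shipped values were tuned on the
#: synthetic fixtures of this package (see docs/methods.md).
PST_PRESETS: dict[str, PSTParams] = {}


def _register_presets() -> None:
    PST_PRESETS["nuclei"] = PSTParams(
        lpf_sigma=0.05,
        phase_strength=0.5,
        warp_strength=12.0,
        phase_threshold_low=0.02,
        phase_threshold_high=None,
        min_region_area=200,
        morphology_ops=(("close", 3), ("fill_holes", 0), ("open", 3)),
    )
    PST_PRESETS["fa"] = PSTParams(
        lpf_sigma=0.25,
        phase_strength=0.5,
        warp_strength=12.0,
        phase_threshold_low=0.02,
        phase_threshold_high=None,
        min_region_area=10,
        morphology_ops=(("close", 1), ("fill_holes", 0)),
    )


_register_presets()


def get_pst_preset(name: str) -> PSTParams:
    try:
        return dataclasses.replace(PST_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown PST preset {name!r}; available: {sorted(PST_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Cell-body segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    """Cell-body segmentation from the cytoplasm channel.

    The background threshold is ``threshold_factor`` times the mean of the
    dimmest ``dim_fraction`` of pixels; regions whose nucleus count differs
    from one are dropped or re-split (``reseg_factor`` raises the threshold
    for re-segmentation of multi-nucleus regions).
    """

    smooth_sigma: float = 2.0
    dim_fraction: float = 0.20
    threshold_factor: float = 2.0
    reseg_factor: float = 1.5
    max_grow_iters: int = 500
    border_policy: str = "drop"
    min_cell_area: int = 500
    nucleus_majority_fraction: float = 0.5
    nuclei_preset: str = "nuclei"

    def __post_init__(self) -> None:
        if not 0.0 < self.dim_fraction < 1.0:
            raise ValueError("dim_fraction must be in (0, 1)")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.reseg_factor <= 1.0:
            raise ValueError("reseg_factor must be > 1")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")


# ---------------------------------------------------------------------------
# Morphometry / blebbing classification
# ---------------------------------------------------------------------------

@dataclass
class BlebbingThresholds:
    """Cutoffs of the three-feature blebbing rule and the outlier filters.

    A cell is called blebbing when mean boundary curvature exceeds
    ``curvature_min`` (px⁻¹) AND the nuclear/cytoplasmic adhesion-marker
    intensity ratio is below ``intensity_ratio_max`` AND the cell/nucleus
    area ratio is below ``area_ratio_max`` (all strict).  Cells with a
    DAPI-positive area under ``nucleus_area_min`` px or a cell area over
    ``cell_area_max`` px are excluded as outliers before classification.
    """

    curvature_min: float = 0.029
    intensity_ratio_max: float = 1.15
    area_ratio_max: float = 4.5
    nucleus_area_min: float = 1000.0
    cell_area_max: float = 150000.0

    def __post_init__(self) -> None:
        for name in (
            "curvature_min",
            "intensity_ratio_max",
            "area_ratio_max",
            "nucleus_area_min",
            "cell_area_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MorphometryConfig:
    """Boundary smoothing and curvature sampling."""

    savgol_window: int = 9
    savgol_polyorder: int = 3
    #: triplet half-spacing, in boundary samples, for the circumradius
    #: estimator; at the native sub-pixel contour spacing (~0.7 px) a spacing
    #: of 8 spans ~5 px chords, long enough that pixel quantization cancels
    #: while bead-scale protrusions (radius >= ~5 px) still register
    curvature_step: int = 8

    def __post_init__(self) -> None:
        if self.savgol_window % 2 != 1:
            raise ValueError("savgol_window must be odd")
        if self.savgol_window <= self.savgol_polyorder:
            raise ValueError("savgol_window must exceed savgol_polyorder")
        if self.curvature_step < 1:
            raise ValueError("curvature_step must be >= 1")


# ---------------------------------------------------------------------------
# Focal adhesions
# ---------------------------------------------------------------------------

@dataclass
class FAConfig:
    """Focal-adhesion segmentation filters and per-dataset count cutoffs."""

    fa_preset: str = "fa"
    min_fa_area: int = 30
    intensity_rule: str = "cell_mean"
    upper_percentile: float = 99.0
    lower_count_max: int = 4
    percentile_method: str = "linear_interpolation"

    def __post_init__(self) -> None:
        if self.min_fa_area < 1:
            raise ValueError("min_fa_area must be >= 1")
        if not 0.0 < self.upper_percentile <= 100.0:
            raise ValueError("upper_percentile must be in (0, 100]")
        if self.lower_count_max < 0:
            raise ValueError("lower_count_max must be >= 0")
        if self.intensity_rule != "cell_mean":
            raise ValueError("only the 'cell_mean' intensity rule is supported")
        if self.percentile_method != "linear_interpolation":
            raise ValueError("only 'linear_interpolation' percentiles are supported")


# ---------------------------------------------------------------------------
# YAML plumbing
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "scene": SceneParams,
    "segmentation": SegmentationConfig,
    "morphometry": MorphometryConfig,
    "thresholds": BlebbingThresholds,
    "fa": FAConfig,
}


@dataclass
class PipelineConfig:
    """Bundle of every stage's parameters, as read from one YAML file."""

    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    thresholds: BlebbingThresholds = field(default_factory=BlebbingThresholds)
    fa: FAConfig = field(default_factory=FAConfig)
    pst: dict[str, PSTParams] = field(default_factory=lambda: dict(PST_PRESETS))


def _build(cls, mapping: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        if key == "channel_intensities" and isinstance(value, dict):
            value = ChannelIntensities(**value)
        elif isinstance(value, list) and key in ("n_blebs_range", "n_fas_range", "fa_area_range"):
            value = tuple(value)
        elif key == "morphology_ops" and isinstance(value, list):
            value = tuple((op, int(r)) for op, r in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a pipeline YAML config; omitted sections take the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            setattr(cfg, section, _build(cls, raw[section]))
    for name, mapping in (raw.get("pst") or {}).items():
        base = dataclasses.asdict(PST_PRESETS[name]) if name in PST_PRESETS else {}
        base.update(mapping)
        if "morphology_ops" in base and isinstance(base["morphology_ops"], list):
            base["morphology_ops"] = tuple((op, int(r)) for op, r in base["morphology_ops"])
        cfg.pst[name] = PSTParams(**base)
    return cfg
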