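"""Pipeline parameter containers and YAML config round-tripping.

Every tunable of the analysis pipeline lives here with its default value.
The defaults are the reference settings of the cytospin workflow:
global two-class Otsu thresholding with a smoothing scale of 1.3488 and a
correction factor of 0.7 (primary) / 0.9 (secondary), a 16-60 px nucleus
diameter gate, a nucleus circularity (FormFactor) cut-off of 0.599, a
propagation regularization factor lambda = 0.1, and cell-body filters of
Area >= 28 px^2, FormFactor >= 0.35 and VIME mean intensity >= 9e-6.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

#: Divisor that maps the conventional smoothing scale onto a Gaussian sigma in
#: pixels: a smoothing scale of 1.3488 corresponds to sigma = 1 px.
SMOOTHING_SCALE_UNIT = 1.3488


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class PrimarySegmentationParams:
    """Settings for identifying intact cell nuclei from the DAPI channel.

    Parameters
    ----------
    min_diameter, max_diameter : float
        Accepted object equivalent-diameter range in pixels (default 16-60).
    smoothing_scale : float
        Pre-threshold smoothing scale; sigma = smoothing_scale / 1.3488 px.
    threshold_correction : float
        Multiplier applied to the Otsu threshold (0.7 = more lenient).
    threshold_bounds : (float, float)
        Lower/upper clamp for the corrected threshold.
    min_form_factor : float
        Circularity cut-off separating intact ("real") nuclei from burst
        nuclei; FormFactor = 4*pi*Area/Perimeter^2.
    distance_smoothing_sigma : float, optional
        Sigma for smoothing the distance transform before maxima detection.
        ``None`` selects max(1, min_diameter / 7).
    """

    min_diameter: float = 16.0
    max_diameter: float = 60.0
    smoothing_scale: float = 1.3488
    threshold_correction: float = 0.7
    threshold_bounds: Tuple[float, float] = (0.0, 1.0)
    min_form_factor: float = 0.599
    exclude_border: bool = True
    fill_holes: bool = True
    distance_smoothing_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.min_diameter <= self.max_diameter:
            raise ValueError("require 0 < min_diameter <= max_diameter")
        lo, hi = self.threshold_bounds
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("threshold_bounds must satisfy 0 <= lo <= hi <= 1")
        if self.threshold_correction <= 0:
            raise ValueError("threshold_correction must be > 0")
        if not 0.0 <= self.min_form_factor <= 1.0:
            raise ValueError("min_form_factor outside nominal [0, 1] range")

    @property
    def sigma(self) -> float:
        """Gaussian sigma (px) implied by the smoothing scale."""
        return self.smoothing_scale / SMOOTHING_SCALE_UNIT

    @property
    def distance_sigma(self) -> float:
        if self.distance_smoothing_sigma is not None:
            return self.distance_smoothing_sigma
        return max(1.0, self.min_diameter / 7.0)


@dataclass
class SecondarySegmentationParams:
    """Settings for the seeded propagation of VIME+ cell bodies and the
    intact-cell filters applied to them."""

    threshold_correction: float = 0.9
    smoothing_scale: float = 1.3488
    threshold_bounds: Tuple[float, float] = (0.0, 1.0)
    regularization_lambda: float = 0.1
    min_body_area: float = 28.0
    min_body_form_factor: float = 0.35
    min_body_mean_intensity: float = 0.000009
    fill_holes: bool = True
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.regularization_lambda < 0:
            raise ValueError("regularization_lambda must be >= 0")
        if self.min_body_area < 1:
            raise ValueError("min_body_area must be >= 1")
        if self.threshold_correction <= 0:
            raise ValueError("threshold_correction must be > 0")
        lo, hi = self.threshold_bounds
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("threshold_bounds must satisfy 0 <= lo <= hi <= 1")

    @property
    def sigma(self) -> float:
        return self.smoothing_scale / SMOOTHING_SCALE_UNIT


@dataclass
class MarkerThresholds:
    """Operator-set mean-intensity thresholds for marker positivity.

    The cut-offs depend on staining intensity and are meant to be chosen per
    cytospin by inspecting the per-nucleus mean intensities; no universal
    default exists, hence ``None`` until set. With ``auto_suggest`` enabled
    an Otsu split of the observed per-nucleus means is applied instead.
    """

    sox10_min_mean_intensity: Optional[float] = None
    edu_min_mean_intensity: Optional[float] = None
    auto_suggest: bool = False

    def __post_init__(self) -> None:
        for name in ("sox10_min_mean_intensity", "edu_min_mean_intensity"):
            value = getattr(self, name)
            if value is not None:
                _check_fraction(name, value)


@dataclass
class PipelineConfig:
    """Aggregate of all pipeline tunables plus orchestration options."""

    primary: PrimarySegmentationParams = field(default_factory=PrimarySegmentationParams)
    secondary: SecondarySegmentationParams = field(default_factory=SecondarySegmentationParams)
    markers: MarkerThresholds = field(default_factory=MarkerThresholds)
    proliferation_denominator: str = "real_cells"
    output_dir: Optional[str] = None
    save_debug_images: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.proliferation_denominator not in ("real_cells", "sox10_cells"):
            raise ValueError(
                "proliferation_denominator must be 'real_cells' or 'sox10_cells'"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["primary"]["threshold_bounds"] = list(self.primary.threshold_bounds)
        d["secondary"]["threshold_bounds"] = list(self.secondary.threshold_bounds)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        primary = dict(d.pop("primary", {}))
        secondary = dict(d.pop("secondary", {}))
        markers = dict(d.pop("markers", {}))
        if "threshold_bounds" in primary:
            primary["threshold_bounds"] = tuple(primary["threshold_bounds"])
        if "threshold_bounds" in secondary:
            secondary["threshold_bounds"] = tuple(secondary["threshold_bounds"])
        return cls(
            primary=PrimarySegmentationParams(**primary),
            secondary=SecondarySegmentationParams(**secondary),
            markers=MarkerThresholds(**markers),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
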