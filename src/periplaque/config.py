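"""Run configuration: every tunable of the pipeline, in physical units.

All lengths are in micrometres and areas in square micrometres; they are
converted to pixels only at the point of use (see :func:`um_to_px` and
:func:`radius_um_to_px`).  The defaults mirror a standard FIJI-style plaque
analysis: a 2 μm Gaussian blur before plaque thresholding, a >50 μm² object
filter, a 5 μm peri-plaque band, a 3-puncta threshold for Aβ-positive
neurons and a 4-dystrophy threshold for neuritic plaques.  Constants the
published workflow leaves unstated (threshold method, soma-area windows,
puncta detector settings, classification cutoffs) are explicit config
fields so every run is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError

THRESHOLD_METHODS = ("otsu", "fixed_percentile", "fixed_value")

#: Channel names understood by the pipeline.
CHANNELS = ("abeta", "thios", "gfap", "iba1", "neun", "syp", "aqp4")


def um_to_px(length_um: float, pixel_size_um: float) -> float:
    """Convert a physical length to (fractional) pixels."""
    if pixel_size_um <= 0:
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return length_um / pixel_size_um


def radius_um_to_px(radius_um: float, pixel_size_um: float) -> int:
    """Structuring-element radius in whole pixels: round half up, minimum 1."""
    return max(1, int(math.floor(um_to_px(radius_um, pixel_size_um) + 0.5)))


@dataclass(frozen=True)
class ThresholdSpec:
    """How a channel is binarized.

    method:
        ``otsu`` (parameter-free, on the supplied image), ``fixed_percentile``
        (``value`` is a percentile in [0, 100]) or ``fixed_value`` (``value``
        is an absolute intensity).
    """

    method: str = "otsu"
    value: Optional[float] = None

    def validate(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValidationError(f"unknown threshold method {self.method!r}")
        if self.method != "otsu" and self.value is None:
            raise ValidationError(f"threshold method {self.method!r} needs a value")
        if self.method == "fixed_percentile" and not (0.0 <= self.value <= 100.0):
            raise ValidationError("percentile must lie in [0, 100]")


@dataclass(frozen=True)
class ClassificationParams:
    """Cutoffs of the dense-core / fibrillar / mixed rule.

    The published classification is visual ("very bright" vs "weaker"
    thioflavin S); these numeric surrogates are this package's own defaults,
    not published values.
    """

    core_thios_quantile: float = 0.90
    core_bright_ratio: float = 2.0
    min_core_frac: float = 0.25
    min_halo_frac: float = 0.25
    #: plaque thioS mean must exceed this multiple of the thioS background
    #: to be classified at all (else: unclassified).
    thios_background_factor: float = 1.5
    #: background-subtracted thioS:Aβ mean ratio above which a plaque with
    #: no internal core/halo contrast is called dense-core (else fibrillar).
    thios_abeta_ratio_min: float = 0.6
    #: morphological opening radius applied to the candidate core (μm).
    core_open_radius_um: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.core_thios_quantile < 1.0):
            raise ValidationError("core_thios_quantile must lie in (0, 1)")
        if self.core_bright_ratio <= 1.0:
            raise ValidationError("core_bright_ratio must exceed 1")
        for name in ("min_core_frac", "min_halo_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.thios_background_factor < 1.0:
            raise ValidationError("thios_background_factor must be >= 1")
        if self.thios_abeta_ratio_min <= 0:
            raise ValidationError("thios_abeta_ratio_min must be > 0")
        if self.core_open_radius_um <= 0:
            raise ValidationError("core_open_radius_um must be > 0")


def _default_thresholds() -> dict:
    return {name: ThresholdSpec() for name in CHANNELS}


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one analysis run (all physical units in μm)."""

    blur_radius_um: float = 2.0
    min_plaque_area_um2: float = 50.0
    band_width_um: float = 5.0
    thresholds: dict = field(default_factory=_default_thresholds)
    coverage_distance_um: float = 2.0
    neuron_search_radius_um: float = 50.0
    puncta_positive_threshold: int = 3
    dystrophy_positive_threshold: int = 4
    min_dystrophy_area_um2: float = 3.0
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    background_percentile: float = 1.0
    rng_seed: int = 0
    # soma-area windows (μm²) for automated counting
    microglia_soma_area_um2: tuple = (20.0, 500.0)
    neuron_soma_area_um2: tuple = (40.0, 400.0)
    # intracellular puncta detector
    puncta_tophat_radius_um: float = 1.5
    puncta_area_um2: tuple = (0.2, 5.0)
    puncta_contrast_factor: float = 2.0
    #: Gaussian denoise applied before the top-hat so shot-noise speckle
    #: does not register as puncta; small vs the punctum radius.
    puncta_smooth_sigma_um: float = 0.5
    # neuron splitting
    watershed_min_distance_um: float = 5.0
    # summaries
    exclude_border_plaques: bool = False
    min_plaques_per_mouse: int = 10
    # group statistics: Student (equal-variance) unpaired t by default
    equal_variance_ttest: bool = True

    def validate(self) -> "RunConfig":
        for name in (
            "blur_radius_um",
            "min_plaque_area_um2",
            "band_width_um",
            "coverage_distance_um",
            "neuron_search_radius_um",
            "min_dystrophy_area_um2",
            "puncta_tophat_radius_um",
            "watershed_min_distance_um",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("puncta_positive_threshold", "dystrophy_positive_threshold", "min_plaques_per_mouse"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValidationError(f"{name} must be a positive integer")
        if not (0.0 <= self.background_percentile <= 100.0):
            raise ValidationError("background_percentile must lie in [0, 100]")
        for name in ("microglia_soma_area_um2", "neuron_soma_area_um2", "puncta_area_um2"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValidationError(f"{name} must be an increasing positive pair")
        if self.puncta_contrast_factor <= 1.0:
            raise ValidationError("puncta_contrast_factor must exceed 1")
        for spec in self.thresholds.values():
            spec.validate()
        self.classification.validate()
        return self

    def threshold_for(self, channel: str) -> ThresholdSpec:
        return self.thresholds.get(channel, ThresholdSpec())

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs).validate()

    # ------------------------------------------------------------------
    # (de)serialization: a single flat YAML/JSON document
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = {k: dataclasses.asdict(v) for k, v in self.thresholds.items()}
        for key in ("microglia_soma_area_um2", "neuron_soma_area_um2", "puncta_area_um2"):
            d[key] = list(d[key])
        return d

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d:
            d["thresholds"] = {
                k: v if isinstance(v, ThresholdSpec) else ThresholdSpec(**v)
                for k, v in d["thresholds"].items()
            }
        if "classification" in d and not isinstance(d["classification"], ClassificationParams):
            d["classification"] = ClassificationParams(**d["classification"])
        for key in ("microglia_soma_area_um2", "neuron_soma_area_um2", "puncta_area_um2"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})
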