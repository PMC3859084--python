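"""Pipeline configuration.

All tunables of the extraction pipeline live here, grouped by stage.  The
defaults are the operating point of the method: ROI expansion delta = 1.5,
14 retained Fourier descriptors, 2000 Monte Carlo hypotheses per shape
class, cluster-merge overlap alpha = 0.90, 30 random-walk refinement
iterations, and the gamma = 0.95 area-overlap criterion used when
evaluating against ground truth.  Unknown keys in a config file are
rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class CannyConfig:
    #: Canny hysteresis thresholds on the gradient magnitude of the
    #: [0, 1]-scaled image; None derives high from Otsu and low = high / 2
    low: float | None = None
    high: float | None = None
    #: Gaussian smoothing scale of the edge detector, pixels
    sigma: float = 1.4

    def validate(self) -> None:
        if self.low is not None and self.high is not None and not (0 <= self.low < self.high):
            raise ConfigError("canny thresholds require 0 <= low < high")
        if self.sigma <= 0:
            raise ConfigError("canny.sigma must be positive")


@dataclass
class RoiConfig:
    #: ROI expansion factor: the search rectangle spans (1 + delta)*IPD
    #: horizontally and delta*IPD vertically around the inter-eye midpoint
    delta: float = 1.5

    def validate(self) -> None:
        if self.delta <= 0:
            raise ConfigError("roi.delta must be positive")


@dataclass
class EyesConfig:
    #: eye localization mode: cascade | supplied | template
    mode: str = "template"
    #: skimage cascade XML file (mode=cascade only)
    cascade_path: str | None = None
    #: maximum tolerated inter-eye slope, degrees
    max_tilt_deg: float = 10.0
    #: synthesized eye rectangle size relative to IPD (supplied mode)
    rect_width_ipd: float = 0.18
    rect_height_ipd: float = 0.11

    def validate(self) -> None:
        if self.mode not in ("cascade", "supplied", "template"):
            raise ConfigError(f"unknown eyes.mode {self.mode!r}")
        if self.max_tilt_deg <= 0:
            raise ConfigError("eyes.max_tilt_deg must be positive")


@dataclass
class DescriptorConfig:
    #: retained Fourier descriptors per rim shape
    count: int = 14
    #: contour sampling/reconstruction point count
    n_points: int = 64

    def validate(self) -> None:
        if self.count < 2:
            raise ConfigError("descriptors.count must be >= 2")
        if self.n_points < max(3, self.count):
            raise ConfigError("descriptors.n_points must be >= descriptors.count")


@dataclass
class SearchConfig:
    #: Monte Carlo hypotheses generated per shape class
    max_hypotheses: int = 2000
    #: minimum bounding-box overlap fraction for cluster merging
    alpha: float = 0.90
    #: half-width of the uniform centroid sampling box, IPD units
    centroid_box_ipd: float = 0.25
    #: uniform lens size (first-harmonic radius) bounds, IPD units
    size_min_ipd: float = 0.35
    size_max_ipd: float = 0.70

    def validate(self) -> None:
        if self.max_hypotheses < 1:
            raise ConfigError("search.max_hypotheses must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ConfigError("search.alpha must be in (0, 1]")
        if not 0 < self.size_min_ipd < self.size_max_ipd:
            raise ConfigError("search size bounds require 0 < min < max")
        if self.centroid_box_ipd <= 0:
            raise ConfigError("search.centroid_box_ipd must be positive")


@dataclass
class RefineConfig:
    #: random-walk iterations (each sweeps once over the four dimensions)
    max_iterations: int = 30
    #: initial Gaussian proposal standard deviations (position/size in IPD
    #: units); each decays geometrically to anneal_floor * initial
    sigma_pos_ipd: float = 0.06
    sigma_size_ipd: float = 0.06
    sigma_beta: float = 0.20
    anneal_floor: float = 0.05

    def validate(self) -> None:
        if self.max_iterations < 0:
            raise ConfigError("refine.max_iterations must be >= 0")
        for name in ("sigma_pos_ipd", "sigma_size_ipd", "sigma_beta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"refine.{name} must be >= 0")
        if not 0 < self.anneal_floor <= 1:
            raise ConfigError("refine.anneal_floor must be in (0, 1]")


@dataclass
class PipelineConfig:
    #: mean edge distance (pixels) above which extraction is declared failed
    reject_score: float = 5.0
    #: RNG seed for the whole pipeline
    seed: int = 0

    def validate(self) -> None:
        if self.reject_score <= 0:
            raise ConfigError("pipeline.reject_score must be positive")


@dataclass
class EvalConfig:
    #: area-overlap fraction above which a detection counts as a true positive
    gamma: float = 0.95

    def validate(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ConfigError("eval.gamma must be in (0, 1]")


@dataclass
class Config:
    canny: CannyConfig = field(default_factory=CannyConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    eyes: EyesConfig = field(default_factory=EyesConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def validate(self) -> "Config":
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate()
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls()
        for section, values in (d or {}).items():
            if not hasattr(cfg, section):
                raise ConfigError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            if not isinstance(values, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            for key, value in values.items():
                if not any(f.name == key for f in dataclasses.fields(sub)):
                    raise ConfigError(f"unknown config key {section}.{key}")
                setattr(sub, key, value)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "Config":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for logs and reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
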