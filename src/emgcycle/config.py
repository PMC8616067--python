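"""Pipeline configuration: schema, YAML loading, validation, hashing."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .synthetic import SynthConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PreprocessingConfig:
    highpass_hz: float = 10.0
    lowpass_hz: float = 10.0


@dataclass
class SegmentationConfig:
    min_period_s: float | None = None  # None: half the autocorrelation cadence
    prominence_frac: float = 0.1


@dataclass
class AveragingConfig:
    t_norm: int = 200
    onset_frac: float = 0.2


@dataclass
class NmfConfig:
    order: int | None = 3  # None: select by VAF threshold
    vaf_threshold: float = 0.95
    n_max: int = 4
    restarts: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0


@dataclass
class StabilityConfig:
    mode: str = "nmf"  # or "projection"
    restarts: int = 3
    max_iter: int = 500
    tol: float = 1e-5


@dataclass
class StatsConfig:
    unit: str = "cycle"  # observation unit column for contribution tests
    paired: bool = False
    holm: bool = False


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    averaging: AveragingConfig = field(default_factory=AveragingConfig)
    nmf: NmfConfig = field(default_factory=NmfConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        self.synth.validate()
        if self.preprocessing.highpass_hz <= 0 or self.preprocessing.lowpass_hz <= 0:
            raise ValueError("filter cutoffs must be positive")
        if not 0 < self.averaging.onset_frac < 1:
            raise ValueError("onset_frac must lie in (0, 1)")
        if self.averaging.t_norm < 8:
            raise ValueError("t_norm too small")
        if self.nmf.order is not None and self.nmf.order < 1:
            raise ValueError("nmf order must be >= 1")
        if not 0 <= self.nmf.vaf_threshold <= 1:
            raise ValueError("vaf_threshold must lie in [0, 1]")
        if self.stability.mode not in ("nmf", "projection"):
            raise ValueError("stability mode must be 'nmf' or 'projection'")
        if self.segmentation.min_period_s is not None and self.segmentation.min_period_s <= 0:
            raise ValueError("min_period_s must be positive")

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        raw = {
            name: convert(getattr(self, name))
            for name in (
                "synth",
                "preprocessing",
                "segmentation",
                "averaging",
                "nmf",
                "stability",
                "stats",
            )
        }
        # asdict already recursed; normalize arrays/tuples inside
        return json.loads(json.dumps(raw, default=lambda o: list(o)))


def _build_section(cls, payload: dict | None):
    payload = payload or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(payload)
    if cls is SynthConfig:
        for key in ("planted_W",):
            if key in kwargs:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        for key in ("phase_centers", "phase_widths", "carrier_band_hz", "muscle_labels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a validated config from an optional YAML file plus overrides."""
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    if overrides:
        for section, values in overrides.items():
            payload.setdefault(section, {}).update(values)
    cfg = PipelineConfig(
        synth=_build_section(SynthConfig, payload.get("synth")),
        preprocessing=_build_section(PreprocessingConfig, payload.get("preprocessing")),
        segmentation=_build_section(SegmentationConfig, payload.get("segmentation")),
        averaging=_build_section(AveragingConfig, payload.get("averaging")),
        nmf=_build_section(NmfConfig, payload.get("nmf")),
        stability=_build_section(StabilityConfig, payload.get("stability")),
        stats=_build_section(StatsConfig, payload.get("stats")),
    )
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable digest of the fully resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
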