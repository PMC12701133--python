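"""Run configuration: every tolerance and threshold used by the pipeline.

One YAML file drives a full run; :func:`load_config` reads it,
:func:`default_config` gives the in-memory defaults.  A fixed ``seed``
makes the entire pipeline byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class DetectorConfig:
    image_size: int = 96
    stem_channels: int = 12
    body_widths: tuple = (16, 24, 32)
    body_depths: tuple = (1, 1, 1)
    pyramid_channels: int = 24
    head_channels: int = 24
    anchor_scales: tuple = (16.0, 32.0, 64.0)      # pixels, one per level
    anchor_aspects: tuple = (0.35, 0.6, 1.0)       # height / width
    iou_pos: float = 0.5
    iou_neg: float = 0.4
    score_thresh: float = 0.05
    nms_iou: float = 0.5
    max_detections: int = 20
    loss: str = "focal"                            # "focal" | "bce"
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    learning_rate: float = 2e-3
    steps: int = 500
    batch_size: int = 8
    second_pass_direction: str = "bottom_up"       # path-aggregation pass


@dataclass
class EtedConfig:
    """Gated-attention LSTM classifier settings."""

    hidden_size: int = 16
    n_timesteps: int = 6
    learning_rate: float = 1e-2
    epochs: int = 80
    batch_size: int = 32
    early_stopping_patience: int = 10
    threshold: float = 0.5
    gate_location: str = "pooled"                  # "pooled" | "hidden"
    dense_map_mode: str = "elementwise"            # "elementwise" | "matmul"


@dataclass
class SplitConfig:
    train_fraction: float = 0.8
    stratified: bool = True


@dataclass
class PathsConfig:
    images_dir: str = "images"
    annotations_file: str = "annotations.json"
    clinical_csv: str = "cohort.csv"
    output_dir: str = "output"


@dataclass
class RunConfig:
    seed: int = 0
    image_size: int = 96
    iou_thresholds: tuple = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    eted: EtedConfig = field(default_factory=EtedConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def __post_init__(self):
        if not 0.0 < self.split.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        ts = list(self.iou_thresholds)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("iou_thresholds must be strictly increasing")
        if any(not 0.0 <= t <= 1.0 for t in ts):
            raise ValueError("iou_thresholds must lie in [0,1]")


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if dataclasses.is_dataclass(_RESOLVE.get(name)):
            kwargs[name] = _build(_RESOLVE[name], value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_RESOLVE = {"detector": DetectorConfig, "eted": EtedConfig,
            "split": SplitConfig, "paths": PathsConfig}


def default_config(**overrides) -> RunConfig:
    cfg = RunConfig()
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path: str | Path):
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(dataclasses.asdict(cfg)), fh, sort_keys=True)
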