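"""Configuration for the fall-detection pipeline.

All tunables live in nested dataclasses with field names mirroring the
dotted config keys used in YAML files (``bg.learning_rate``,
``flow.static_eps``, ``occl.vanish_frames``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class BackgroundConfig:
    """Mixture-of-Gaussians background model (``bg.*``)."""

    learning_rate: float = 0.05     # fast rate; selective learning makes it safe
    n_components: int = 5
    match_sigma: float = 3.0        # Mahalanobis match threshold (in std units)
    initial_variance: float = 100.0
    min_variance: float = 4.0
    bg_weight_threshold: float = 0.3  # component weight needed to count as background
    shadow_enabled: bool = True
    shadow_lo: float = 0.4          # brightness ratio band for shadow pixels
    shadow_hi: float = 0.95
    min_area_frac: float = 0.005    # contour area cutoff, fraction of frame area
    protect_dilate_px: int = 5
    aggregate_margin_frac: float = 0.2  # predicted-region expansion per side


@dataclass
class TrackingConfig:
    """Kalman filter and data association (``track.*``)."""

    dt: float = 1.0 / 8.0
    # process noise std per step
    q_pos: float = 2.0
    q_vel: float = 1.0
    q_size: float = 1.5
    q_vratio: float = 0.05
    q_angle: float = 2.0
    # measurement noise std
    r_pos: float = 1.0
    r_size: float = 2.0
    r_vratio: float = 0.1
    r_angle: float = 5.0
    gate_factor: float = 0.75       # gate = factor * max(pred w, pred h)
    promote_frames: int = 3
    demote_frames: int = 5
    max_unseen_frames: int = 10
    initial_pos_var: float = 25.0
    initial_vel_var: float = 100.0


@dataclass
class FlowConfig:
    """Sparse optical-flow point clouds (``flow.*``)."""

    max_points: int = 100
    window_radius: int = 7          # LK integration window half-size
    pyramid_levels: int = 3
    iterations: int = 10
    min_eigen: float = 1e-3         # reject points on untextured patches
    base_fraction: float = 0.4      # fraction of points forming the base set
    flag_sigma: float = 1.5         # flag beyond this many base-set stds
    doubtful_max_age: int = 3
    coherence_angle_deg: float = 60.0
    max_removed_frac: float = 0.25  # safety bound per pruning pass
    static_eps: float = 0.5         # px/frame: below this a cloud is static
    window_frames: int = 5
    reseed_fraction: float = 0.4    # reseed when cloud shrinks below this


@dataclass
class ClassifierConfig:
    """KNN state classification (``clf.*``)."""

    k: int = 3
    vote_epsilon: float = 1e-6
    fold_angle: bool = True         # fold ellipse angle to [0, 90] degrees


@dataclass
class OcclusionConfig:
    """Inferior-occlusion handling (``occl.*``)."""

    lower_frac: float = 0.4         # bottom fraction of the reference box
    lower_drop_frac: float = 0.5    # area drop that signals occlusion
    upper_tol_frac: float = 0.15    # tolerated top-edge / upper-width variation
    window_frames: int = 4
    reference_frames: int = 5       # median box over frames preceding onset
    vanish_frames: int = 8
    height_tol: float = 0.2


@dataclass
class AlertConfig:
    """Debounced alerting (``alert.*``)."""

    delay_s: float = 2.0
    blur: bool = False


@dataclass
class PipelineConfig:
    bg: BackgroundConfig = field(default_factory=BackgroundConfig)
    track: TrackingConfig = field(default_factory=TrackingConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    clf: ClassifierConfig = field(default_factory=ClassifierConfig)
    occl: OcclusionConfig = field(default_factory=OcclusionConfig)
    alert: AlertConfig = field(default_factory=AlertConfig)

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.track.dt

    def with_frame_rate(self, frame_rate: float) -> "PipelineConfig":
        self.track.dt = 1.0 / float(frame_rate)
        return self


def _apply(obj: Any, data: Mapping[str, Any]) -> None:
    known = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in known:
            raise KeyError(f"unknown config key: {key!r}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, Mapping):
            _apply(current, value)
        else:
            setattr(obj, key, type(current)(value) if current is not None else value)


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file.

    The YAML file uses nested maps (``bg: {learning_rate: 0.02}``);
    ``overrides`` is a nested mapping applied on top.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _apply(cfg, data)
    if overrides:
        _apply(cfg, overrides)
    return cfg
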