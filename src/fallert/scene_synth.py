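"""Deterministic synthetic video scenes with ground-truth event logs.

Real recordings of falls are scarce and hard to share, so the test bed
is a scripted renderer: a single human silhouette — a two-segment
capsule (torso + legs, so that the lower body can disappear behind
furniture independently of the upper body) — moves over a static
textured background and performs one scripted activity per scene
(walking, falling perpendicular or parallel to the camera, sitting,
walking or falling behind an occluder, leaving), optionally with
nuisance events (a displaced static object, a slow illumination ramp,
a slowly unfolding low-contrast carpet-like blob).

Every scene is a pure function of its :class:`ScenarioScript`, including
the seed: rendering the same script twice yields byte-identical frames.
The ground-truth log records the visible silhouette's bounding box and
orientation per frame and a non-overlapping set of labelled intervals
(``FALL`` / ``NOT_FALL`` / ``OCCLUDED_FALL``) covering the whole scene.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

FLOOR_Y = 210            # image row of the subject's feet
WALK_SPEED = 32.0        # px/s
SUBJECT_LENGTH = 80.0    # standing height, px
TORSO_RADIUS = 14.0
LEG_RADIUS = 10.0
FALL_TRANSITION_S = 0.75
BACKGROUND_SEED = 12345  # background texture is shared by all scenes


class Activity(str, Enum):
    WALK = "WALK"
    FALL_PERP = "FALL_PERP"
    FALL_PARA = "FALL_PARA"
    SIT = "SIT"
    OCCLUDED_WALK = "OCCLUDED_WALK"
    OCCLUDED_FALL = "OCCLUDED_FALL"
    OBJECT_MOVE = "OBJECT_MOVE"
    CARPET_UNFOLD = "CARPET_UNFOLD"
    ILLUM_RAMP = "ILLUM_RAMP"


_OCCLUDED = {Activity.OCCLUDED_WALK, Activity.OCCLUDED_FALL}
DEFAULT_OCCLUDER = (170, 160, 92, 52)  # x, y, w, h — desk-like box on the floor


@dataclass(frozen=True)
class ScenarioScript:
    """Everything that determines a rendered scene."""

    activity: Activity
    duration: float                 # seconds
    frame_rate: float = 8.0         # Hz
    image_size: tuple[int, int] = (320, 240)   # (width, height)
    seed: int = 0
    occluder_rect: tuple[int, int, int, int] | None = None
    noise_sigma: float = 2.0        # grey levels of per-frame pixel noise
    subject_scale: float = 1.0      # silhouette size multiplier

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image size must have positive area")
        act = Activity(self.activity)
        if act in _OCCLUDED and self.occluder_rect is None:
            raise ValueError(f"{act.value} requires occluder_rect")
        if act not in _OCCLUDED and self.occluder_rect is not None:
            raise ValueError(f"{act.value} does not take occluder_rect")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def default_script(activity: Activity | str, seed: int = 0, **kwargs) -> ScenarioScript:
    """A script with activity-appropriate duration and occluder defaults."""
    act = Activity(activity)
    durations = {
        Activity.WALK: 10.0,
        Activity.FALL_PERP: 13.0,
        Activity.FALL_PARA: 13.0,
        Activity.SIT: 13.0,
        Activity.OCCLUDED_WALK: 14.0,
        Activity.OCCLUDED_FALL: 17.0,
        Activity.OBJECT_MOVE: 12.0,
        Activity.CARPET_UNFOLD: 16.0,
        Activity.ILLUM_RAMP: 12.0,
    }
    kwargs.setdefault("duration", durations[act])
    if act in _OCCLUDED:
        kwargs.setdefault("occluder_rect", DEFAULT_OCCLUDER)
    return ScenarioScript(activity=act, seed=seed, **kwargs)


@dataclass
class FrameTruth:
    """Visible-silhouette geometry for one frame (``None`` if absent)."""

    bbox: tuple[int, int, int, int] | None   # x, y, w, h of visible pixels
    orientation: float | None                # degrees vs. x-axis, [0, 180)
    ratio: float | None                      # bbox w / h
    occluded_frac: float                     # hidden fraction of the silhouette


@dataclass
class GroundTruthLog:
    """Labelled intervals plus per-frame silhouette geometry.

    Intervals are half-open ``[start, end)`` frame ranges, non-overlapping,
    and together cover every frame exactly once.
    """

    intervals: list[tuple[int, int, str]]
    per_frame: list[FrameTruth] = field(default_factory=list)

    def label_at(self, frame: int) -> str:
        for start, end, label in self.intervals:
            if start <= frame < end:
                return label
        raise IndexError(f"frame {frame} not covered by any interval")

    def fall_intervals(self) -> list[tuple[int, int, str]]:
        return [iv for iv in self.intervals if iv[2] in ("FALL", "OCCLUDED_FALL")]

    def validate(self, n_frames: int | None = None) -> None:
        ivs = sorted(self.intervals)
        if n_frames is not None and (ivs[0][0] != 0 or ivs[-1][1] != n_frames):
            raise ValueError("intervals do not span [0, n_frames)")
        for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
            if e0 != s1:
                raise ValueError("intervals overlap or leave gaps")
        for s, e, lab in ivs:
            if e <= s or lab not in ("FALL", "NOT_FALL", "OCCLUDED_FALL"):
                raise ValueError(f"bad interval {(s, e, lab)}")

    def save(self, path: str | Path) -> None:
        payload = {
            "intervals": [list(iv) for iv in self.intervals],
            "per_frame": [
                {
                    "bbox": list(ft.bbox) if ft.bbox else None,
                    "orientation": ft.orientation,
                    "ratio": ft.ratio,
                    "occluded_frac": ft.occluded_frac,
                }
                for ft in self.per_frame
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthLog":
        payload = json.loads(Path(path).read_text())
        per_frame = [
            FrameTruth(
                bbox=tuple(d["bbox"]) if d["bbox"] else None,
                orientation=d["orientation"],
                ratio=d["ratio"],
                occluded_frac=d.get("occluded_frac", 0.0),
            )
            for d in payload["per_frame"]
        ]
        intervals = [(int(s), int(e), str(l)) for s, e, l in payload["intervals"]]
        return cls(intervals=intervals, per_frame=per_frame)


# ---------------------------------------------------------------------------
# Subject pose model
# ---------------------------------------------------------------------------

@dataclass
class _Pose:
    feet_x: float
    feet_y: float
    theta: float        # body-axis angle vs. x-axis, degrees (upright = 90)
    length: float
    torso_r: float
    leg_r: float


def _silhouette_mask(pose: _Pose, width: int, height: int) -> np.ndarray:
    """Boolean mask of the two-segment capsule silhouette."""
    th = math.radians(pose.theta)
    ax, ay = math.cos(th), -math.sin(th)          # axis unit vector, image coords
    L, rt, rl = pose.length, pose.torso_r, pose.leg_r

    def seg(s0: float, s1: float):
        p0 = (pose.feet_x + ax * s0, pose.feet_y + ay * s0)
        p1 = (pose.feet_x + ax * s1, pose.feet_y + ay * s1)
        return p0, p1

    # legs occupy the lower half, torso+head the upper half; end caps round off
    legs = (seg(rl, 0.5 * L), rl)
    torso = (seg(0.45 * L, L - rt), rt)

    xs = np.arange(width, dtype=np.float64)
    ys = np.arange(height, dtype=np.float64)
    X, Y = np.meshgrid(xs, ys)
    mask = np.zeros((height, width), dtype=bool)
    for (p0, p1), r in (legs, torso):
        dx, dy = p1[0] - p0[0], p1[1] - p0[1]
        denom = dx * dx + dy * dy
        if denom < 1e-12:
            t = np.zeros_like(X)
        else:
            t = np.clip(((X - p0[0]) * dx + (Y - p0[1]) * dy) / denom, 0.0, 1.0)
        d2 = (X - (p0[0] + t * dx)) ** 2 + (Y - (p0[1] + t * dy)) ** 2
        mask |= d2 <= r * r
    return mask


def _lerp(a: float, b: float, u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return a + (b - a) * u


def _smooth(u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return u * u * (3 - 2 * u)


# ---------------------------------------------------------------------------
# Activity timelines
# ---------------------------------------------------------------------------

class _Timeline:
    """Maps time to subject pose and frames to truth labels for one script."""

    def __init__(self, script: ScenarioScript):
        self.script = script
        s = script.subject_scale
        self.L = SUBJECT_LENGTH * s
        self.rt = TORSO_RADIUS * s
        self.rl = LEG_RADIUS * s
        self.enter_t = 0.5
        self.x0 = -25.0 * s
        self.D = script.duration
        act = script.activity
        # activity way-points (seconds)
        if act in (Activity.FALL_PERP, Activity.FALL_PARA, Activity.CARPET_UNFOLD):
            fall_x = 130.0
            self.t_fall = self.enter_t + (fall_x - self.x0) / WALK_SPEED
            if act is Activity.CARPET_UNFOLD:
                self.t_fall = min(self.t_fall, 3.5)
            self.t_plateau = self.t_fall + FALL_TRANSITION_S
            self.t_rec = (self.D - 2.5) if act is not Activity.CARPET_UNFOLD else 8.0
            self.t_up = self.t_rec + FALL_TRANSITION_S
            self.fall_x = self.x0 + WALK_SPEED * (self.t_fall - self.enter_t)
        elif act is Activity.SIT:
            sit_x = 140.0
            self.t_sit = self.enter_t + (sit_x - self.x0) / WALK_SPEED
            self.t_seated = self.t_sit + 0.6
            self.t_stand = self.D - 2.5
            self.t_up = self.t_stand + 0.6
            self.sit_x = sit_x
        elif act is Activity.OCCLUDED_FALL:
            ox, oy, ow, oh = script.occluder_rect
            self.occ_cx = ox + ow / 2.0
            self.t_reach = self.enter_t + (self.occ_cx - self.x0) / WALK_SPEED
            self.t_fall = self.t_reach + 1.0
            self.t_hidden = self.t_fall + FALL_TRANSITION_S

    # -- pose ---------------------------------------------------------------

    def pose(self, t: float) -> _Pose | None:
        act = self.script.activity
        if act in (Activity.WALK, Activity.ILLUM_RAMP, Activity.OBJECT_MOVE,
                   Activity.OCCLUDED_WALK):
            return self._walk_pose(t)
        if act in (Activity.FALL_PERP, Activity.FALL_PARA, Activity.CARPET_UNFOLD):
            return self._fall_pose(t, perp=(act is Activity.FALL_PERP))
        if act is Activity.SIT:
            return self._sit_pose(t)
        if act is Activity.OCCLUDED_FALL:
            return self._occluded_fall_pose(t)
        raise AssertionError(act)

    def _bob(self, t: float) -> float:
        # gait bobbing: periodic silhouette-length modulation while walking
        return 3.0 * self.script.subject_scale * math.sin(2 * math.pi * 1.5 * t)

    def _upright(self, x: float, length: float | None = None) -> _Pose:
        return _Pose(x, float(FLOOR_Y), 90.0, length if length is not None else self.L,
                     self.rt, self.rl)

    def _walk_pose(self, t: float) -> _Pose | None:
        if t < self.enter_t:
            return None
        x = self.x0 + WALK_SPEED * (t - self.enter_t)
        if x > self.script.image_size[0] + 30:
            return None
        return self._upright(x, self.L + self._bob(t))

    def _fall_pose(self, t: float, perp: bool) -> _Pose | None:
        if t < self.enter_t:
            return None
        if t < self.t_fall:
            return self._upright(self.x0 + WALK_SPEED * (t - self.enter_t),
                                 self.L + self._bob(t))
        if t < self.t_plateau:
            u = _smooth((t - self.t_fall) / FALL_TRANSITION_S)
        elif t < self.t_rec:
            u = 1.0
        elif t < self.t_up:
            u = 1.0 - _smooth((t - self.t_rec) / FALL_TRANSITION_S)
        else:
            x = self.fall_x + WALK_SPEED * (t - self.t_up)
            if x > self.script.image_size[0] + 30:
                return None
            return self._upright(x, self.L + self._bob(t))
        lying = self.t_plateau <= t < self.t_rec
        wobble = 1.0 * math.sin(2 * math.pi * 0.8 * t) if lying else 0.0
        if perp:
            # rotate about the feet towards the horizontal
            theta = _lerp(90.0, 8.0, u) + wobble
            return _Pose(self.fall_x, float(FLOOR_Y), theta, self.L, self.rt, self.rl)
        # parallel to the camera axis: the silhouette foreshortens to a blob
        length = _lerp(self.L, 0.42 * self.L, u)
        rt = _lerp(self.rt, 1.25 * self.rt, u)
        return _Pose(self.fall_x, float(FLOOR_Y), 90.0 + 2 * wobble, length, rt,
                     _lerp(self.rl, 1.2 * self.rl, u))

    def _sit_pose(self, t: float) -> _Pose | None:
        if t < self.enter_t:
            return None
        if t < self.t_sit:
            return self._upright(self.x0 + WALK_SPEED * (t - self.enter_t),
                                 self.L + self._bob(t))
        if t < self.t_seated:
            u = _smooth((t - self.t_sit) / (self.t_seated - self.t_sit))
        elif t < self.t_stand:
            u = 1.0
        elif t < self.t_up:
            u = 1.0 - _smooth((t - self.t_stand) / (self.t_up - self.t_stand))
        else:
            x = self.sit_x + WALK_SPEED * (t - self.t_up)
            if x > self.script.image_size[0] + 30:
                return None
            return self._upright(x, self.L + self._bob(t))
        length = _lerp(self.L, 0.65 * self.L, u)
        return _Pose(self.sit_x, float(FLOOR_Y), 90.0, length,
                     _lerp(self.rt, 1.2 * self.rt, u), _lerp(self.rl, 1.35 * self.rl, u))

    def _occluded_fall_pose(self, t: float) -> _Pose | None:
        if t < self.enter_t:
            return None
        if t < self.t_reach:
            return self._upright(self.x0 + WALK_SPEED * (t - self.enter_t),
                                 self.L + self._bob(t))
        if t < self.t_fall:
            return self._upright(self.occ_cx, self.L + self._bob(t))
        # collapse in place behind the occluder (foreshortening fall)
        u = _smooth((t - self.t_fall) / FALL_TRANSITION_S)
        length = _lerp(self.L, 0.42 * self.L, u)
        return _Pose(self.occ_cx, float(FLOOR_Y), 90.0, length,
                     _lerp(self.rt, 1.25 * self.rt, u), _lerp(self.rl, 1.2 * self.rl, u))

    # -- labels -------------------------------------------------------------

    def intervals(self) -> list[tuple[int, int, str]]:
        fr = self.script.frame_rate
        n = self.script.n_frames
        act = self.script.activity

        def f(t: float) -> int:
            return min(max(int(round(t * fr)), 0), n)

        if act in (Activity.FALL_PERP, Activity.FALL_PARA, Activity.CARPET_UNFOLD):
            s, e = f(self.t_plateau), f(self.t_rec)
            out = [(0, s, "NOT_FALL"), (s, e, "FALL"), (e, n, "NOT_FALL")]
        elif act is Activity.OCCLUDED_FALL:
            s = f(self.t_hidden)
            out = [(0, s, "NOT_FALL"), (s, n, "OCCLUDED_FALL")]
        else:
            out = [(0, n, "NOT_FALL")]
        return [(s, e, lab) for s, e, lab in out if e > s]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _background_texture(width: int, height: int) -> np.ndarray:
    """Static room texture shared by every scene (floor darker than wall)."""
    rng = np.random.default_rng(BACKGROUND_SEED)
    base = np.full((height, width), 95.0)
    base[FLOOR_Y - 8:, :] = 72.0
    # low-frequency mottle: upsampled coarse noise
    coarse = rng.normal(0.0, 18.0, size=(height // 16 + 2, width // 16 + 2))
    ys = np.linspace(0, coarse.shape[0] - 1.001, height)
    xs = np.linspace(0, coarse.shape[1] - 1.001, width)
    yi, xi = np.floor(ys).astype(int), np.floor(xs).astype(int)
    fy, fx = (ys - yi)[:, None], (xs - xi)[None, :]
    mottle = ((1 - fy) * (1 - fx) * coarse[np.ix_(yi, xi)]
              + (1 - fy) * fx * coarse[np.ix_(yi, xi + 1)]
              + fy * (1 - fx) * coarse[np.ix_(yi + 1, xi)]
              + fy * fx * coarse[np.ix_(yi + 1, xi + 1)])
    fine = rng.normal(0.0, 4.0, size=(height, width))
    return base + mottle + fine


def _subject_texture(mask: np.ndarray, pose: _Pose) -> np.ndarray:
    """Clothing-like texture anchored to the subject's local frame."""
    ys, xs = np.nonzero(mask)
    th = math.radians(pose.theta)
    ax, ay = math.cos(th), -math.sin(th)
    u = (xs - pose.feet_x) * ax + (ys - pose.feet_y) * ay        # along body axis
    v = -(xs - pose.feet_x) * ay + (ys - pose.feet_y) * ax       # across
    tex = 185.0 + 22.0 * np.sin(0.55 * u) * np.cos(0.8 * v) + 10.0 * np.sin(1.7 * v)
    return tex


def _rect_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]) -> np.ndarray:
    x, y, w, h = rect
    m = np.zeros(shape, dtype=bool)
    m[max(y, 0):y + h, max(x, 0):x + w] = True
    return m


def render_scenario(script: ScenarioScript) -> tuple[np.ndarray, GroundTruthLog]:
    """Render a scripted scene.

    Returns an ``(n_frames, height, width)`` uint8 array and the matching
    :class:`GroundTruthLog`.  Identical scripts (including seed) produce
    bit-identical output.
    """
    script = ScenarioScript(**{**script.__dict__})  # re-validate
    width, height = script.image_size
    n = script.n_frames
    tl = _Timeline(script)
    rng = np.random.default_rng(script.seed)
    bg = _background_texture(width, height)

    act = script.activity
    occ_mask = None
    if script.occluder_rect is not None:
        occ_mask = _rect_mask((height, width), script.occluder_rect)

    frames = np.empty((n, height, width), dtype=np.uint8)
    per_frame: list[FrameTruth] = []
    chair_rect_a = (60, 168, 30, 42)
    chair_rect_b = (104, 168, 30, 42)

    for k in range(n):
        t = k / script.frame_rate
        canvas = bg.copy()

        if act is Activity.OBJECT_MOVE:
            rect = chair_rect_a if t < 2.0 else chair_rect_b
            m = _rect_mask((height, width), rect)
            canvas[m] = 150.0

        if act is Activity.CARPET_UNFOLD and t >= 9.0:
            u = _smooth((t - 9.0) / (script.duration - 9.0))
            cw = int(_lerp(12, 80, u))
            ch = int(_lerp(6, 20, u))
            m = _rect_mask((height, width), (150, FLOOR_Y - ch, cw, ch))
            canvas[m] += 22.0

        pose = tl.pose(t)
        sil = None
        if pose is not None:
            sil = _silhouette_mask(pose, width, height)
            if sil.any():
                canvas[sil] = _subject_texture(sil, pose)
            else:
                sil = None

        if occ_mask is not None:
            canvas[occ_mask] = 55.0
            ys, xs = np.nonzero(occ_mask)
            canvas[ys, xs] += 8.0 * np.sin(0.5 * xs)  # give the desk some texture

        if act is Activity.ILLUM_RAMP:
            canvas *= 1.0 + 0.25 * (t / script.duration)

        noise = rng.normal(0.0, script.noise_sigma, size=(height, width))
        frames[k] = np.clip(canvas + noise, 0, 255).astype(np.uint8)

        per_frame.append(_frame_truth(sil, pose, occ_mask))

    log = GroundTruthLog(intervals=tl.intervals(), per_frame=per_frame)
    log.validate(n)
    return frames, log


def _frame_truth(sil: np.ndarray | None, pose: _Pose | None,
                 occ_mask: np.ndarray | None) -> FrameTruth:
    if sil is None or pose is None:
        return FrameTruth(None, None, None, 0.0 if pose is None else 1.0)
    visible = sil & ~occ_mask if occ_mask is not None else sil
    total = int(sil.sum())
    occluded_frac = 1.0 - visible.sum() / total if total else 1.0
    if visible.sum() < 20:
        return FrameTruth(None, None, None, occluded_frac)
    ys, xs = np.nonzero(visible)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    w, h = x1 - x0 + 1, y1 - y0 + 1
    theta = pose.theta % 180.0
    return FrameTruth((x0, y0, w, h), theta, w / h, occluded_frac)


# ---------------------------------------------------------------------------
# Frame I/O
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


def write_frames(frames: Sequence[np.ndarray] | np.ndarray, directory: str | Path) -> list[Path]:
    """Write frames as lexicographically sortable 8-bit PNGs.

    Files are named ``frame_000000.png`` onward; reading them back
    reproduces the pixel values exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = directory / f"frame_{i:06d}.png"
        try:
            iio.imwrite(path, np.asarray(frame, dtype=np.uint8))
        except OSError as exc:
            raise OSError(f"failed to write frame to {path}: {exc}") from exc
        paths.append(path)
    return paths


def read_frames(source: str | Path) -> np.ndarray:
    """Read a frame sequence from a directory of images or a container file.

    Directories are read in lexicographic filename order; RGB input is
    converted to grayscale by channel averaging.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff"))
        if not files:
            return np.empty((0, 0, 0), dtype=np.uint8)
        arrs = [iio.imread(p) for p in files]
    else:
        arrs = list(iio.imread(source))
    frames = []
    for a in arrs:
        a = np.asarray(a)
        if a.ndim == 3:
            a = a.mean(axis=2)
        frames.append(a.astype(np.uint8))
    return np.stack(frames)
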