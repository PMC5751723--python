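"""Sparse optical-flow point clouds and their statistical pruning.

Each subject (and each candidate object) carries a cloud of corner-like
feature points tracked frame-to-frame with a pyramidal Lucas–Kanade
solver.  The cloud serves two purposes: measuring how much an element of
the scene actually moves (people standing "still" always jitter; a
displaced chair does not), and keeping the point set attached to the
subject despite clothes folding and turning.

Points that stop moving with the rest of the cloud are removed by a
two-stage statistical rule: the 40% of points whose displacement
magnitude is closest to the cloud mean form a *base set*; points whose
magnitude deviates from the base-set mean by more than 1.5 base-set
standard deviations are flagged *doubtful*; a point that stays doubtful
for three consecutive frames and moves in a direction incoherent with
the base set is dropped.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from fallert.config import FlowConfig


@dataclass
class MotionEvidence:
    """Windowed displacement summary for one cloud."""

    mean_magnitude: float              # px/frame over the window
    direction: float                   # degrees, mean displacement direction
    is_static: bool


@dataclass
class PointCloud:
    """Tracked feature points with displacement statistics."""

    points: np.ndarray                 # (N, 2) float (x, y)
    displacements: np.ndarray          # (N, 2) float, last frame's (dx, dy)
    doubtful_age: np.ndarray           # (N,) int in {0, 1, 2, 3}
    owner_id: int | None = None
    initial_size: int = 0
    history: deque = field(default_factory=lambda: deque(maxlen=32))

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls, owner_id: int | None = None) -> "PointCloud":
        return cls(points=np.empty((0, 2)), displacements=np.empty((0, 2)),
                   doubtful_age=np.empty(0, dtype=int), owner_id=owner_id)

    def needs_reseed(self, cfg: FlowConfig) -> bool:
        return len(self) < cfg.reseed_fraction * max(self.initial_size, 1)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def seed_points(frame: np.ndarray, subject_mask: np.ndarray,
                cfg: FlowConfig | None = None, owner_id: int | None = None
                ) -> PointCloud:
    """Pick up to ``max_points`` corner features inside a subject mask.

    An untextured region may legitimately yield few or no corners; an
    empty mask yields an empty cloud.
    """
    cfg = cfg or FlowConfig()
    mask = np.asarray(subject_mask, dtype=bool)
    if not mask.any():
        return PointCloud.empty(owner_id)
    img = np.asarray(frame, dtype=np.float64)
    response = corner_shi_tomasi(img)
    response[~mask] = 0.0
    peaks = corner_peaks(response, min_distance=3,
                         threshold_rel=0.01, num_peaks=cfg.max_points)
    if len(peaks) == 0:
        # fall back to the strongest in-mask responses so a textured
        # subject always gets at least a handful of points
        ys, xs = np.nonzero(mask)
        vals = response[ys, xs]
        order = np.argsort(vals)[::-1][:min(cfg.max_points, 25)]
        keep = vals[order] > 0
        peaks = np.stack([ys[order][keep], xs[order][keep]], axis=1)
    if len(peaks) == 0:
        return PointCloud.empty(owner_id)
    pts = peaks[:, ::-1].astype(np.float64)       # (row, col) -> (x, y)
    cloud = PointCloud(points=pts,
                       displacements=np.zeros_like(pts),
                       doubtful_age=np.zeros(len(pts), dtype=int),
                       owner_id=owner_id, initial_size=len(pts))
    return cloud


# ---------------------------------------------------------------------------
# Pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------

def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    out = [img.astype(np.float64)]
    for _ in range(levels - 1):
        prev = out[-1]
        h, w = prev.shape
        if min(h, w) < 16:
            break
        sm = ndimage.gaussian_filter(prev, 1.0)
        out.append(sm[: h - h % 2: 2, : w - w % 2: 2].copy())
    return out


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_level(prev: np.ndarray, cur: np.ndarray, pts: np.ndarray,
              guess: np.ndarray, cfg: FlowConfig
              ) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level of iterative LK, vectorised over all points.

    Returns (flow, valid)."""
    r = cfg.window_radius
    n = len(pts)
    h, w = prev.shape
    gy, gx = np.gradient(prev)
    offs = np.arange(-r, r + 1, dtype=np.float64)
    wy, wx = np.meshgrid(offs, offs, indexing="ij")
    wy, wx = wy.ravel(), wx.ravel()                   # (W2,), W2 = (2r+1)^2

    px, py = pts[:, 0], pts[:, 1]
    valid = (px >= r) & (px < w - r) & (py >= r) & (py < h - r)
    ys = py[:, None] + wy[None, :]                    # (N, W2)
    xs = px[:, None] + wx[None, :]
    ix = _sample(gx, ys, xs)
    iy = _sample(gy, ys, xs)
    i0 = _sample(prev, ys, xs)
    gxx = (ix * ix).sum(axis=1)
    gxy = (ix * iy).sum(axis=1)
    gyy = (iy * iy).sum(axis=1)
    # smaller eigenvalue of the structure tensor, per point
    tr, det = gxx + gyy, gxx * gyy - gxy * gxy
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    min_eig = tr / 2.0 - disc
    valid &= min_eig > cfg.min_eigen * (2 * r + 1) ** 2
    det = np.where(np.abs(det) < 1e-12, np.nan, det)

    flow = guess.copy()
    active = valid.copy()
    for _ in range(cfg.iterations):
        if not active.any():
            break
        ys2 = ys + flow[:, 1:2]
        xs2 = xs + flow[:, 0:1]
        diff = i0 - _sample(cur, ys2, xs2)
        bx = (diff * ix).sum(axis=1)
        by = (diff * iy).sum(axis=1)
        # 2x2 solve via the adjugate
        dvx = (gyy * bx - gxy * by) / det
        dvy = (gxx * by - gxy * bx) / det
        step = np.where(active[:, None], np.stack([dvx, dvy], axis=1), 0.0)
        step = np.nan_to_num(step)
        flow += step
        active &= np.hypot(step[:, 0], step[:, 1]) >= 0.01
    centre = pts + flow
    valid &= (centre[:, 0] >= 0) & (centre[:, 0] < w) & \
             (centre[:, 1] >= 0) & (centre[:, 1] < h)
    valid &= np.all(np.isfinite(flow), axis=1)
    return np.nan_to_num(flow), valid


def advect(cloud: PointCloud, prev_frame: np.ndarray, frame: np.ndarray,
           cfg: FlowConfig | None = None) -> PointCloud:
    """Move every point to its Lucas–Kanade correspondence in ``frame``.

    Points whose correspondence fails (untextured patch, out of bounds,
    diverged solve) are dropped; displacements of the survivors are
    recorded on the cloud.  Never invents points.
    """
    cfg = cfg or FlowConfig()
    prev_frame = np.asarray(prev_frame, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    if prev_frame.shape != frame.shape:
        raise ValueError("frame dimensions differ")
    if len(cloud) == 0:
        return cloud
    pyr_prev = _pyramid(prev_frame, cfg.pyramid_levels)
    pyr_cur = _pyramid(frame, cfg.pyramid_levels)
    levels = min(len(pyr_prev), len(pyr_cur))
    flow = np.zeros_like(cloud.points)
    valid = np.ones(len(cloud), dtype=bool)
    for lvl in range(levels - 1, -1, -1):
        scale = 2.0 ** lvl
        pts_l = cloud.points / scale
        flow, ok = _lk_level(pyr_prev[lvl], pyr_cur[lvl], pts_l, flow, cfg)
        if lvl == 0:
            valid &= ok
        flow = flow * 2.0 if lvl > 0 else flow
    new_pts = cloud.points + flow
    h, w = frame.shape
    inb = (new_pts[:, 0] >= 0) & (new_pts[:, 0] < w) & \
          (new_pts[:, 1] >= 0) & (new_pts[:, 1] < h)
    keep = valid & inb
    out = PointCloud(points=new_pts[keep],
                     displacements=flow[keep],
                     doubtful_age=cloud.doubtful_age[keep],
                     owner_id=cloud.owner_id,
                     initial_size=cloud.initial_size,
                     history=cloud.history)
    if len(out):
        out.history.append(out.displacements.mean(axis=0))
    return out


# ---------------------------------------------------------------------------
# Statistical pruning
# ---------------------------------------------------------------------------

def base_set_indices(magnitudes: np.ndarray, base_fraction: float) -> np.ndarray:
    """Indices of the ``base_fraction`` of points closest to the mean
    displacement magnitude; ties broken by point index."""
    n = len(magnitudes)
    k = int(np.floor(base_fraction * n))
    closeness = np.abs(magnitudes - magnitudes.mean())
    order = np.lexsort((np.arange(n), closeness))   # stable on ties
    return np.sort(order[:k])


def prune_outliers(cloud: PointCloud, cfg: FlowConfig | None = None) -> PointCloud:
    """Apply the base-set / doubtful-flag / three-frame removal rule.

    1. The 40% of points with displacement magnitude closest to the
       cloud mean form the base set; its magnitude mean and standard
       deviation give the reference band.
    2. Points outside mean ± 1.5·std get their doubtful age incremented;
       points inside have it reset to zero.
    3. A point reaching doubtful age 3 whose displacement direction
       deviates from the base-set mean direction by more than the
       coherence angle is removed (a safety bound caps removals at 25%
       of the cloud per pass).

    Clouds of fewer than 5 points are returned unchanged.
    """
    cfg = cfg or FlowConfig()
    n = len(cloud)
    if n < 5:
        return cloud
    mags = np.hypot(cloud.displacements[:, 0], cloud.displacements[:, 1])
    base = base_set_indices(mags, cfg.base_fraction)
    mu_b = mags[base].mean()
    sigma_b = mags[base].std()
    deviation = np.abs(mags - mu_b)
    flagged = deviation > cfg.flag_sigma * sigma_b
    age = np.where(flagged, np.minimum(cloud.doubtful_age + 1, cfg.doubtful_max_age), 0)

    base_dir = cloud.displacements[base].mean(axis=0)
    remove = np.zeros(n, dtype=bool)
    ripe = age >= cfg.doubtful_max_age
    if ripe.any() and np.hypot(*base_dir) > 1e-9:
        d = cloud.displacements
        norms = np.hypot(d[:, 0], d[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (d @ base_dir) / (norms * np.hypot(*base_dir))
        cosang = np.where(norms > 1e-9, cosang, -1.0)  # motionless = incoherent
        incoherent = np.degrees(np.arccos(np.clip(cosang, -1, 1))) > cfg.coherence_angle_deg
        remove = ripe & incoherent
    elif ripe.any():
        remove = ripe                     # base set motionless: ripe points drop

    max_removed = int(np.ceil(cfg.max_removed_frac * n))
    if remove.sum() > max_removed:
        idx = np.nonzero(remove)[0]
        order = np.lexsort((idx, -deviation[idx]))    # worst deviators first
        keep_flagged = idx[order[max_removed:]]
        remove[keep_flagged] = False

    keep = ~remove
    return PointCloud(points=cloud.points[keep],
                      displacements=cloud.displacements[keep],
                      doubtful_age=age[keep],
                      owner_id=cloud.owner_id,
                      initial_size=cloud.initial_size,
                      history=cloud.history)


def motion_summary(cloud: PointCloud, window_frames: int | None = None,
                   cfg: FlowConfig | None = None) -> MotionEvidence | None:
    """Windowed mean displacement of the cloud; ``None`` without history.

    An element is *static* when its mean per-frame displacement falls
    below ``static_eps`` — sensitive enough that the micro-jitter of a
    person standing in place still registers as motion.
    """
    cfg = cfg or FlowConfig()
    window = window_frames or cfg.window_frames
    if len(cloud.history) == 0:
        return None
    recent = np.array(list(cloud.history)[-window:])
    mean_vec = recent.mean(axis=0)
    mean_mag = float(np.hypot(recent[:, 0], recent[:, 1]).mean())
    direction = float(np.degrees(np.arctan2(-mean_vec[1], mean_vec[0])) % 360.0)
    return MotionEvidence(mean_magnitude=mean_mag, direction=direction,
                          is_static=mean_mag < cfg.static_eps)
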