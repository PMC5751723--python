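"""Frame-loop orchestration of the fall-detection chain.

Per frame the pipeline runs: background subtraction (analysis pass,
no learning) → contour extraction → data association against the
Kalman-predicted tracks → broken-contour aggregation per track →
Kalman measurement update → feature extraction → KNN classification
(suppressed while a track is occluded) → inferior-occlusion logic →
selective background learning with a protect mask covering every
active subject.

Occlusion handling follows the "height memory" scheme: when the lower
part of a subject disappears over a few frames while the upper profile
stays continuous (walking behind a desk), the track enters the
OCCLUDED state and the pre-occlusion height is stored.  While
occluded, the classifier is never invoked; if the remaining visible
evidence then vanishes entirely and stays vanished, the track becomes
OCCLUDED_FALLEN (a fall hidden behind the occluder).  The occlusion
ends when the observed height returns to the stored height, at which
point regular classification resumes.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from fallert import foreground, optflow, tracking
from fallert.classify import (StateLabel, TrainingSet, classify_sample,
                              compute_features)
from fallert.config import PipelineConfig
from fallert.foreground import (FOREGROUND, MixtureBackgroundModel,
                                aggregate_broken_contours, build_protect_mask,
                                expand_region, extract_contours)
from fallert.observation import SubjectObservation


class OcclusionState(str, Enum):
    NONE = "NONE"
    OCCLUDED = "OCCLUDED"
    OCCLUDED_FALLEN = "OCCLUDED_FALLEN"


@dataclass
class TrackStatus:
    """Per-frame public status of one track."""

    track_id: int
    state: StateLabel | None           # None while occluded or untrained
    occlusion: OcclusionState
    stored_height: float | None
    frames_in_state: int
    frame: int
    ratio: float
    angle: float
    vratio: float
    bbox: tuple[int, int, int, int] | None

    @property
    def is_fall_state(self) -> bool:
        """Whether this frame counts as a fall for alerting purposes."""
        return (self.state == StateLabel.FALL
                or self.occlusion is OcclusionState.OCCLUDED_FALLEN)


@dataclass
class _ObsStats:
    """Light per-frame silhouette statistics kept for occlusion tests."""

    bbox: tuple[int, int, int, int]
    area: int
    row_counts: np.ndarray             # (H,) pixels per image row
    row_min: np.ndarray                # (H,) leftmost column (or -1)
    row_max: np.ndarray


def _obs_stats(obs: SubjectObservation, height: int) -> _ObsStats:
    rows = obs.coords[:, 0]
    cols = obs.coords[:, 1]
    counts = np.bincount(rows, minlength=height).astype(np.int32)
    row_min = np.full(height, np.iinfo(np.int32).max, dtype=np.int32)
    np.minimum.at(row_min, rows, cols)
    row_min[counts == 0] = -1
    row_max = np.full(height, -1, dtype=np.int32)
    np.maximum.at(row_max, rows, cols)
    return _ObsStats(bbox=obs.bbox, area=obs.area, row_counts=counts,
                     row_min=row_min, row_max=row_max)


@dataclass
class _TrackBook:
    """Pipeline-side bookkeeping attached to each track id."""

    prev_ratio: float | None = None
    vratio_hist: deque = field(default_factory=lambda: deque([0.0, 0.0, 0.0], maxlen=3))
    state: StateLabel | None = None
    frames_in_state: int = 0
    occlusion: OcclusionState = OcclusionState.NONE
    stored_height: float | None = None
    occlusion_zone: tuple[float, float, float, float] | None = None
    vanish_streak: int = 0
    history: deque = field(default_factory=lambda: deque(maxlen=16))
    rows: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Occlusion rules
# ---------------------------------------------------------------------------

def detect_inferior_occlusion(history: list[_ObsStats], cfg: PipelineConfig) -> bool:
    """Lower area vanishing under a continuous upper profile.

    Compares the last ``occl.window_frames`` frames against a reference
    bounding box (median over the ``occl.reference_frames`` frames
    preceding the window): occlusion iff the foreground area inside the
    bottom ``lower_frac`` of the reference box dropped by more than
    ``lower_drop_frac`` while the top edge and the upper-half width each
    varied less than ``upper_tol_frac`` of the reference extent.
    """
    oc = cfg.occl
    need = oc.window_frames + oc.reference_frames
    if len(history) < need:
        return False
    window = list(history)[-oc.window_frames:]
    reference = list(history)[-need:-oc.window_frames]

    ref_box = np.median(np.array([s.bbox for s in reference]), axis=0)
    rx, ry, rw, rh = ref_box
    lo_start = int(round(ry + (1.0 - oc.lower_frac) * rh))
    lo_end = int(round(ry + rh)) + 1
    up_end = int(round(ry + 0.5 * rh))

    def lower_area(s: _ObsStats) -> float:
        return float(s.row_counts[lo_start:lo_end].sum())

    def upper_width(s: _ObsStats) -> float:
        sel = s.row_counts[: up_end] > 0
        if not sel.any():
            return 0.0
        mins = s.row_min[:up_end][sel]
        maxs = s.row_max[:up_end][sel]
        return float(maxs.max() - mins.min() + 1)

    ref_lower = float(np.median([lower_area(s) for s in reference]))
    if ref_lower <= 0:
        return False
    cur_lower = lower_area(window[-1])
    if cur_lower > (1.0 - oc.lower_drop_frac) * ref_lower:
        return False

    ref_top = float(np.median([s.bbox[1] for s in reference]))
    ref_upper_w = float(np.median([upper_width(s) for s in reference]))
    for s in window:
        if abs(s.bbox[1] - ref_top) > oc.upper_tol_frac * rh:
            return False
        if abs(upper_width(s) - ref_upper_w) > max(oc.upper_tol_frac * rw, 4.0):
            return False
    return True


def occluded_fall_confirmed(book: _TrackBook, cfg: PipelineConfig) -> bool:
    """Vanished-for-long-enough test while in the OCCLUDED state."""
    return book.vanish_streak >= cfg.occl.vanish_frames


def end_occlusion(book: _TrackBook, obs: SubjectObservation, cfg: PipelineConfig) -> bool:
    """Occlusion ends when the observed height matches the stored one."""
    if book.stored_height is None:
        return False
    return abs(obs.bbox[3] - book.stored_height) <= cfg.occl.height_tol * book.stored_height


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class FallDetectionPipeline:
    """Stateful frame-by-frame fall detector.

    Feed grayscale frames through :meth:`step`; each call returns the
    per-track statuses for that frame.  A training set enables KNN
    classification; without one the pipeline still tracks subjects and
    handles occlusions but reports ``state=None``.
    """

    def __init__(self, config: PipelineConfig | None = None,
                 training: TrainingSet | None = None):
        self.config = config or PipelineConfig()
        self.training = training
        self.model: MixtureBackgroundModel | None = None
        self.registry = tracking.TrackRegistry(cfg=self.config.track)
        self.books: dict[int, _TrackBook] = {}
        self.frame_idx = -1
        self.prev_frame: np.ndarray | None = None
        self.statuses: list[TrackStatus] = []

    # -- helpers ------------------------------------------------------------

    def _min_area(self, shape: tuple[int, int]) -> int:
        return max(int(self.config.bg.min_area_frac * shape[0] * shape[1]), 1)

    def _predicted_rect(self, track: tracking.Track) -> tuple[float, float, float, float]:
        st = track.state
        return (st.x - st.w / 2.0, st.y - st.h / 2.0, st.w, st.h)

    def _contour_to_obs(self, contour: foreground.Contour) -> SubjectObservation:
        from fallert.observation import ellipse_from_coords
        return SubjectObservation(bbox=contour.bbox,
                                  ellipse=ellipse_from_coords(contour.coords),
                                  area=contour.area, centroid=contour.centroid,
                                  coords=contour.coords)

    # -- main loop ----------------------------------------------------------

    def step(self, frame: np.ndarray) -> list[TrackStatus]:
        frame = np.asarray(frame)
        if frame.ndim == 3:
            frame = frame.mean(axis=2).astype(frame.dtype)
        self.frame_idx += 1
        try:
            return self._step(frame)
        except Exception as exc:
            raise RuntimeError(f"pipeline failure at frame {self.frame_idx}: {exc}") from exc
        finally:
            self.prev_frame = frame

    def _step(self, frame: np.ndarray) -> list[TrackStatus]:
        cfg = self.config
        if self.model is None:
            self.model = MixtureBackgroundModel(frame.shape, cfg.bg)
            self.model.initialize(frame)
            return []

        mask = self.model.subtract(frame)
        contours = extract_contours(mask, self._min_area(frame.shape[:2]))

        # Kalman time update for every live track
        for track in self.registry.tracks.values():
            track.state = tracking.predict(track.state, cfg.track)

        contour_obs = [self._contour_to_obs(c) for c in contours]
        _, unmatched_idx = tracking.associate(contour_obs, self.registry)

        statuses: list[TrackStatus] = []
        claimed: set[int] = set()
        for tid in sorted(self.registry.tracks):
            track = self.registry.tracks[tid]
            region = expand_region(self._predicted_rect(track),
                                   cfg.bg.aggregate_margin_frac)
            members = [i for i, c in enumerate(contours)
                       if i not in claimed and c.intersects(region)]
            obs = aggregate_broken_contours([contours[i] for i in members], region)
            if obs is not None:
                claimed.update(members)
            statuses.append(self._update_track(track, obs, contours, frame, mask))

        unmatched = [contour_obs[i] for i in unmatched_idx if i not in claimed]
        self._handle_candidates(unmatched, frame, mask)
        self._reap_tracks()

        protect_rects = []
        for tid, track in self.registry.tracks.items():
            book = self.books[tid]
            rect = book.history[-1].bbox if book.history else self._predicted_rect(track)
            if book.occlusion is not OcclusionState.NONE and book.occlusion_zone:
                protect_rects.append(book.occlusion_zone)
            protect_rects.append(rect)
        protect = build_protect_mask(frame.shape[:2], protect_rects,
                                     cfg.bg.protect_dilate_px)
        self.model.selective_learn(frame, protect)

        statuses = [s for s in statuses if s.track_id in self.registry.tracks]
        self.statuses.extend(statuses)
        return statuses

    # -- track update -------------------------------------------------------

    def _update_track(self, track: tracking.Track, obs: SubjectObservation | None,
                      contours: list[foreground.Contour], frame: np.ndarray,
                      mask: np.ndarray) -> TrackStatus:
        cfg = self.config
        book = self.books.setdefault(track.id, _TrackBook())

        if obs is None:
            track.frames_unseen += 1
            if book.occlusion is OcclusionState.OCCLUDED:
                zone = book.occlusion_zone
                evidence = zone and any(c.intersects(zone) for c in contours)
                if not evidence:
                    book.vanish_streak += 1
                else:
                    book.vanish_streak = 0
                if occluded_fall_confirmed(book, cfg):
                    book.occlusion = OcclusionState.OCCLUDED_FALLEN
            return self._status(track, book, None)

        track.frames_unseen = 0
        track.age += 1
        raw_ratio = obs.ratio
        vratio_meas = 0.0
        if book.prev_ratio not in (None, 0.0):
            vratio_meas = abs(raw_ratio - book.prev_ratio) / book.prev_ratio
        track.state = tracking.update(track.state, obs, vratio_meas, cfg.track)
        book.vratio_hist.appendleft(max(track.state.vratio, 0.0))
        book.history.append(_obs_stats(obs, frame.shape[0]))
        self._update_flow(track, frame, mask, obs)

        # occlusion bookkeeping
        if book.occlusion is OcclusionState.NONE:
            if detect_inferior_occlusion(list(book.history), cfg):
                ref = list(book.history)[-(cfg.occl.window_frames
                                           + cfg.occl.reference_frames):-cfg.occl.window_frames]
                ref_box = np.median(np.array([s.bbox for s in ref]), axis=0)
                book.occlusion = OcclusionState.OCCLUDED
                book.stored_height = float(ref_box[3])
                book.occlusion_zone = expand_region(tuple(ref_box), 0.3)
                book.vanish_streak = 0
        else:
            book.vanish_streak = 0
            if book.occlusion is OcclusionState.OCCLUDED and end_occlusion(book, obs, cfg):
                book.occlusion = OcclusionState.NONE
                book.stored_height = None
                book.occlusion_zone = None

        # classification (never while occluded)
        if book.occlusion is OcclusionState.NONE and self.training is not None:
            sample, _ = compute_features(obs, track.state, book.prev_ratio,
                                         tuple(book.vratio_hist), cfg.clf)
            label = classify_sample(sample, self.training, cfg.clf)
            if label == book.state:
                book.frames_in_state += 1
            else:
                book.state = label
                book.frames_in_state = 1
        book.prev_ratio = raw_ratio
        return self._status(track, book, obs)

    def _update_flow(self, track: tracking.Track, frame: np.ndarray,
                     mask: np.ndarray, obs: SubjectObservation) -> None:
        cfg = self.config.flow
        subject_mask = np.zeros(frame.shape, dtype=bool)
        subject_mask[obs.coords[:, 0], obs.coords[:, 1]] = True
        if track.cloud is None or len(track.cloud) == 0 or \
                track.cloud.needs_reseed(cfg):
            history = track.cloud.history if track.cloud is not None else None
            track.cloud = optflow.seed_points(frame, subject_mask, cfg, track.id)
            if history is not None:
                track.cloud.history = history
        elif self.prev_frame is not None:
            track.cloud = optflow.advect(track.cloud, self.prev_frame, frame, cfg)
            track.cloud = optflow.prune_outliers(track.cloud, cfg)

    def _status(self, track: tracking.Track, book: _TrackBook,
                obs: SubjectObservation | None) -> TrackStatus:
        st = track.state
        status = TrackStatus(
            track_id=track.id,
            state=book.state if book.occlusion is OcclusionState.NONE else None,
            occlusion=book.occlusion,
            stored_height=book.stored_height,
            frames_in_state=max(book.frames_in_state, 1),
            frame=self.frame_idx,
            ratio=st.ratio, angle=st.angle, vratio=st.vratio,
            bbox=obs.bbox if obs is not None else None,
        )
        book.rows.append({
            "frame": self.frame_idx, "id": track.id,
            "x": st.x, "y": st.y, "w": st.w, "h": st.h,
            "ratio_raw": obs.ratio if obs else "",
            "ratio_filt": st.ratio,
            "angle_raw": obs.ellipse.orientation if obs else "",
            "angle_filt": st.angle,
            "vratio_filt": st.vratio,
            "state": status.state.value if status.state else book.occlusion.value,
        })
        return status

    # -- candidates and lifecycle -------------------------------------------

    def _handle_candidates(self, unmatched: list[SubjectObservation],
                           frame: np.ndarray, mask: np.ndarray) -> None:
        cfg = self.config
        matched_cands: set[int] = set()
        for obs in unmatched:
            best, best_d = None, 40.0
            for cand in self.registry.candidates.values():
                if cand.id in matched_cands:
                    continue
                d = float(np.hypot(obs.centroid[0] - cand.observation.centroid[0],
                                   obs.centroid[1] - cand.observation.centroid[1]))
                if d < best_d:
                    best, best_d = cand, d
            if best is None:
                cand = self.registry.add_candidate(obs)
                sub = np.zeros(frame.shape, dtype=bool)
                sub[obs.coords[:, 0], obs.coords[:, 1]] = True
                cand.cloud = optflow.seed_points(frame, sub, cfg.flow, cand.id)
                matched_cands.add(cand.id)
            else:
                best.observation = obs
                best.age += 1
                matched_cands.add(best.id)
                if best.cloud is not None and len(best.cloud) and \
                        self.prev_frame is not None:
                    best.cloud = optflow.advect(best.cloud, self.prev_frame,
                                                frame, cfg.flow)

        # stale candidates disappear on their own
        for cid in list(self.registry.candidates):
            if cid not in matched_cands:
                cand = self.registry.candidates[cid]
                cand.age -= 1
                if cand.age <= 0:
                    del self.registry.candidates[cid]

        evidence: dict[int, float | None] = {}
        for cid, cand in self.registry.candidates.items():
            if cand.cloud is None or len(cand.cloud) == 0:
                evidence[cid] = 0.0
                continue
            summary = optflow.motion_summary(cand.cloud, cfg=cfg.flow)
            evidence[cid] = summary.mean_magnitude if summary else None
        promoted = tracking.triage_candidates(self.registry, evidence,
                                              cfg.flow.static_eps)
        for track in promoted:
            self.books[track.id] = _TrackBook()

    def _reap_tracks(self) -> None:
        cfg = self.config.track
        for tid in list(self.registry.tracks):
            book = self.books.get(tid)
            occluded = book is not None and book.occlusion is not OcclusionState.NONE
            if occluded:
                continue
            if self.registry.tracks[tid].frames_unseen > cfg.max_unseen_frames:
                del self.registry.tracks[tid]

    # -- whole-sequence helpers ---------------------------------------------

    def run(self, frames) -> list[list[TrackStatus]]:
        return [self.step(f) for f in frames]

    def export_track_csv(self, path: str | Path) -> None:
        """Write per-frame track histories (the plotted traces) as CSV."""
        fieldnames = ["frame", "id", "x", "y", "w", "h", "ratio_raw",
                      "ratio_filt", "angle_raw", "angle_filt", "vratio_filt",
                      "state"]
        rows = []
        for book in self.books.values():
            rows.extend(book.rows)
        rows.sort(key=lambda r: (r["frame"], r["id"]))
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
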