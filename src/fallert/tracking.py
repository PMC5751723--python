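"""Linear Kalman tracking of subjects and data association.

Each subject carries a 10-dimensional constant-velocity state

    [x, y, x_dot, y_dot, h, w, v_ratio, v_ratio_dot, phi, phi_dot]

where (x, y) is the silhouette centre of mass in pixels, (h, w) the
bounding-box height/width, ``v_ratio`` the (absolute, normalised)
ratio-change speed per second, and ``phi`` the fitted-ellipse angle in
degrees.  The transition model is the obvious one: positions, the
ratio-change speed and the angle integrate their rates over one frame
interval ``dT``; height and width are modelled as locally constant.
The measurement vector is (x, y, h, w, v_ratio, phi).

The filter serves two purposes: the predicted centre drives frame-to-
frame data association (solved globally via the Hungarian algorithm
with a size-relative gate), and the filtered ratio/angle/ratio-speed
traces — much smoother than the raw ones, since the filter absorbs the
periodic silhouette deformation of gait — feed the state classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import linear_sum_assignment

from fallert.config import TrackingConfig
from fallert.observation import SubjectObservation

if TYPE_CHECKING:
    from fallert.optflow import PointCloud

# state vector indices
IX, IY, IVX, IVY, IH, IW, IVR, IVRD, IPHI, IPHID = range(10)
STATE_DIM = 10
MEAS_DIM = 6
_MEAS_IDX = (IX, IY, IH, IW, IVR, IPHI)


def transition_matrix(dt: float) -> np.ndarray:
    F = np.eye(STATE_DIM)
    F[IX, IVX] = dt
    F[IY, IVY] = dt
    F[IVR, IVRD] = dt
    F[IPHI, IPHID] = dt
    return F


def measurement_matrix() -> np.ndarray:
    H = np.zeros((MEAS_DIM, STATE_DIM))
    for row, idx in enumerate(_MEAS_IDX):
        H[row, idx] = 1.0
    return H


def process_noise(cfg: TrackingConfig) -> np.ndarray:
    stds = np.array([cfg.q_pos, cfg.q_pos, cfg.q_vel, cfg.q_vel,
                     cfg.q_size, cfg.q_size, cfg.q_vratio, cfg.q_vratio,
                     cfg.q_angle, cfg.q_angle])
    return np.diag(stds ** 2)


def measurement_noise(cfg: TrackingConfig) -> np.ndarray:
    stds = np.array([cfg.r_pos, cfg.r_pos, cfg.r_size, cfg.r_size,
                     cfg.r_vratio, cfg.r_angle])
    return np.diag(stds ** 2)


@dataclass
class KalmanTrackState:
    """Filtered subject state and covariance."""

    vector: np.ndarray                 # (10,)
    cov: np.ndarray                    # (10, 10)
    dt: float

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    x = property(lambda self: self.vector[IX])
    y = property(lambda self: self.vector[IY])
    h = property(lambda self: self.vector[IH])
    w = property(lambda self: self.vector[IW])
    vratio = property(lambda self: self.vector[IVR])
    angle = property(lambda self: self.vector[IPHI] % 180.0)

    @property
    def ratio(self) -> float:
        return self.vector[IW] / self.vector[IH]

    @classmethod
    def from_observation(cls, obs: SubjectObservation, cfg: TrackingConfig
                         ) -> "KalmanTrackState":
        v = np.zeros(STATE_DIM)
        v[IX], v[IY] = obs.centroid
        v[IH], v[IW] = obs.bbox[3], obs.bbox[2]
        v[IPHI] = obs.ellipse.orientation
        P = np.diag([cfg.initial_pos_var, cfg.initial_pos_var,
                     cfg.initial_vel_var, cfg.initial_vel_var,
                     cfg.initial_pos_var, cfg.initial_pos_var,
                     1.0, 1.0,
                     cfg.initial_pos_var, cfg.initial_pos_var]).astype(float)
        return cls(vector=v, cov=P, dt=cfg.dt)


def predict(state: KalmanTrackState, cfg: TrackingConfig) -> KalmanTrackState:
    """Time update: integrate rates over one frame interval."""
    F = transition_matrix(state.dt)
    v = F @ state.vector
    P = F @ state.cov @ F.T + process_noise(cfg)
    return KalmanTrackState(vector=v, cov=P, dt=state.dt)


def _wrap_angle_innovation(delta: float) -> float:
    """Fold an angle difference to (-90, 90] degrees."""
    return (delta + 90.0) % 180.0 - 90.0


def update(state: KalmanTrackState, obs: SubjectObservation,
           vratio_meas: float, cfg: TrackingConfig) -> KalmanTrackState:
    """Measurement update from an associated observation.

    ``vratio_meas`` is the absolute normalised ratio change measured by
    the feature extractor for this frame (it is a derived measurement,
    not part of the raw silhouette geometry).
    """
    z = np.array([obs.centroid[0], obs.centroid[1],
                  obs.bbox[3], obs.bbox[2],
                  vratio_meas, obs.ellipse.orientation], dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite observation values: {z}")
    H = measurement_matrix()
    R = measurement_noise(cfg)
    innovation = z - H @ state.vector
    innovation[5] = _wrap_angle_innovation(innovation[5])
    S = H @ state.cov @ H.T + R
    K = state.cov @ H.T @ np.linalg.solve(S, np.eye(MEAS_DIM))
    v = state.vector + K @ innovation
    v[IH] = max(v[IH], 1.0)
    v[IW] = max(v[IW], 1.0)
    P = (np.eye(STATE_DIM) - K @ H) @ state.cov
    P = 0.5 * (P + P.T)               # keep the covariance symmetric
    return KalmanTrackState(vector=v, cov=P, dt=state.dt)


# ---------------------------------------------------------------------------
# Registry and association
# ---------------------------------------------------------------------------

@dataclass
class Track:
    id: int
    state: KalmanTrackState
    age: int = 1
    frames_unseen: int = 0
    cloud: "PointCloud | None" = None


@dataclass
class Candidate:
    """A contour that may become a new subject."""

    id: int
    observation: SubjectObservation
    age: int = 1
    moving_frames: int = 0
    still_frames: int = 0
    cloud: "PointCloud | None" = None


@dataclass
class TrackRegistry:
    cfg: TrackingConfig
    tracks: dict[int, Track] = field(default_factory=dict)
    candidates: dict[int, Candidate] = field(default_factory=dict)
    released_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    _next_id: int = 1

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def add_candidate(self, obs: SubjectObservation) -> Candidate:
        cand = Candidate(id=self.new_id(), observation=obs)
        self.candidates[cand.id] = cand
        return cand

    def promote(self, cand: Candidate) -> Track:
        track = Track(id=cand.id,
                      state=KalmanTrackState.from_observation(cand.observation, self.cfg),
                      cloud=cand.cloud)
        self.tracks[track.id] = track
        del self.candidates[cand.id]
        return track


def associate(observations: list[SubjectObservation], registry: TrackRegistry
              ) -> tuple[dict[int, int], list[int]]:
    """Globally assign observations to predicted tracks.

    Assumes :func:`predict` has already been applied this frame.  The
    cost is the Euclidean distance between predicted and observed
    centres; pairs beyond the size-relative gate are infeasible.  The
    assignment minimises total distance (Hungarian algorithm), with at
    most one observation per track.  Returns ``(track_id -> obs index,
    unmatched obs indices)``.
    """
    tracks = list(registry.tracks.values())
    if not tracks or not observations:
        return {}, list(range(len(observations)))
    cfg = registry.cfg
    BIG = 1e9
    cost = np.full((len(tracks), len(observations)), BIG)
    for i, tr in enumerate(tracks):
        gate = cfg.gate_factor * max(tr.state.w, tr.state.h)
        px, py = tr.state.x, tr.state.y
        for j, obs in enumerate(observations):
            d = float(np.hypot(obs.centroid[0] - px, obs.centroid[1] - py))
            if d <= gate:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    assignments = {tracks[i].id: j for i, j in zip(rows, cols) if cost[i, j] < BIG}
    unmatched = [j for j in range(len(observations)) if j not in assignments.values()]
    return assignments, unmatched


def triage_candidates(registry: TrackRegistry,
                      motion_evidence: dict[int, float | None],
                      static_eps: float = 0.5) -> list[Track]:
    """Promote moving candidates, discard motionless ones.

    ``motion_evidence`` maps candidate id to its mean point-cloud
    displacement in px/frame (``None`` when no evidence exists yet).
    Candidates moving for ``promote_frames`` consecutive frames become
    tracks; candidates motionless for ``demote_frames`` are marked
    uninteresting and their region is released to background learning.
    Returns the tracks promoted this frame.
    """
    cfg = registry.cfg
    promoted: list[Track] = []
    for cid in list(registry.candidates):
        cand = registry.candidates[cid]
        evidence = motion_evidence.get(cid)
        if evidence is None:
            continue
        if evidence >= static_eps:
            cand.moving_frames += 1
            cand.still_frames = 0
        else:
            cand.still_frames += 1
            cand.moving_frames = 0
        if cand.moving_frames >= cfg.promote_frames:
            promoted.append(registry.promote(cand))
        elif cand.still_frames >= cfg.demote_frames:
            registry.released_regions.append(cand.observation.bbox)
            del registry.candidates[cid]
    return promoted
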