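"""Kalman filter equations, association and candidate triage."""

import itertools

import numpy as np
import pytest

from fallert import tracking
from fallert.config import TrackingConfig
from fallert.observation import Ellipse, SubjectObservation
from fallert.tracking import (Candidate, KalmanTrackState, Track, TrackRegistry,
                              associate, predict, triage_candidates, update,
                              IX, IY, IVX, IVY, IH, IW, IVR, IVRD, IPHI, IPHID)


def literal_prediction(v: np.ndarray, dt: float) -> np.ndarray:
    """Direct scalar transcription of the constant-velocity update."""
    out = v.copy()
    out[IX] = v[IX] + v[IVX] * dt
    out[IY] = v[IY] + v[IVY] * dt
    out[IVX] = v[IVX]
    out[IVY] = v[IVY]
    out[IH] = v[IH]
    out[IW] = v[IW]
    out[IVR] = v[IVR] + v[IVRD] * dt
    out[IVRD] = v[IVRD]
    out[IPHI] = v[IPHI] + v[IPHID] * dt
    out[IPHID] = v[IPHID]
    return out


def _obs(x, y, w, h, angle=90.0):
    return SubjectObservation(bbox=(int(x - w / 2), int(y - h / 2), int(w), int(h)),
                              ellipse=Ellipse((x, y), h / 2, w / 2, angle),
                              area=int(w * h), centroid=(x, y))


def _state(cfg, **kw):
    st = KalmanTrackState.from_observation(_obs(100, 100, 30, 80), cfg)
    for key, val in kw.items():
        st.vector[key] = val
    return st


@pytest.fixture()
def cfg():
    return TrackingConfig()


def test_predict_integrates_position(cfg):
    cfg1 = TrackingConfig(dt=1.0)
    st = _state(cfg1)
    st.vector[IX], st.vector[IVX] = 10.0, 2.0
    assert predict(st, cfg1).vector[IX] == pytest.approx(12.0)


def test_predict_identity_at_zero_rates(cfg):
    st = _state(cfg)
    st.vector[[IVX, IVY, IVRD, IPHID]] = 0.0
    out = predict(st, cfg)
    for idx in (IX, IY, IH, IW, IVR, IPHI):
        assert out.vector[idx] == st.vector[idx]


def test_predict_keeps_height_width(cfg):
    st = _state(cfg)
    st.vector[IH], st.vector[IW] = 60.0, 20.0
    out = predict(st, cfg)
    assert (out.vector[IH], out.vector[IW]) == (60.0, 20.0)


def test_predict_matches_literal_equations(cfg, rng):
    for _ in range(200):
        st = _state(cfg)
        st.vector[:] = rng.normal(0, 50, size=10)
        st.vector[IH] = abs(st.vector[IH]) + 1
        st.vector[IW] = abs(st.vector[IW]) + 1
        expected = literal_prediction(st.vector, cfg.dt)
        got = predict(st, cfg).vector
        np.testing.assert_allclose(got, expected, rtol=1e-13, atol=1e-13)


def test_update_zero_measurement_noise_limit():
    cfg = TrackingConfig(r_pos=1e-6, r_size=1e-6, r_vratio=1e-9, r_angle=1e-6)
    st = _state(cfg)
    obs = _obs(140, 90, 40, 70, angle=80.0)
    out = update(st, obs, vratio_meas=0.25, cfg=cfg)
    assert out.x == pytest.approx(140, abs=1e-3)
    assert out.h == pytest.approx(70, abs=1e-3)
    assert out.vratio == pytest.approx(0.25, abs=1e-6)
    assert out.angle == pytest.approx(80.0, abs=1e-3)


def test_update_zero_process_noise_converges_to_constant():
    cfg = TrackingConfig(q_pos=1e-9, q_vel=1e-9, q_size=1e-9,
                         q_vratio=1e-12, q_angle=1e-9)
    st = _state(cfg)
    obs = _obs(120, 110, 32, 78)
    for _ in range(300):
        st = predict(st, cfg)
        st = update(st, obs, vratio_meas=0.0, cfg=cfg)
    assert st.x == pytest.approx(120, abs=0.2)
    assert st.h == pytest.approx(78, abs=0.2)


def test_update_rejects_nonfinite():
    cfg = TrackingConfig()
    st = _state(cfg)
    bad = _obs(100, 100, 30, 80)
    bad.centroid = (np.nan, 100.0)
    with pytest.raises(ValueError):
        update(st, bad, 0.0, cfg)


def test_covariance_stays_symmetric_psd(cfg):
    st = _state(cfg)
    gen = np.random.default_rng(5)
    for _ in range(2000):
        st = predict(st, cfg)
        obs = _obs(100 + gen.normal(0, 2), 100 + gen.normal(0, 2), 30, 80)
        st = update(st, obs, abs(gen.normal(0, 0.05)), cfg)
        assert np.allclose(st.cov, st.cov.T)
        eigs = np.linalg.eigvalsh(st.cov)
        assert eigs.min() > -1e-9


def test_filtered_ratio_smoother_than_raw_on_walk(walk_result):
    """Gait bobbing and segmentation noise shrink under the filter."""
    raw, filt = [], []
    for frame_statuses in walk_result.statuses:
        for st in frame_statuses:
            if st.bbox is not None:
                raw.append(st.bbox[2] / st.bbox[3])
                filt.append(st.ratio)
    raw, filt = np.array(raw[10:]), np.array(filt[10:])
    assert len(raw) >= 40
    assert np.var(np.diff(filt)) < np.var(np.diff(raw))


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def _registry_with_tracks(cfg, centres):
    reg = TrackRegistry(cfg=cfg)
    for cx, cy in centres:
        tid = reg.new_id()
        reg.tracks[tid] = Track(id=tid,
                                state=KalmanTrackState.from_observation(
                                    _obs(cx, cy, 30, 80), cfg))
    return reg


def test_associate_observation_at_predicted_centre(cfg):
    reg = _registry_with_tracks(cfg, [(100, 100)])
    assignments, unmatched = associate([_obs(100, 100, 30, 80)], reg)
    assert list(assignments.values()) == [0] and unmatched == []


def test_associate_gating_rejects_distant_observation(cfg):
    reg = _registry_with_tracks(cfg, [(100, 100)])
    assignments, unmatched = associate([_obs(300, 100, 30, 80)], reg)
    assert assignments == {} and unmatched == [0]


def test_associate_matches_exhaustive_min_cost_matching(cfg, rng):
    """Hungarian assignment equals the brute-force optimum."""
    for _ in range(20):
        centres = rng.uniform(60, 260, size=(5, 2))
        reg = _registry_with_tracks(cfg, centres)
        obs = [_obs(cx + rng.uniform(-15, 15), cy + rng.uniform(-15, 15), 30, 80)
               for cx, cy in centres]
        assignments, _ = associate(obs, reg)
        track_ids = sorted(reg.tracks)
        # oracle: enumerate all permutations, minimise total gated distance
        def total(perm):
            s = 0.0
            for tid, j in zip(track_ids, perm):
                tr = reg.tracks[tid].state
                d = np.hypot(obs[j].centroid[0] - tr.x, obs[j].centroid[1] - tr.y)
                gate = cfg.gate_factor * max(tr.w, tr.h)
                s += d if d <= gate else 1e9
            return s
        best = min(itertools.permutations(range(5)), key=total)
        expected = {tid: j for tid, j in zip(track_ids, best)}
        assert assignments == expected


# ---------------------------------------------------------------------------
# Candidate triage
# ---------------------------------------------------------------------------

def test_motionless_candidate_marked_uninteresting(cfg):
    reg = TrackRegistry(cfg=cfg)
    cand = reg.add_candidate(_obs(50, 50, 20, 30))
    for _ in range(cfg.demote_frames):
        triage_candidates(reg, {cand.id: 0.0})
    assert cand.id not in reg.candidates and cand.id not in reg.tracks
    assert reg.released_regions == [cand.observation.bbox]


def test_moving_candidate_promoted(cfg):
    reg = TrackRegistry(cfg=cfg)
    cand = reg.add_candidate(_obs(50, 50, 20, 30))
    promoted = []
    for _ in range(cfg.promote_frames):
        promoted = triage_candidates(reg, {cand.id: 3.0})
    assert [t.id for t in promoted] == [cand.id]
    assert cand.id in reg.tracks


def test_candidate_without_evidence_is_retained(cfg):
    reg = TrackRegistry(cfg=cfg)
    cand = reg.add_candidate(_obs(50, 50, 20, 30))
    for _ in range(10):
        triage_candidates(reg, {cand.id: None})
    assert cand.id in reg.candidates


def test_track_id_stable_through_fall(fall_perp_result):
    ids = {st.track_id for frame in fall_perp_result.statuses for st in frame}
    assert len(ids) == 1
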