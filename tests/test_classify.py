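"""Feature extraction, normalisation/weighting and KNN behaviour."""

import numpy as np
import pytest

from _oracles import knn_oracle
from fallert.classify import (FeatureSample, StateLabel, TrainingSet,
                              build_training_set, classify_sample,
                              compute_features, knn_classify,
                              normalize_and_weight)
from fallert.config import ClassifierConfig, TrackingConfig
from fallert.observation import Ellipse, SubjectObservation
from fallert.tracking import KalmanTrackState


def _obs(w, h, angle=90.0):
    return SubjectObservation(bbox=(0, 0, w, h),
                              ellipse=Ellipse((w / 2, h / 2), h / 2, w / 2, angle),
                              area=w * h, centroid=(w / 2, h / 2))


def _state(w, h, angle=90.0, vratio=0.0):
    st = KalmanTrackState.from_observation(_obs(w, h, angle), TrackingConfig())
    st.vector[6] = vratio
    return st


def _sample(angle, ratio, vr=(0.0, 0.0, 0.0), label=None):
    return FeatureSample(angle=angle, ratio=ratio, vratio_hist=tuple(vr),
                         label=label)


def _training(rng, n=60, k=3):
    samples = []
    for i in range(n):
        fall = i % 2 == 0
        ratio = rng.uniform(1.2, 3.0) if fall else rng.uniform(0.3, 0.8)
        angle = rng.uniform(0, 30) if fall else rng.uniform(60, 90)
        vr = tuple(rng.uniform(0, 0.3, size=3))
        samples.append(_sample(angle, ratio, vr,
                               StateLabel.FALL if fall else StateLabel.NOT_FALL))
    return TrainingSet(samples=samples, k=k)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def test_ratio_is_width_over_height():
    sample, _ = compute_features(_obs(20, 60), _state(20, 60), None, (0, 0, 0))
    assert sample.ratio == pytest.approx(1 / 3, rel=1e-6)


def test_upright_silhouette_angle_is_90():
    sample, _ = compute_features(_obs(20, 60, angle=90.0), _state(20, 60, 90.0),
                                 None, (0, 0, 0))
    assert sample.angle == pytest.approx(90.0)


def test_angle_folding_symmetric():
    cfg = ClassifierConfig(fold_angle=True)
    left, _ = compute_features(_obs(60, 20, 170.0), _state(60, 20, 170.0),
                               None, (0, 0, 0), cfg)
    right, _ = compute_features(_obs(60, 20, 10.0), _state(60, 20, 10.0),
                                None, (0, 0, 0), cfg)
    assert left.angle == pytest.approx(right.angle)


def test_constant_ratio_zero_delta():
    _, meas = compute_features(_obs(30, 60), _state(30, 60), prev_ratio=0.5,
                               vratio_hist=(0, 0, 0))
    assert meas == 0.0


def test_normalized_delta_definition():
    _, meas = compute_features(_obs(36, 60), _state(36, 60), prev_ratio=0.5,
                               vratio_hist=(0, 0, 0))
    assert meas == pytest.approx(abs(0.6 - 0.5) / 0.5)


def test_zero_height_observation_rejected():
    with pytest.raises(ValueError):
        _obs(10, 0)


# ---------------------------------------------------------------------------
# Normalisation and weighting
# ---------------------------------------------------------------------------

def test_normalized_vector_at_bounds(rng):
    tr = _training(rng)
    lo_sample = _sample(tr.lo[0], tr.lo[1], tuple(tr.lo[2:]))
    hi_sample = _sample(tr.hi[0], tr.hi[1], tuple(tr.hi[2:]))
    np.testing.assert_allclose(normalize_and_weight(lo_sample, tr), np.zeros(5))
    w = 1 / np.sqrt(3)
    np.testing.assert_allclose(normalize_and_weight(hi_sample, tr),
                               [1, 1, w, w, w])


def test_out_of_bounds_clamped(rng):
    tr = _training(rng)
    sample = _sample(720.0, 99.0, (9.0, 9.0, 9.0))
    vec = normalize_and_weight(sample, tr)
    assert vec[0] == 1.0 and vec[1] == 1.0


def test_degenerate_dimension_maps_to_half():
    samples = [_sample(45.0, 1.0, (0.1, 0.1, 0.1), StateLabel.FALL),
               _sample(45.0, 2.0, (0.2, 0.0, 0.3), StateLabel.NOT_FALL)]
    tr = TrainingSet(samples=samples, k=1)
    vec = normalize_and_weight(_sample(45.0, 1.5, (0.15, 0.05, 0.2)), tr)
    assert vec[0] == 0.5                     # angle span is zero


def test_vratio_triplet_contributes_one_unit(rng):
    """The weighted triple adds (sum of scaled squares)/3 to the metric."""
    tr = _training(rng)
    sample = _sample(50.0, 1.0, tuple(rng.uniform(0, 0.3, size=3)))
    vec = normalize_and_weight(sample, tr)
    span = tr.hi - tr.lo
    scaled = np.clip((sample.as_array() - tr.lo) / span, 0, 1)
    assert np.sum(vec[2:] ** 2) == pytest.approx(np.sum(scaled[2:] ** 2) / 3)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def test_exact_match_dominates(rng):
    tr = _training(rng, k=1)
    fall_sample = next(s for s in tr.samples if s.label is StateLabel.FALL)
    assert classify_sample(fall_sample, tr) is StateLabel.FALL


def test_equidistant_majority_wins():
    # explicit unit bounds so the features below are already normalised
    samples = [
        _sample(0.4, 0.5, (0, 0, 0), StateLabel.NOT_FALL),
        _sample(0.6, 0.5, (0, 0, 0), StateLabel.NOT_FALL),
        _sample(0.5, 0.6, (0, 0, 0), StateLabel.FALL),
        _sample(0.0, 0.9, (0, 0, 0), StateLabel.FALL),
    ]
    tr = TrainingSet(samples=samples, k=3, lo=np.zeros(5), hi=np.ones(5))
    # query at distance 0.1 from two NOT_FALL and one FALL neighbour
    query = normalize_and_weight(_sample(0.5, 0.5, (0, 0, 0)), tr)
    assert knn_classify(query, tr) is StateLabel.NOT_FALL


def test_training_order_permutation_invariant(rng):
    tr = _training(rng)
    perm = list(rng.permutation(len(tr.samples)))
    tr_perm = TrainingSet(samples=[tr.samples[i] for i in perm], k=tr.k)
    for _ in range(25):
        sample = _sample(rng.uniform(0, 90), rng.uniform(0.3, 3.0),
                         tuple(rng.uniform(0, 0.3, size=3)))
        assert classify_sample(sample, tr) is classify_sample(sample, tr_perm)


def test_knn_matches_bruteforce_oracle(rng):
    tr = _training(rng, n=200)
    for _ in range(50):
        sample = _sample(rng.uniform(0, 90), rng.uniform(0.2, 3.5),
                         tuple(rng.uniform(0, 0.4, size=3)))
        vec = normalize_and_weight(sample, tr)
        expected = knn_oracle(vec, tr.matrix, tr.labels, k=tr.k)
        got = knn_classify(vec, tr) is StateLabel.FALL
        assert got == expected


def test_knn_matches_sklearn_neighbour_set(rng):
    """The k nearest neighbours agree with scikit-learn's search."""
    from sklearn.neighbors import NearestNeighbors

    tr = _training(rng, n=150)
    queries = [normalize_and_weight(
        _sample(rng.uniform(0, 90), rng.uniform(0.2, 3.5),
                tuple(rng.uniform(0, 0.4, size=3))), tr) for _ in range(20)]
    nn = NearestNeighbors(n_neighbors=3).fit(tr.matrix)
    dists, idx = nn.kneighbors(np.array(queries))
    for q, d_ref in zip(queries, dists):
        d = np.sort(np.linalg.norm(tr.matrix - q, axis=1))[:3]
        np.testing.assert_allclose(d, d_ref, atol=1e-12)


def test_k1_and_k3_agree_when_neighbourhood_unanimous(rng):
    tr1 = _training(rng, k=1)
    tr3 = TrainingSet(samples=tr1.samples, k=3)
    checked = 0
    for _ in range(60):
        sample = _sample(rng.uniform(0, 90), rng.uniform(0.2, 3.5),
                         tuple(rng.uniform(0, 0.4, size=3)))
        vec = normalize_and_weight(sample, tr1)
        d = np.linalg.norm(tr1.matrix - vec, axis=1)
        nearest3 = tr1.labels[np.argsort(d)[:3]]
        if nearest3.all() or not nearest3.any():
            assert knn_classify(vec, tr1) is knn_classify(vec, tr3)
            checked += 1
    assert checked > 5


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        TrainingSet(samples=[_sample(10, 1.0, (0, 0, 0), StateLabel.FALL)], k=3)


# ---------------------------------------------------------------------------
# Training-set construction and persistence
# ---------------------------------------------------------------------------

def _track_csv(tmp_path, name, n_frames):
    import csv
    path = tmp_path / name
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["frame", "id", "ratio_filt",
                                           "angle_filt", "vratio_filt"])
        w.writeheader()
        for f in range(n_frames):
            w.writerow({"frame": f, "id": 1, "ratio_filt": 0.4 + 0.01 * f,
                        "angle_filt": 88.0, "vratio_filt": 0.02})
    return path


def test_interval_yields_one_sample_per_frame(tmp_path):
    path = _track_csv(tmp_path, "walkfall.csv", 40)
    tr = build_training_set(
        [path], {"walkfall.csv": [(0, 20, "NOT_FALL"), (25, 35, "FALL")]})
    assert sum(s.label is StateLabel.FALL for s in tr.samples) == 10
    assert len(tr.samples) == 30


def test_missing_frames_error_names_range(tmp_path):
    path = _track_csv(tmp_path, "short.csv", 10)
    with pytest.raises(ValueError, match=r"\[50, 60\)"):
        build_training_set([path], {"short.csv": [(0, 5, "FALL"),
                                                  (50, 60, "NOT_FALL")]})


def test_training_set_roundtrip(tmp_path, rng):
    tr = _training(rng)
    path = tmp_path / "model.csv"
    tr.save(path)
    back = TrainingSet.load(path)
    assert len(back.samples) == len(tr.samples)
    np.testing.assert_allclose(back.lo, tr.lo)
    np.testing.assert_allclose(back.hi, tr.hi)
    for a, b in zip(tr.samples, back.samples):
        assert a.label == b.label
        assert a.as_array() == pytest.approx(b.as_array())


def test_scale_invariance_of_features(config, training_set):
    """A subject twice the size yields near-identical ratio and angle."""
    from fallert.experiment import run_scenario
    from fallert.scene_synth import default_script

    def median_features(scale):
        script = default_script("WALK", seed=11, subject_scale=scale)
        result = run_scenario(script, config, training_set)
        ratios = [st.ratio for fr in result.statuses for st in fr
                  if st.bbox is not None]
        angles = [st.angle for fr in result.statuses for st in fr
                  if st.bbox is not None]
        return np.median(ratios[10:]), np.median(angles[10:])

    r1, a1 = median_features(1.0)
    r2, a2 = median_features(2.0)
    assert abs(r2 - r1) / r1 < 0.05
    assert abs(a2 - a1) / a1 < 0.05
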