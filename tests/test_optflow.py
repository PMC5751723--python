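"""Point seeding, Lucas–Kanade advection and statistical pruning."""

import numpy as np
import pytest

from _oracles import prune_oracle
from fallert.config import FlowConfig
from fallert.optflow import (PointCloud, advect, base_set_indices,
                             motion_summary, prune_outliers, seed_points)


def _textured(rng, h=120, w=160):
    coarse = rng.normal(120, 40, size=(h // 4, w // 4))
    return np.kron(coarse, np.ones((4, 4)))[:h, :w] + rng.normal(0, 2, (h, w))


def _cloud(displacements, ages=None, points=None):
    displacements = np.asarray(displacements, dtype=float)
    n = len(displacements)
    return PointCloud(
        points=points if points is not None else np.tile([50.0, 50.0], (n, 1)),
        displacements=displacements,
        doubtful_age=np.zeros(n, dtype=int) if ages is None else
        np.asarray(ages, dtype=int))


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def test_seed_points_empty_mask():
    cloud = seed_points(np.zeros((50, 50)), np.zeros((50, 50), dtype=bool))
    assert len(cloud) == 0


def test_seed_points_uniform_region_may_be_empty():
    frame = np.full((60, 60), 128.0)
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:50] = True
    cloud = seed_points(frame, mask)          # no texture, no corners: fine
    assert len(cloud) >= 0


def test_seed_points_textured_subject(rng):
    frame = _textured(rng)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[20:100, 40:120] = True
    cloud = seed_points(frame, mask)
    assert len(cloud) >= 10
    xs, ys = cloud.points[:, 0].astype(int), cloud.points[:, 1].astype(int)
    assert mask[ys, xs].all()


def test_seed_points_respects_cap(rng):
    frame = _textured(rng)
    mask = np.ones(frame.shape, dtype=bool)
    cloud = seed_points(frame, mask, FlowConfig(max_points=5))
    assert len(cloud) <= 5


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------

def test_advect_identical_frames_zero_displacement(rng):
    frame = _textured(rng)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[20:100, 40:120] = True
    cloud = seed_points(frame, mask)
    moved = advect(cloud, frame, frame)
    assert len(moved) > 0
    assert np.abs(moved.displacements).max() < 0.1


def test_advect_recovers_translation(rng):
    frame = _textured(rng)
    shifted = np.roll(frame, 3, axis=1)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[30:90, 40:100] = True
    cloud = seed_points(frame, mask)
    moved = advect(cloud, frame, shifted)
    mean = moved.displacements.mean(axis=0)
    assert np.hypot(mean[0] - 3.0, mean[1]) < 0.5


def test_advect_never_invents_points(rng):
    a = rng.normal(128, 30, size=(80, 80))
    b = rng.normal(128, 30, size=(80, 80))
    mask = np.ones((80, 80), dtype=bool)
    cloud = seed_points(a, mask)
    moved = advect(cloud, a, b)
    assert len(moved) <= len(cloud)


def test_advect_dimension_mismatch():
    cloud = _cloud([[1, 0]] * 6)
    with pytest.raises(ValueError):
        advect(cloud, np.zeros((50, 50)), np.zeros((60, 60)))


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def test_base_set_size_and_tie_break():
    mags = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.0, 9.0, 9.0, 9.0, 9.0])
    base = base_set_indices(mags, 0.4)
    assert len(base) == 4
    assert list(base) == [0, 1, 2, 3]      # all tie: earliest indices win


def test_homogeneous_cloud_nothing_flagged():
    cloud = _cloud([[2.0, 0.0]] * 20)
    out = prune_outliers(cloud)
    assert len(out) == 20
    assert (out.doubtful_age == 0).all()


def test_small_cloud_pruning_skipped():
    cloud = _cloud([[0.0, 0.0], [9.0, 9.0], [1.0, 1.0], [2.0, 2.0]])
    out = prune_outliers(cloud)
    assert len(out) == 4


def test_planted_outlier_removed_on_third_frame(rng):
    cfg = FlowConfig()
    disps = np.tile([2.0, 0.0], (20, 1)) + rng.normal(0, 0.05, (20, 2))
    disps[7] = [-20.0, 15.0]               # huge, incoherent direction
    cloud = _cloud(disps)
    for frame in range(3):
        cloud = prune_outliers(cloud, cfg)
        if frame < 2:
            assert len(cloud) == 20
            assert cloud.doubtful_age.max() == frame + 1
            cloud.displacements = disps[:len(cloud)].copy()
            cloud.displacements[7] = [-20.0, 15.0]
    assert len(cloud) == 19


def test_direction_coherent_deviant_survives(rng):
    """Magnitude deviation alone does not remove a direction-coherent point."""
    disps = np.tile([2.0, 0.0], (20, 1)) + rng.normal(0, 0.02, (20, 2))
    disps[3] = [30.0, 0.0]                 # way off in magnitude, same direction
    cloud = _cloud(disps, ages=[2] + [0] * 19)
    cloud.doubtful_age[3] = 2
    out = prune_outliers(cloud)
    assert len(out) == 20


def test_removal_bounded_per_pass(rng):
    disps = rng.normal(0, 0.1, size=(40, 2))
    disps[:, 0] += 2.0
    disps[20:] = rng.uniform(-30, 30, size=(20, 2))   # half the cloud is junk
    cloud = _cloud(disps, ages=[0] * 20 + [3] * 20)
    out = prune_outliers(cloud)
    assert len(cloud) - len(out) <= int(np.ceil(0.25 * 40))


def test_prune_matches_brute_force_oracle(rng):
    cfg = FlowConfig()
    for _ in range(100):
        n = int(rng.integers(5, 120))
        disps = rng.normal(0, 1.5, size=(n, 2)) + [2.5, 0.0]
        outliers = rng.random(n) < 0.1
        disps[outliers] = rng.uniform(-25, 25, size=(outliers.sum(), 2))
        ages = rng.integers(0, 4, size=n)
        cloud = _cloud(disps, ages=ages)
        out = prune_outliers(cloud, cfg)
        keep, new_ages = prune_oracle(cloud.points, disps, ages)
        assert len(out) == keep.sum()
        np.testing.assert_array_equal(out.doubtful_age, new_ages[keep])
        np.testing.assert_array_equal(out.displacements, disps[keep])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
                min_size=5, max_size=80),
       st.lists(st.integers(0, 3), min_size=80, max_size=80))
def test_pruning_invariants_hold_for_any_cloud(disps, ages):
    """Base-set size, age bounds and the removal cap are structural."""
    n = len(disps)
    cloud = _cloud(disps, ages=ages[:n])
    mags = np.hypot(cloud.displacements[:, 0], cloud.displacements[:, 1])
    assert len(base_set_indices(mags, 0.4)) == int(np.floor(0.4 * n))
    out = prune_outliers(cloud)
    assert n - len(out) <= int(np.ceil(0.25 * n))
    assert set(np.unique(out.doubtful_age)) <= {0, 1, 2, 3}


# ---------------------------------------------------------------------------
# Motion summary
# ---------------------------------------------------------------------------

def _with_history(vectors):
    cloud = _cloud([[0.0, 0.0]] * 6)
    for v in vectors:
        cloud.history.append(np.asarray(v, dtype=float))
    return cloud


def test_motion_summary_static():
    cloud = _with_history([[0.0, 0.0]] * 5)
    ev = motion_summary(cloud)
    assert ev.is_static and ev.mean_magnitude == 0.0


def test_motion_summary_drift():
    cloud = _with_history([[3.0, 0.0]] * 5)
    ev = motion_summary(cloud)
    assert not ev.is_static
    assert ev.mean_magnitude == pytest.approx(3.0)


def test_motion_summary_microjitter_not_static(rng):
    """A standing person's jitter stays above the static threshold."""
    angles = rng.uniform(0, 2 * np.pi, size=5)
    cloud = _with_history([[0.8 * np.cos(a), 0.8 * np.sin(a)] for a in angles])
    ev = motion_summary(cloud)
    assert ev.mean_magnitude == pytest.approx(0.8, abs=1e-6)
    assert not ev.is_static


def test_motion_summary_no_history():
    assert motion_summary(_cloud([[1.0, 0.0]] * 6)) is None
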