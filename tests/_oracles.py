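"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is a deliberately literal, loop-based re-implementation of a
rule, kept free of any code shared with the library path it checks.
"""

from __future__ import annotations

import math

import numpy as np


def prune_oracle(points, displacements, ages, base_fraction=0.4, flag_sigma=1.5,
                 max_age=3, coherence_angle_deg=60.0, max_removed_frac=0.25):
    """Literal transcription of the point-cloud pruning rule.

    Returns (keep_mask, new_ages) over the input points.
    """
    n = len(points)
    if n < 5:
        return np.ones(n, dtype=bool), np.asarray(ages).copy()
    mags = [math.hypot(dx, dy) for dx, dy in displacements]
    mean_mag = sum(mags) / n
    # base set: floor(0.4 n) points closest to the mean magnitude, ties by index
    order = sorted(range(n), key=lambda i: (abs(mags[i] - mean_mag), i))
    k = int(math.floor(base_fraction * n))
    base = sorted(order[:k])
    mu = sum(mags[i] for i in base) / len(base)
    var = sum((mags[i] - mu) ** 2 for i in base) / len(base)
    sd = math.sqrt(var)

    new_ages = []
    for i in range(n):
        if abs(mags[i] - mu) > flag_sigma * sd:
            new_ages.append(min(ages[i] + 1, max_age))
        else:
            new_ages.append(0)

    bx = sum(displacements[i][0] for i in base) / len(base)
    by = sum(displacements[i][1] for i in base) / len(base)
    base_norm = math.hypot(bx, by)
    removable = []
    for i in range(n):
        if new_ages[i] < max_age:
            continue
        if base_norm <= 1e-9:
            removable.append(i)
            continue
        dx, dy = displacements[i]
        norm = math.hypot(dx, dy)
        if norm <= 1e-9:
            removable.append(i)
            continue
        cosang = (dx * bx + dy * by) / (norm * base_norm)
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ang > coherence_angle_deg:
            removable.append(i)

    cap = int(math.ceil(max_removed_frac * n))
    if len(removable) > cap:
        removable = sorted(removable,
                           key=lambda i: (-abs(mags[i] - mu), i))[:cap]
    keep = np.ones(n, dtype=bool)
    keep[list(removable)] = False
    return keep, np.asarray(new_ages)


def knn_oracle(query, train_x, train_is_fall, k=3, eps=1e-6):
    """Exhaustive-search KNN with the inverse-distance vote rule."""
    dists = []
    for i, row in enumerate(train_x):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(query, row)))
        dists.append((d, i))
    dists.sort(key=lambda t: (t[0], t[1]))
    fall_vote = not_fall_vote = 0.0
    for d, i in dists[:k]:
        vote = 1.0 / (d + eps)
        if train_is_fall[i]:
            fall_vote += vote
        else:
            not_fall_vote += vote
    return fall_vote >= not_fall_vote      # ties break toward FALL
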