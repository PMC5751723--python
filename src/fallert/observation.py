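"""Per-frame silhouette geometry shared across modules."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Ellipse:
    """Second-moment ellipse of a pixel set."""

    centre: tuple[float, float]        # x, y
    semi_major: float
    semi_minor: float
    orientation: float                 # degrees vs. image x-axis, in [0, 180)


@dataclass
class SubjectObservation:
    """Measured silhouette geometry for one subject in one frame."""

    bbox: tuple[int, int, int, int]    # x, y, w, h
    ellipse: Ellipse
    area: int                          # foreground pixel count
    centroid: tuple[float, float]      # x, y
    coords: np.ndarray | None = None   # (N, 2) pixel (row, col) coordinates

    def __post_init__(self):
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError("observation bbox must have positive extent")

    @property
    def ratio(self) -> float:
        """Width/height of the bounding rectangle."""
        return self.bbox[2] / self.bbox[3]


def ellipse_from_coords(coords: np.ndarray) -> Ellipse:
    """Fit a second-moment ellipse to pixel (row, col) coordinates.

    The returned orientation is the angle between the image x-axis and
    the major axis, folded to [0, 180): an upright silhouette reads 90°,
    a lying one reads near 0°.
    """
    coords = np.asarray(coords, dtype=np.float64)
    ys, xs = coords[:, 0], coords[:, 1]
    cx, cy = xs.mean(), ys.mean()
    if len(coords) < 3:
        return Ellipse((cx, cy), 1.0, 1.0, 90.0)
    cov = np.cov(np.stack([xs, ys]))
    evals, evecs = np.linalg.eigh(cov)        # ascending eigenvalues
    major = evecs[:, 1]
    # y grows downward in image coordinates; flip for a conventional angle
    angle = math.degrees(math.atan2(-major[1], major[0])) % 180.0
    # solid-ellipse relation between second moments and semi-axes
    semi_major = 2.0 * math.sqrt(max(evals[1], 0.25))
    semi_minor = 2.0 * math.sqrt(max(evals[0], 0.25))
    return Ellipse((cx, cy), semi_major, semi_minor, angle)
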