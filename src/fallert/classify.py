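"""Silhouette features and KNN fall/not-fall classification.

The classifier input is a five-dimensional feature vector per frame:

* ``angle`` — the fitted ellipse's major-axis angle vs. the image
  x-axis (optionally folded to [0°, 90°] so left and right falls are
  treated symmetrically),
* ``ratio`` — bounding-box width/height (< 1 standing, > 1 lying
  perpendicular to the camera),
* the three most recent Kalman-filtered values of the absolute
  normalised ratio-change speed, which capture how fast the silhouette
  is deforming and separate stable states from transitions.

Features are min-max normalised with bounds fitted on the training set,
and each of the three ratio-speed copies is down-weighted by 1/sqrt(3) so
the triplicated feature contributes one unit of squared Euclidean
distance, like any single dimension.  Voting among the k nearest
neighbours is inverse-distance weighted; exact ties break toward FALL,
since missing a fall is the costly error.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from fallert.config import ClassifierConfig
from fallert.observation import SubjectObservation
from fallert.tracking import KalmanTrackState

N_FEATURES = 5
_VR_WEIGHT = 1.0 / np.sqrt(3.0)


class StateLabel(str, Enum):
    FALL = "FALL"
    NOT_FALL = "NOT_FALL"


@dataclass
class FeatureSample:
    """One frame's classifier input."""

    angle: float                        # degrees
    ratio: float                        # w/h, dimensionless
    vratio_hist: tuple[float, float, float]   # most recent first
    label: StateLabel | None = None

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if len(self.vratio_hist) != 3:
            raise ValueError("vratio_hist must hold exactly 3 values")

    def as_array(self) -> np.ndarray:
        return np.array([self.angle, self.ratio, *self.vratio_hist], dtype=np.float64)


def compute_features(observation: SubjectObservation,
                     filtered_state: KalmanTrackState,
                     prev_ratio: float | None,
                     vratio_hist: tuple[float, float, float],
                     cfg: ClassifierConfig | None = None
                     ) -> tuple[FeatureSample, float]:
    """Assemble a feature sample and this frame's raw ratio-speed measurement.

    ``prev_ratio`` is the previous frame's raw ratio (``None`` at track
    birth); the returned measurement ``|ratio_t - ratio_{t-1}| /
    ratio_{t-1}`` is what the Kalman filter ingests as the ratio-change
    speed, and ``vratio_hist`` holds the three most recent *filtered*
    values (zero-padded at track start).  Angle and ratio entering the
    sample are the Kalman-filtered values.
    """
    cfg = cfg or ClassifierConfig()
    if observation.bbox[3] == 0:
        raise ValueError("observation height is zero")
    raw_ratio = observation.ratio
    if prev_ratio is None or prev_ratio <= 0:
        vratio_meas = 0.0
    else:
        vratio_meas = abs(raw_ratio - prev_ratio) / prev_ratio
    angle = filtered_state.angle
    if cfg.fold_angle:
        angle = min(angle % 180.0, 180.0 - angle % 180.0)
    sample = FeatureSample(angle=angle, ratio=max(filtered_state.ratio, 1e-6),
                           vratio_hist=vratio_hist)
    return sample, vratio_meas


# ---------------------------------------------------------------------------
# Training set
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Labelled samples plus the normalisation recipe fitted on them."""

    samples: list[FeatureSample]
    lo: np.ndarray = field(default=None)     # per-dimension minima
    hi: np.ndarray = field(default=None)     # per-dimension maxima
    weights: np.ndarray = field(default=None)
    k: int = 3

    def __post_init__(self):
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if self.weights is None:
            self.weights = np.array([1.0, 1.0, _VR_WEIGHT, _VR_WEIGHT, _VR_WEIGHT])
        if self.lo is None or self.hi is None:
            self.fit_bounds()
        labels = {s.label for s in self.samples}
        if self.samples and labels != {StateLabel.FALL, StateLabel.NOT_FALL}:
            raise ValueError("training set must contain both labels")
        self._matrix = None

    def fit_bounds(self) -> None:
        X = np.stack([s.as_array() for s in self.samples])
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = np.stack([
                normalize_and_weight(s, self) for s in self.samples])
        return self._matrix

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label == StateLabel.FALL for s in self.samples])

    # -- persistence: CSV of samples + JSON sidecar with the recipe ---------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "angle", "ratio", "vr1", "vr2", "vr3"])
            for s in self.samples:
                writer.writerow([s.label.value, repr(float(s.angle)),
                                 repr(float(s.ratio)),
                                 *[repr(float(v)) for v in s.vratio_hist]])
        sidecar = {"lo": self.lo.tolist(), "hi": self.hi.tolist(),
                   "weights": self.weights.tolist(), "k": self.k}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingSet":
        path = Path(path)
        samples = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                samples.append(FeatureSample(
                    angle=float(row["angle"]), ratio=float(row["ratio"]),
                    vratio_hist=(float(row["vr1"]), float(row["vr2"]),
                                 float(row["vr3"])),
                    label=StateLabel(row["label"])))
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(samples=samples, lo=np.array(sidecar["lo"]),
                   hi=np.array(sidecar["hi"]),
                   weights=np.array(sidecar["weights"]), k=int(sidecar["k"]))


def normalize_and_weight(sample: FeatureSample, training: TrainingSet) -> np.ndarray:
    """Min-max scale to [0, 1] with training bounds, then apply weights.

    Values outside the bounds are clamped; a degenerate dimension
    (min == max) maps to 0.5.
    """
    x = sample.as_array()
    span = training.hi - training.lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (x - training.lo) / span
    scaled = np.where(span > 0, np.clip(scaled, 0.0, 1.0), 0.5)
    return scaled * training.weights


def knn_classify(vector: np.ndarray, training: TrainingSet,
                 cfg: ClassifierConfig | None = None) -> StateLabel:
    """Distance-weighted k-nearest-neighbour vote.

    Each of the k nearest training points casts a vote weighted
    1/(d + eps); the label with the larger total wins, exact ties
    breaking toward FALL.
    """
    cfg = cfg or ClassifierConfig()
    if not training.samples:
        raise ValueError("empty training set")
    k = min(training.k, len(training.samples))
    d = np.linalg.norm(training.matrix - np.asarray(vector), axis=1)
    order = np.lexsort((np.arange(len(d)), d))
    nearest = order[:k]
    votes = 1.0 / (d[nearest] + cfg.vote_epsilon)
    is_fall = training.labels[nearest]
    fall_vote = votes[is_fall].sum()
    not_fall_vote = votes[~is_fall].sum()
    return StateLabel.FALL if fall_vote >= not_fall_vote else StateLabel.NOT_FALL


def classify_sample(sample: FeatureSample, training: TrainingSet,
                    cfg: ClassifierConfig | None = None) -> StateLabel:
    return knn_classify(normalize_and_weight(sample, training), training, cfg)


# ---------------------------------------------------------------------------
# Training-set construction from track histories
# ---------------------------------------------------------------------------

def build_training_set(track_csv_files: list[str | Path],
                       labelled_intervals: dict[str, list[tuple[int, int, str]]],
                       k: int = 3, fold_angle: bool = True) -> TrainingSet:
    """Assemble labelled samples from exported track-history CSVs.

    ``labelled_intervals`` maps each file name (key: ``Path(...).name``)
    to half-open ``(start_frame, end_frame, label)`` intervals, the
    manually identified fall / not-fall stretches of that recording.
    One sample per frame inside a labelled interval; the three-frame
    ratio-speed history is reconstructed per track from consecutive
    rows.  Normalisation bounds are fitted on the assembled samples.
    """
    import pandas as pd

    samples: list[FeatureSample] = []
    for path in track_csv_files:
        path = Path(path)
        intervals = labelled_intervals.get(path.name)
        if intervals is None:
            raise KeyError(f"no labelled intervals for {path.name}")
        df = pd.read_csv(path)
        max_frame = int(df["frame"].max()) if len(df) else -1
        for start, end, label in intervals:
            wanted = df[(df["frame"] >= start) & (df["frame"] < end)]
            if wanted.empty:
                raise ValueError(
                    f"{path.name}: interval [{start}, {end}) references no "
                    f"tracked frames (history ends at frame {max_frame})")
            for tid, g in wanted.groupby("id"):
                g = g.sort_values("frame")
                vr = g["vratio_filt"].to_numpy()
                for i in range(len(g)):
                    hist = tuple(vr[max(0, i - 2): i + 1][::-1])
                    hist = tuple(hist) + (0.0,) * (3 - len(hist))
                    row = g.iloc[i]
                    angle = float(row["angle_filt"]) % 180.0
                    if fold_angle:
                        angle = min(angle, 180.0 - angle)
                    samples.append(FeatureSample(
                        angle=angle,
                        ratio=float(row["ratio_filt"]),
                        vratio_hist=hist,
                        label=StateLabel(label)))
    return TrainingSet(samples=samples, k=k)
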