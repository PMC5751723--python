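"""Background modelling with selective learning.

A per-pixel mixture of Gaussian components models the static scene.
Each frame is processed in two passes:

1. an *analysis* pass (:meth:`MixtureBackgroundModel.subtract`) that
   classifies pixels as background / shadow / foreground **without**
   updating the model, and
2. a *learning* pass (:meth:`MixtureBackgroundModel.selective_learn`)
   on a composite frame in which confirmed subject regions are replaced
   by the model's expected background, so a fast learning rate can be
   used without ever absorbing the subject into the background.

Shadows are pixels darker than, but chromatically consistent with, the
expected background; they are excluded from foreground area entirely.
Foreground components are extracted as contours and, when a subject's
silhouette is split by similarly coloured scenery, the fragments inside
the tracker's predicted region are aggregated into a single observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from fallert.config import BackgroundConfig
from fallert.observation import SubjectObservation, ellipse_from_coords

BACKGROUND = 0
SHADOW = 127
FOREGROUND = 255


class MixtureBackgroundModel:
    """Per-pixel mixture of up to K Gaussian components.

    Works on grayscale ``(H, W)`` or colour ``(H, W, C)`` frames; each
    component keeps a mean per channel and a single scalar variance.
    """

    def __init__(self, frame_shape: tuple[int, ...], config: BackgroundConfig | None = None):
        self.config = config or BackgroundConfig()
        if len(frame_shape) == 2:
            h, w = frame_shape
            c = 1
        elif len(frame_shape) == 3:
            h, w, c = frame_shape
        else:
            raise ValueError(f"unsupported frame shape {frame_shape}")
        self.shape = (h, w)
        self.channels = c
        k = self.config.n_components
        self.weight = np.zeros((k, h, w), dtype=np.float32)
        self.mean = np.zeros((k, h, w, c), dtype=np.float32)
        self.var = np.full((k, h, w), self.config.initial_variance, dtype=np.float32)
        self._initialized = False

    # -- helpers ------------------------------------------------------------

    def _as_float(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame)
        if frame.shape[:2] != self.shape or \
                (frame.ndim == 2) != (self.channels == 1) or \
                (frame.ndim == 3 and frame.shape[2] != self.channels):
            raise ValueError(f"frame shape {frame.shape} does not match model "
                             f"{self.shape} x{self.channels}")
        f = frame.astype(np.float32)
        if f.ndim == 2:
            f = f[..., None]
        return f

    def initialize(self, frame: np.ndarray) -> None:
        """Seed the model with a frame as the sole background component."""
        f = self._as_float(frame)
        self.weight[:] = 0.0
        self.weight[0] = 1.0
        self.mean[0] = f
        self.var[:] = self.config.initial_variance
        self._initialized = True

    @property
    def expected_background(self) -> np.ndarray:
        """Highest-weight component mean per pixel."""
        idx = np.argmax(self.weight, axis=0)                      # (H, W)
        bg = np.take_along_axis(self.mean, idx[None, ..., None], axis=0)[0]
        return bg[..., 0] if self.channels == 1 else bg

    def _match(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-component squared distance and match flags for a frame."""
        d2 = ((f[None] - self.mean) ** 2).sum(axis=-1)            # (K, H, W)
        thresh = (self.config.match_sigma ** 2) * self.var * self.channels
        matched = (d2 <= thresh) & (self.weight > 0)
        return d2, matched

    # -- analysis pass ------------------------------------------------------

    def subtract(self, frame: np.ndarray) -> np.ndarray:
        """Classify pixels; performs no model update.

        Returns a uint8 mask with values :data:`BACKGROUND`,
        :data:`SHADOW` and :data:`FOREGROUND`.
        """
        if not self._initialized:
            raise RuntimeError("model not initialized; call initialize() first")
        f = self._as_float(frame)
        _, matched = self._match(f)
        bg_hit = (matched & (self.weight >= self.config.bg_weight_threshold)).any(axis=0)
        mask = np.where(bg_hit, BACKGROUND, FOREGROUND).astype(np.uint8)
        if self.config.shadow_enabled:
            fg = mask == FOREGROUND
            if fg.any():
                bg = self.expected_background
                bgf = bg[..., None] if bg.ndim == 2 else bg
                denom = np.maximum(bgf, 1.0)
                ratio = f / denom
                bright = ratio.mean(axis=-1)
                chroma_ok = (ratio.max(axis=-1) - ratio.min(axis=-1)) < 0.15 \
                    if self.channels > 1 else np.ones(self.shape, dtype=bool)
                shadow = fg & chroma_ok & \
                    (bright >= self.config.shadow_lo) & (bright <= self.config.shadow_hi)
                mask[shadow] = SHADOW
        return mask

    # -- learning pass ------------------------------------------------------

    def learn(self, frame: np.ndarray) -> None:
        """Ordinary mixture update with the configured learning rate."""
        if not self._initialized:
            self.initialize(frame)
            return
        f = self._as_float(frame)
        alpha = self.config.learning_rate
        d2, matched = self._match(f)
        any_match = matched.any(axis=0)
        # among matched components pick the heaviest
        score = np.where(matched, self.weight, -1.0)
        best = np.argmax(score, axis=0)                           # (H, W)
        onehot = np.zeros_like(self.weight, dtype=bool)
        np.put_along_axis(onehot, best[None], True, axis=0)
        chosen = onehot & any_match[None]

        self.weight *= (1.0 - alpha)
        self.weight[chosen] += alpha
        rho = alpha
        diff = f[None] - self.mean
        self.mean += np.where(chosen[..., None], rho * diff, 0.0)
        self.var += np.where(chosen, rho * (d2 / self.channels - self.var), 0.0)

        # unmatched pixels: replace the weakest component with the pixel value
        replace = ~any_match
        if replace.any():
            weakest = np.argmin(self.weight, axis=0)
            rep = np.zeros_like(self.weight, dtype=bool)
            np.put_along_axis(rep, weakest[None], True, axis=0)
            rep &= replace[None]
            self.weight[rep] = alpha
            self.mean[rep.nonzero()] = f[rep.any(axis=0)]
            self.var[rep] = self.config.initial_variance

        np.clip(self.var, self.config.min_variance, None, out=self.var)
        self.weight /= self.weight.sum(axis=0, keepdims=True)

    def selective_learn(self, frame: np.ndarray,
                        protect_mask: np.ndarray | None = None) -> None:
        """Learning pass on a composite frame.

        Pixels under ``protect_mask`` (confirmed subject regions) are
        substituted by the expected background before the update, so the
        model re-learns its own background there and the subject never
        drifts into it.  An empty/None mask is an ordinary update.
        """
        if protect_mask is None or not np.any(protect_mask):
            self.learn(frame)
            return
        protect_mask = np.asarray(protect_mask, dtype=bool)
        if protect_mask.shape != self.shape:
            raise ValueError("protect_mask shape mismatch")
        composite = self._as_float(frame).copy()
        bg = self.expected_background
        bgf = bg[..., None] if bg.ndim == 2 else bg
        composite[protect_mask] = bgf[protect_mask]
        self.learn(composite[..., 0] if self.channels == 1 else composite)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """A connected foreground component."""

    area: int                                  # pixel count
    bbox: tuple[int, int, int, int]            # x, y, w, h
    centroid: tuple[float, float]              # x, y
    coords: np.ndarray                         # (N, 2) array of (row, col)

    def intersects(self, rect: tuple[float, float, float, float]) -> bool:
        x, y, w, h = rect
        bx, by, bw, bh = self.bbox
        return not (bx + bw <= x or x + w <= bx or by + bh <= y or y + h <= by)


def extract_contours(mask: np.ndarray, min_area: int) -> list[Contour]:
    """Connected FOREGROUND components with area >= ``min_area``.

    Shadow pixels are excluded — they never count towards foreground
    area downstream.
    """
    binary = np.asarray(mask) == FOREGROUND
    labels = measure.label(binary, connectivity=2)
    out: list[Contour] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        minr, minc, maxr, maxc = region.bbox
        cy, cx = region.centroid
        out.append(Contour(
            area=int(region.area),
            bbox=(int(minc), int(minr), int(maxc - minc), int(maxr - minr)),
            centroid=(float(cx), float(cy)),
            coords=region.coords,
        ))
    return out


def expand_region(rect: tuple[float, float, float, float],
                  margin_frac: float) -> tuple[float, float, float, float]:
    x, y, w, h = rect
    mx, my = margin_frac * w, margin_frac * h
    return (x - mx, y - my, w + 2 * mx, h + 2 * my)


def aggregate_broken_contours(contours: list[Contour],
                              predicted_region: tuple[float, float, float, float],
                              ) -> SubjectObservation | None:
    """Merge the contours intersecting a predicted subject region.

    Background subtraction can split a subject moving through
    similarly-coloured scenery into several fragments; all fragments
    intersecting the (margin-expanded) Kalman-predicted rectangle are
    pooled into one observation whose bounding box is the union, whose
    area is the sum of member areas and whose ellipse is fitted to the
    pooled pixels.  Returns ``None`` when nothing intersects — the
    subject is unobserved this frame.
    """
    members = [c for c in contours if c.intersects(predicted_region)]
    if not members:
        return None
    coords = np.concatenate([c.coords for c in members], axis=0)
    rows, cols = coords[:, 0], coords[:, 1]
    x0, y0 = int(cols.min()), int(rows.min())
    w = int(cols.max()) - x0 + 1
    h = int(rows.max()) - y0 + 1
    area = sum(c.area for c in members)
    centroid = (float(cols.mean()), float(rows.mean()))
    ellipse = ellipse_from_coords(coords)
    return SubjectObservation(bbox=(x0, y0, w, h), ellipse=ellipse,
                              area=area, centroid=centroid, coords=coords)


def build_protect_mask(shape: tuple[int, int],
                       rects: list[tuple[float, float, float, float]],
                       dilate_px: int = 5) -> np.ndarray:
    """Union of subject rectangles dilated by a fixed margin."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for (x, y, rw, rh) in rects:
        x0 = max(int(np.floor(x)) - dilate_px, 0)
        y0 = max(int(np.floor(y)) - dilate_px, 0)
        x1 = min(int(np.ceil(x + rw)) + dilate_px, w)
        y1 = min(int(np.ceil(y + rh)) + dilate_px, h)
        mask[y0:y1, x0:x1] = True
    return mask


def save_mask(mask: np.ndarray, path) -> None:
    """Debug export of a classification mask as an 8-bit PNG."""
    import imageio.v3 as iio
    iio.imwrite(path, np.asarray(mask, dtype=np.uint8))
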