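"""Debounced alert state machine with pluggable delivery sinks.

A fall alert is only emitted after the track has been continuously in a
fall state (classifier FALL or an occluded fall) for a configurable
delay, 2 s by default: the transition phases between standing and lying
produce unstable classifications that must never reach a caregiver.
Recovery is debounced symmetrically, so a fallen subject unsuccessfully
trying to rise does not flap between alerts.  Events alternate strictly
FALL_ALERT / RECOVERY per track.

Delivery is a sink interface: any callable or :class:`AlertSink` can be
registered; the bundled :class:`FileSink` writes a message file (event
type, timestamp, snapshot path) next to the snapshot image.  One failing
sink never blocks the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from fallert.config import AlertConfig
from fallert.pipeline import TrackStatus


class AlertType(str, Enum):
    FALL_ALERT = "FALL_ALERT"
    RECOVERY = "RECOVERY"


@dataclass(frozen=True)
class AlertEvent:
    type: AlertType
    track_id: int
    frame: int
    time: float                        # seconds since stream start
    snapshot: str | None = None        # image path, if a snapshot was written


@dataclass
class _TrackAlertState:
    run_state: bool | None = None      # True while in fall-state run
    run_start: float = 0.0
    alert_active: bool = False
    fired_this_run: bool = False


@dataclass
class DebouncedAlerter:
    """Per-track debounce of fall / recovery events."""

    config: AlertConfig = field(default_factory=AlertConfig)
    _tracks: dict[int, _TrackAlertState] = field(default_factory=dict)

    def debounce_step(self, status: TrackStatus, time: float) -> AlertEvent | None:
        """Advance one frame for one track; maybe emit an event.

        ``status.is_fall_state`` folds both classifier FALL and the
        occluded-fall condition.  An unknown state (``None`` while the
        track is occluded but not fallen) interrupts any run.
        """
        ts = self._tracks.setdefault(status.track_id, _TrackAlertState())
        if status.state is None and not status.is_fall_state:
            ts.run_state = None        # unknown: reset the timer
            return None
        falling = status.is_fall_state
        if falling != ts.run_state:
            ts.run_state = falling
            ts.run_start = time
            ts.fired_this_run = False
        elapsed = time - ts.run_start
        if falling and not ts.alert_active and not ts.fired_this_run \
                and elapsed >= self.config.delay_s:
            ts.alert_active = True
            ts.fired_this_run = True
            return AlertEvent(AlertType.FALL_ALERT, status.track_id,
                              status.frame, time)
        if not falling and ts.alert_active and elapsed >= self.config.delay_s:
            ts.alert_active = False
            return AlertEvent(AlertType.RECOVERY, status.track_id,
                              status.frame, time)
        return None


# ---------------------------------------------------------------------------
# Sinks
# ---------------------------------------------------------------------------

class AlertSink:
    def deliver(self, event: AlertEvent, snapshot: np.ndarray | None) -> None:
        raise NotImplementedError


@dataclass
class FileSink(AlertSink):
    """Writes one message file (and the snapshot PNG) per event."""

    directory: Path

    def deliver(self, event: AlertEvent, snapshot: np.ndarray | None) -> None:
        self.directory = Path(self.directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        stem = f"{event.type.value.lower()}_track{event.track_id}_f{event.frame:06d}"
        snap_path = None
        if snapshot is not None and event.type is AlertType.FALL_ALERT:
            import imageio.v3 as iio
            snap_path = self.directory / f"{stem}.png"
            iio.imwrite(snap_path, np.asarray(snapshot, dtype=np.uint8))
        lines = [
            f"event: {event.type.value}",
            f"track: {event.track_id}",
            f"frame: {event.frame}",
            f"time_s: {event.time:.3f}",
        ]
        if snap_path is not None:
            lines.append(f"snapshot: {snap_path.name}")
        (self.directory / f"{stem}.txt").write_text("\n".join(lines) + "\n")


@dataclass
class CallbackSink(AlertSink):
    """Adapts any callable to the sink interface (webhook-style)."""

    callback: callable

    def deliver(self, event: AlertEvent, snapshot: np.ndarray | None) -> None:
        self.callback(event, snapshot)


@dataclass
class DeliveryRecord:
    event: AlertEvent
    delivered: list[str]
    failures: list[tuple[str, str]]    # (sink name, error message)


def annotate_snapshot(frame: np.ndarray, bbox: tuple[int, int, int, int] | None,
                      blur: bool = False) -> np.ndarray:
    """Current frame with the subject's bounding box drawn."""
    img = np.asarray(frame).copy()
    if blur:
        from scipy import ndimage
        img = ndimage.gaussian_filter(img, 3.0)
    if bbox is not None:
        x, y, w, h = bbox
        h_img, w_img = img.shape[:2]
        x0, x1 = np.clip([x, x + w - 1], 0, w_img - 1)
        y0, y1 = np.clip([y, y + h - 1], 0, h_img - 1)
        img[y0, x0:x1 + 1] = 255
        img[y1, x0:x1 + 1] = 255
        img[y0:y1 + 1, x0] = 255
        img[y0:y1 + 1, x1] = 255
    return img


def dispatch(event: AlertEvent, sinks: list[AlertSink],
             snapshot: np.ndarray | None = None) -> DeliveryRecord:
    """Deliver an event to every sink; isolate individual failures."""
    if not sinks:
        raise ValueError("at least one sink must be configured")
    delivered, failures = [], []
    for sink in sinks:
        name = type(sink).__name__
        try:
            sink.deliver(event, snapshot)
            delivered.append(name)
        except Exception as exc:        # noqa: BLE001 — sink isolation
            failures.append((name, str(exc)))
    if not delivered:
        raise RuntimeError(f"all sinks failed for {event.type.value}: {failures}")
    return DeliveryRecord(event=event, delivered=delivered, failures=failures)
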