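"""Dispersion-threshold segmentation of binocular gaze recordings.

The detector walks the version (cyclopean) signal sample by sample and
switches between four mutually exclusive states:

* **distortion** — the tracking signal is unusable (lost samples);
* **transient** — a stable run not yet long enough to be a fixation;
* **fixation** — a stable run spanning at least ``min_fixation`` ms;
* **saccade** — the eyes have moved beyond the dispersion threshold.

A sample is *stable* when both its horizontal and vertical version
position lie within ``dispersion_base + noise_multiplier * rms`` of the
running mean of the current state's samples, where ``rms`` is the RMS
deviation of the last ``noise_window`` samples of the current run from
their mean (a dynamic noise estimate; it resets at each state change).
A sample exactly at the threshold counts as within.  Whenever the state
changes, the previous run is emitted as one event, so the events of a
recording tile its sample range exactly.

Saccades are subsequently classified progressive (rightward) or
regressive (leftward); large leftward movements are return sweeps.
Fixations inherit the direction of the nearest preceding saccade.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .recording import GazeRecording

__all__ = [
    "DetectorConfig",
    "GazeEvent",
    "BinocularSignals",
    "binocular_signals",
    "rms_noise",
    "segment_events",
    "classify_directions",
    "detect_events",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the dispersion state machine.

    ``dispersion_base`` (deg) is the static part of the threshold,
    roughly the foveal extent; the dynamic part is ``noise_multiplier``
    times the RMS noise of the last ``noise_window`` samples of the
    current run.  ``min_fixation`` (ms) is the minimum stable span for a
    fixation; shorter stable runs are transients.  ``sweep_min_amplitude``
    (deg) is the leftward displacement at which a regressive movement is
    classified as a (return) sweep instead of a regressive saccade.
    """

    dispersion_base: float = 0.5
    noise_multiplier: float = 2.5
    noise_window: int = 25
    min_fixation: float = 50.0
    sweep_min_amplitude: float = 5.0

    def __post_init__(self) -> None:
        if min(
            self.dispersion_base,
            self.noise_multiplier,
            self.noise_window,
            self.min_fixation,
            self.sweep_min_amplitude,
        ) <= 0:
            raise ValueError("all detector parameters must be positive")


@dataclass
class GazeEvent:
    """One detected segment (inclusive sample span)."""

    kind: str  # fixation | saccade | sweep | transient | distortion
    direction: str  # progressive | regressive | none
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.start_idx > self.end_idx:
            raise ValueError("start_idx must be <= end_idx")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class BinocularSignals:
    """Per-sample version/vergence series of a recording.

    version = (left + right) / 2, vergence = left - right, per axis.
    Samples where either eye is invalid are nan in all four series and
    flagged unusable.
    """

    hor_version: np.ndarray
    vert_version: np.ndarray
    hor_vergence: np.ndarray
    vert_vergence: np.ndarray
    usable: np.ndarray = field(repr=False)

    def series(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            ("hor", "version"): self.hor_version,
            ("vert", "version"): self.vert_version,
            ("hor", "vergence"): self.hor_vergence,
            ("vert", "vergence"): self.vert_vergence,
        }


def binocular_signals(rec: GazeRecording) -> BinocularSignals:
    """Split the two-eye signal into conjugate and disconjugate components."""
    lx, ly, rx, ry = rec.pos.T
    usable = rec.valid[:, 0] & rec.valid[:, 1]
    out = BinocularSignals(
        hor_version=(lx + rx) / 2.0,
        vert_version=(ly + ry) / 2.0,
        hor_vergence=lx - rx,
        vert_vergence=ly - ry,
        usable=usable,
    )
    bad = ~usable
    for arr in (out.hor_version, out.vert_version, out.hor_vergence, out.vert_vergence):
        arr[bad] = np.nan
    return out


def rms_noise(series: np.ndarray, idx: int, window: int = 25) -> float:
    """RMS deviation from the mean of the last ``window`` usable samples
    ending at ``idx`` (inclusive).  Fewer than 2 usable samples -> 0."""
    if idx < 0:
        raise ValueError("idx must be >= 0")
    lo = max(0, idx - window + 1)
    chunk = np.asarray(series[lo : idx + 1], dtype=float)
    chunk = chunk[np.isfinite(chunk)]
    if len(chunk) < 2:
        return 0.0
    return float(np.sqrt(np.mean((chunk - chunk.mean()) ** 2)))


class _Run:
    """Current state's samples with O(1) running mean and windowed RMS."""

    __slots__ = ("n", "sx", "sy", "win", "wsx", "wsy", "wsx2", "wsy2", "maxlen")

    def __init__(self, maxlen: int) -> None:
        self.n = 0
        self.sx = 0.0
        self.sy = 0.0
        self.win: deque[tuple[float, float]] = deque()
        self.wsx = self.wsy = self.wsx2 = self.wsy2 = 0.0
        self.maxlen = maxlen

    def push(self, x: float, y: float) -> None:
        self.n += 1
        self.sx += x
        self.sy += y
        self.win.append((x, y))
        self.wsx += x
        self.wsy += y
        self.wsx2 += x * x
        self.wsy2 += y * y
        if len(self.win) > self.maxlen:
            ox, oy = self.win.popleft()
            self.wsx -= ox
            self.wsy -= oy
            self.wsx2 -= ox * ox
            self.wsy2 -= oy * oy

    def mean(self) -> tuple[float, float]:
        return self.sx / self.n, self.sy / self.n

    def rms(self) -> tuple[float, float]:
        m = len(self.win)
        if m < 2:
            return 0.0, 0.0
        vx = max(self.wsx2 / m - (self.wsx / m) ** 2, 0.0)
        vy = max(self.wsy2 / m - (self.wsy / m) ** 2, 0.0)
        return vx**0.5, vy**0.5


def segment_events(rec: GazeRecording, cfg: DetectorConfig = DetectorConfig()) -> list[GazeEvent]:
    """Run the dispersion state machine; events tile the recording exactly.

    Directions are not assigned here; see :func:`classify_directions`.
    """
    if rec.duration_ms < cfg.min_fixation:
        warnings.warn(
            f"recording {rec.subject_id}: shorter than min_fixation "
            f"({rec.duration_ms:.0f} ms); no events emitted",
            stacklevel=2,
        )
        return []

    sig = binocular_signals(rec)
    vx = sig.hor_version
    vy = sig.vert_version
    usable = sig.usable
    t = rec.t
    n = len(rec)

    events: list[GazeEvent] = []
    state: str | None = None
    start = 0
    run = _Run(cfg.noise_window)

    def flush(end: int) -> None:
        if state is not None and end >= start:
            kind = "transient" if state == "pending" else state
            events.append(GazeEvent(kind, "none", start, end))

    for i in range(n):
        if not usable[i]:
            if state != "distortion":
                flush(i - 1)
                state = "distortion"
                start = i
            continue
        x = vx[i]
        y = vy[i]
        if state is None or state == "distortion":
            flush(i - 1)
            state = "pending"
            start = i
            run = _Run(cfg.noise_window)
            run.push(x, y)
            continue
        mx, my = run.mean()
        rx, ry = run.rms()
        within = (
            abs(x - mx) <= cfg.dispersion_base + cfg.noise_multiplier * rx
            and abs(y - my) <= cfg.dispersion_base + cfg.noise_multiplier * ry
        )
        if state in ("pending", "fixation"):
            if within:
                run.push(x, y)
                if state == "pending" and t[i] - t[start] >= cfg.min_fixation:
                    state = "fixation"
            else:
                flush(i - 1)
                state = "saccade"
                start = i
                run = _Run(cfg.noise_window)
                run.push(x, y)
        else:  # saccade
            if within:
                flush(i - 1)
                state = "pending"
                start = i
                run = _Run(cfg.noise_window)
                run.push(x, y)
            else:
                run.push(x, y)
    flush(n - 1)
    return events


def classify_directions(
    events: list[GazeEvent],
    rec: GazeRecording,
    cfg: DetectorConfig = DetectorConfig(),
) -> list[GazeEvent]:
    """Assign progressive/regressive/sweep classes in place and return the list.

    A saccade's direction is its takeoff-to-landing horizontal version
    displacement: the nearest usable sample before the event to the
    nearest usable sample after it (falling back to the event's own
    endpoints at the recording edges).  Rightward -> progressive;
    leftward -> regressive, except movements of at least
    ``sweep_min_amplitude`` degrees leftward, which become sweeps.
    Fixations inherit the direction of the nearest preceding saccade;
    a fixation right after a sweep resumes forward reading and is
    progressive; fixations with no preceding saccade or sweep stay
    unclassified (``none``).
    """
    sig = binocular_signals(rec)
    vx = sig.hor_version
    usable = sig.usable
    n = len(rec)

    def nearest_usable(idx: int, step: int) -> int | None:
        while 0 <= idx < n:
            if usable[idx]:
                return idx
            idx += step
        return None

    current = "none"
    for ev in events:
        if ev.kind == "saccade":
            i0 = nearest_usable(ev.start_idx - 1, -1)
            i1 = nearest_usable(ev.end_idx + 1, +1)
            if i0 is None:
                i0 = nearest_usable(ev.start_idx, +1)
            if i1 is None:
                i1 = nearest_usable(ev.end_idx, -1)
            disp = 0.0 if i0 is None or i1 is None else float(vx[i1] - vx[i0])
            if disp > 0:
                ev.direction = "progressive"
                current = "progressive"
            elif disp < 0:
                if -disp >= cfg.sweep_min_amplitude:
                    ev.kind = "sweep"
                    ev.direction = "none"
                    current = "progressive"  # reading resumes after a sweep
                else:
                    ev.direction = "regressive"
                    current = "regressive"
            else:
                ev.direction = "none"
        elif ev.kind == "fixation":
            ev.direction = current
    return events


def detect_events(
    rec: GazeRecording, cfg: DetectorConfig = DetectorConfig()
) -> list[GazeEvent]:
    """Segment and direction-classify a recording in one call."""
    return classify_directions(segment_events(rec, cfg), rec, cfg)


def events_to_frame(rec: GazeRecording, events: list[GazeEvent]):
    """Tabulate events as rows of the delimited events-file format."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "kind": [e.kind for e in events],
            "direction": [e.direction for e in events],
            "start_ms": [float(rec.t[e.start_idx]) for e in events],
            "end_ms": [float(rec.t[e.end_idx]) for e in events],
            "start_idx": [e.start_idx for e in events],
            "end_idx": [e.end_idx for e in events],
        }
    )
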