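"""Synthetic binocular reading recordings.

Emulates silent reading of a short multi-line text: a cyclopean (version)
trajectory of fixations joined by rightward progressive saccades,
occasional leftward regressions, and a large leftward-and-downward return
sweep at each line end.  The left/right eye signals are the cyclopean
trajectory plus/minus half a slowly varying vergence offset (AR(1)),
with white measurement noise per eye, random both-eye signal dropouts,
and brief high-amplitude transient artifacts.

Every recording carries its ground-truth event list.  In the noiseless
limit (no measurement noise, dropouts or transients) the rendered events
exactly tile the sample timeline and are recoverable by the dispersion
detector in :mod:`gazescreen.detect`, which makes the generator usable as
an oracle for the detection stage.

Units: degrees of visual angle, milliseconds, Hz.  x grows rightward,
y grows downward; origin at the start of the first line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import GazeRecording, GroundTruthEvent

__all__ = [
    "TextLayout",
    "GroupGazeParams",
    "CohortSpec",
    "HR_DEFAULT_PARAMS",
    "LR_DEFAULT_PARAMS",
    "simulate_recording",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

# Fixation durations below ~60 ms would fall under the detector's 50 ms
# stability criterion; clip the lognormal draws away from that region.
_MIN_FIX_MS = 60.0
_MAX_FIX_MS = 800.0
_MIN_SACC_AMP = 1.1  # keeps every rendered saccade above the 0.5 deg dispersion threshold
_MAX_PROG_AMP = 6.0
_MAX_REGR_AMP = 4.5  # below the 5 deg sweep rule
_REGR_AMP_SCALE = 0.6  # regressions are smaller than progressive saccades
_VERGENCE_AR1 = 0.9


@dataclass(frozen=True)
class TextLayout:
    """Geometry of the stimulus text (content is abstracted away).

    Defaults describe a short age-adapted passage: 8 lines, 10 sentences
    averaging 4.6 words.
    """

    n_lines: int = 8
    sentences: int = 10
    mean_sentence_len: float = 4.6
    line_extent_deg: float = 20.0
    line_spacing_deg: float = 1.5

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.line_extent_deg <= 0 or self.line_spacing_deg <= 0:
            raise ValueError("line extents must be positive")


@dataclass(frozen=True)
class GroupGazeParams:
    """Generative gaze parameters of one subject group.

    ``fixation_dur_*`` parameterize a lognormal over fixation durations
    (ms); ``prog_saccade_amp_*`` a gamma over progressive saccade
    amplitudes (deg); ``regression_prob`` is the per-opportunity chance of
    a leftward regression; ``subject_cv`` is the coefficient of variation
    of per-subject lognormal jitter on the duration and amplitude means
    (between-subject heterogeneity).  Noise terms: AR(1) vergence offset
    SD, white per-eye measurement noise SD (deg), per-sample both-eye
    dropout probability, and transient artifacts per second.
    """

    fixation_dur_mean: float
    fixation_dur_sd: float
    prog_saccade_amp_mean: float
    prog_saccade_amp_sd: float
    regression_prob: float
    vergence_noise_sd: float = 0.2
    measurement_noise_sd: float = 0.1
    dropout_prob: float = 0.01
    transient_rate: float = 0.1
    subject_cv: float = 0.08

    def __post_init__(self) -> None:
        for name in (
            "fixation_dur_mean",
            "fixation_dur_sd",
            "prog_saccade_amp_mean",
            "prog_saccade_amp_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("regression_prob", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "vergence_noise_sd",
            "measurement_noise_sd",
            "transient_rate",
            "subject_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Readers at risk of persistent decoding difficulty: longer fixations,
#: shorter forward saccades, more regressions.
HR_DEFAULT_PARAMS = GroupGazeParams(
    fixation_dur_mean=280.0,
    fixation_dur_sd=70.0,
    prog_saccade_amp_mean=2.0,
    prog_saccade_amp_sd=0.8,
    regression_prob=0.35,
    vergence_noise_sd=0.3,
)

#: Typically developing readers.
LR_DEFAULT_PARAMS = GroupGazeParams(
    fixation_dur_mean=210.0,
    fixation_dur_sd=50.0,
    prog_saccade_amp_mean=3.0,
    prog_saccade_amp_sd=0.9,
    regression_prob=0.15,
    vergence_noise_sd=0.2,
)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic HR/LR cohort."""

    n_hr: int = 97
    n_lr: int = 88
    hr_params: GroupGazeParams = HR_DEFAULT_PARAMS
    lr_params: GroupGazeParams = LR_DEFAULT_PARAMS
    layout: TextLayout = field(default_factory=TextLayout)
    sampling_rate: float = 100.0
    duration_cap_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hr < 0 or self.n_lr < 0 or self.n_hr + self.n_lr < 2:
            raise ValueError("need n_hr + n_lr >= 2")
        if self.sampling_rate <= 0 or self.duration_cap_s <= 0:
            raise ValueError("sampling_rate and duration_cap_s must be positive")


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd**2 / mean))


def _ramp_fractions(amplitude: float) -> list[float]:
    """Interior sample positions of a saccade as fractions of its amplitude.

    The accelerating 1-3 sample profile keeps every interior sample beyond
    the detector's dispersion threshold of the run it leaves or joins, and
    the landing sample within threshold of the in-flight run, so detected
    boundaries coincide with the rendered ones on clean signals.
    """
    if amplitude <= 2.2:
        return [max(0.6, 1.0 - 0.45 / amplitude)]
    if amplitude <= 7.0:
        return [0.25, 0.7]
    return [0.12, 0.45, 0.82]


class _Builder:
    """Accumulates the cyclopean trajectory and its ground-truth events."""

    def __init__(self) -> None:
        self.x: list[float] = []
        self.y: list[float] = []
        self.events: list[GroundTruthEvent] = []

    def add(self, kind: str, direction: str, xs: list[float], ys: list[float]) -> None:
        start = len(self.x)
        self.x.extend(xs)
        self.y.extend(ys)
        self.events.append(GroundTruthEvent(kind, direction, start, len(self.x) - 1))

    def __len__(self) -> int:
        return len(self.x)


def simulate_recording(
    params: GroupGazeParams,
    layout: TextLayout = TextLayout(),
    sampling_rate: float = 100.0,
    duration_cap_s: float = 60.0,
    seed: int = 0,
    subject_id: str = "sim",
    label: str = "unknown",
) -> GazeRecording:
    """Simulate one subject's binocular reading recording.

    Identical ``(params, layout, sampling_rate, duration_cap_s, seed)``
    yield bit-identical recordings.  The returned recording carries the
    rendered ground-truth event list in ``ground_truth``.
    """
    if duration_cap_s <= 0:
        raise ValueError("duration_cap_s must be positive")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sampling_rate
    n_max = int(round(duration_cap_s * sampling_rate))

    # Per-subject multiplicative jitter on the two group-defining means.
    if params.subject_cv > 0:
        fix_mean = params.fixation_dur_mean * _lognormal(rng, 1.0, params.subject_cv)
        amp_mean = params.prog_saccade_amp_mean * _lognormal(rng, 1.0, params.subject_cv)
    else:
        fix_mean = params.fixation_dur_mean
        amp_mean = params.prog_saccade_amp_mean

    b = _Builder()

    def fixation_samples() -> int:
        dur = min(max(_lognormal(rng, fix_mean, params.fixation_dur_sd), _MIN_FIX_MS), _MAX_FIX_MS)
        return max(6, int(round(dur / dt_ms)))

    def add_fixation(x: float, y: float, direction: str) -> None:
        n = fixation_samples()
        b.add("fixation", direction, [x] * n, [y] * n)

    def add_saccade(x0: float, y0: float, x1: float, y1: float, kind: str, direction: str) -> None:
        amp = math.hypot(x1 - x0, y1 - y0)
        fr = _ramp_fractions(amp)
        b.add(
            kind,
            direction,
            [x0 + f * (x1 - x0) for f in fr],
            [y0 + f * (y1 - y0) for f in fr],
        )

    done = False
    x = 0.0
    for line in range(layout.n_lines):
        yline = line * layout.line_spacing_deg
        if line == 0:
            add_fixation(0.0, yline, "none")
            x = 0.0
        while not done:
            if len(b) >= n_max:
                done = True
                break
            if x >= 1.3 and rng.random() < params.regression_prob:
                amp = _gamma(
                    rng,
                    _REGR_AMP_SCALE * amp_mean,
                    _REGR_AMP_SCALE * params.prog_saccade_amp_sd,
                )
                amp = min(max(amp, _MIN_SACC_AMP), _MAX_REGR_AMP, x)
                target = x - amp
                add_saccade(x, yline, target, yline, "saccade", "regressive")
                add_fixation(target, yline, "regressive")
                x = target
            else:
                amp = min(max(_gamma(rng, amp_mean, params.prog_saccade_amp_sd), _MIN_SACC_AMP), _MAX_PROG_AMP)
                if x + amp > layout.line_extent_deg:
                    break  # line finished -> return sweep
                target = x + amp
                add_saccade(x, yline, target, yline, "saccade", "progressive")
                add_fixation(target, yline, "progressive")
                x = target
        if done or line == layout.n_lines - 1:
            break
        # Return sweep to the start of the next line; the landing fixation
        # resumes forward reading and is classified progressive.
        ynext = yline + layout.line_spacing_deg
        add_saccade(x, yline, 0.0, ynext, "sweep", "none")
        add_fixation(0.0, ynext, "progressive")
        x = 0.0

    # Truncate at the last complete event inside the duration cap.
    if len(b) > n_max:
        events = [e for e in b.events if e.end_idx < n_max]
        if not events:
            raise ValueError("duration_cap_s too small to render any reading")
        n = events[-1].end_idx + 1
        cx = np.array(b.x[:n])
        cy = np.array(b.y[:n])
    else:
        events = b.events
        cx = np.array(b.x)
        cy = np.array(b.y)
    n = len(cx)
    if n < 12:
        raise ValueError("duration_cap_s too small to render any reading")

    # Clip trajectory excursions beyond the page (can only arise from
    # extreme parameter choices; rendered events are unaffected).
    x_hi = layout.line_extent_deg + 1.0
    y_hi = (layout.n_lines - 1) * layout.line_spacing_deg + 1.0
    if np.any(cx < -1.0) or np.any(cx > x_hi) or np.any(cy < -1.0) or np.any(cy > y_hi):
        logger.warning("subject %s: trajectory exceeded layout bounds; clipped", subject_id)
        np.clip(cx, -1.0, x_hi, out=cx)
        np.clip(cy, -1.0, y_hi, out=cy)

    # Transient artifacts: brief 2-sample high-amplitude excursions inside
    # long fixations; the host fixation is split in the ground truth.
    n_trans = rng.poisson(params.transient_rate * n * dt_ms / 1000.0) if params.transient_rate > 0 else 0
    for _ in range(n_trans):
        hosts = [
            (i, e) for i, e in enumerate(events)
            if e.kind == "fixation" and e.end_idx - e.start_idx + 1 >= 16
        ]
        if not hosts:
            break
        i, host = hosts[rng.integers(len(hosts))]
        a0 = int(rng.integers(host.start_idx + 7, host.end_idx - 7))
        a1 = a0 + 1
        dx = rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0])
        dy = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
        cx[a0 : a1 + 1] += dx
        cy[a0 : a1 + 1] += dy
        events[i : i + 1] = [
            GroundTruthEvent("fixation", host.direction, host.start_idx, a0 - 1),
            GroundTruthEvent("transient", "none", a0, a1),
            GroundTruthEvent("fixation", host.direction, a1 + 1, host.end_idx),
        ]

    # Binocular rendering: symmetric vergence offset keeps version == cyclopean.
    if params.vergence_noise_sd > 0:
        innov = params.vergence_noise_sd * math.sqrt(1.0 - _VERGENCE_AR1**2)
        eh = rng.normal(0.0, innov, n)
        ev = rng.normal(0.0, innov, n)
        vh = np.empty(n)
        vv = np.empty(n)
        vh[0] = rng.normal(0.0, params.vergence_noise_sd)
        vv[0] = rng.normal(0.0, params.vergence_noise_sd)
        for i in range(1, n):
            vh[i] = _VERGENCE_AR1 * vh[i - 1] + eh[i]
            vv[i] = _VERGENCE_AR1 * vv[i - 1] + ev[i]
    else:
        vh = np.zeros(n)
        vv = np.zeros(n)

    pos = np.column_stack([cx + vh / 2.0, cy + vv / 2.0, cx - vh / 2.0, cy - vv / 2.0])
    if params.measurement_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.measurement_noise_sd, pos.shape)

    valid = np.ones((n, 2), dtype=bool)
    if params.dropout_prob > 0:
        drop = rng.random(n) < params.dropout_prob
        valid[drop] = False
        pos[drop] = np.nan

    return GazeRecording(
        subject_id=subject_id,
        label=label,
        sampling_rate=sampling_rate,
        t=np.arange(n) * dt_ms,
        pos=pos,
        valid=valid,
        ground_truth=events,
    )


def generate_cohort(spec: CohortSpec) -> list[GazeRecording]:
    """Generate the labelled cohort: ``n_hr`` HR then ``n_lr`` LR recordings.

    Per-subject seeds are derived deterministically from ``spec.seed``, so
    equal specs yield byte-identical cohorts through the file round trip.
    """
    n_total = spec.n_hr + spec.n_lr
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(n_total, dtype=np.uint32)
    child_seeds = (child_seeds & 0x7FFFFFFF).tolist()
    recordings = []
    for i in range(n_total):
        hr = i < spec.n_hr
        recordings.append(
            simulate_recording(
                params=spec.hr_params if hr else spec.lr_params,
                layout=spec.layout,
                sampling_rate=spec.sampling_rate,
                duration_cap_s=spec.duration_cap_s,
                seed=child_seeds[i],
                subject_id=f"HR{i + 1:03d}" if hr else f"LR{i - spec.n_hr + 1:03d}",
                label="HR" if hr else "LR",
            )
        )
    return recordings


def noiseless(params: GroupGazeParams) -> GroupGazeParams:
    """A copy of ``params`` with all noise and artifact sources disabled."""
    return replace(
        params,
        measurement_noise_sd=0.0,
        dropout_prob=0.0,
        transient_rate=0.0,
    )
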