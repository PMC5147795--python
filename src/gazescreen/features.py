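"""The 168-dimensional eye-movement feature description of reading.

Events are pooled into four classes — progressive fixations (PF),
regressive fixations (RF), progressive saccades (PS), regressive
saccades (RS); sweeps, transients and distortions feed no pool.  Per
event we measure its duration (Dur, ms) and, for each of the four
spatial signals (horizontal/vertical x version/vergence), five
parameters:

* ``D`` — signed spanning distance, last minus first position;
* ``M`` — mean position;
* ``S`` — standard deviation of position within the event (population);
* ``R`` — maximum range between any two positions;
* ``A`` — accumulated distance over successive positions.

Within each class every parameter forms a distribution over events; its
mean and (population) SD are the features:
4 classes x (1 + 5 x 2 axes x 2 modes) parameters x 2 summaries = 168.

Feature ids are canonical strings such as ``PF.Dur.mean`` or
``RS.A.vert.vergence.sd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import BinocularSignals, DetectorConfig, GazeEvent, binocular_signals, detect_events
from .recording import GazeRecording

__all__ = [
    "EVENT_CLASSES",
    "SPATIAL_PARAMETERS",
    "FeatureDescriptor",
    "FeatureSchema",
    "FeatureVector",
    "feature_schema",
    "parse_feature_id",
    "event_parameters",
    "extract_features",
    "cohort_feature_table",
]

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("PF", "RF", "PS", "RS")
SPATIAL_PARAMETERS = ("D", "M", "S", "R", "A")
AXES = ("hor", "vert")
MODES = ("version", "vergence")
SUMMARIES = ("mean", "sd")

_CLASS_KEY = {
    "PF": ("fixation", "progressive"),
    "RF": ("fixation", "regressive"),
    "PS": ("saccade", "progressive"),
    "RS": ("saccade", "regressive"),
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One cell of the feature taxonomy."""

    event_class: str  # PF | RF | PS | RS
    parameter: str  # Dur | D | M | S | R | A
    axis: str | None  # hor | vert | None (Dur)
    mode: str | None  # version | vergence | None (Dur)
    summary: str  # mean | sd

    @property
    def id(self) -> str:
        if self.parameter == "Dur":
            return f"{self.event_class}.Dur.{self.summary}"
        return f"{self.event_class}.{self.parameter}.{self.axis}.{self.mode}.{self.summary}"


@dataclass(frozen=True)
class FeatureSchema:
    """The fixed, ordered 168-descriptor taxonomy."""

    descriptors: tuple[FeatureDescriptor, ...]
    _index: dict[str, int] = field(repr=False, hash=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {d.id: i for i, d in enumerate(self.descriptors)}
        )
        if len(self._index) != len(self.descriptors):
            raise ValueError("feature ids must be unique")

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.descriptors]

    def index(self, feature_id: str) -> int:
        return self._index[feature_id]


def feature_schema() -> FeatureSchema:
    """Enumerate the canonical 168-feature schema.

    Order: event class (PF, RF, PS, RS); within a class Dur first, then
    the spatial parameters D, M, S, R, A by axis (hor, vert) and mode
    (version, vergence); mean before sd innermost.
    """
    desc: list[FeatureDescriptor] = []
    for cls in EVENT_CLASSES:
        for summary in SUMMARIES:
            desc.append(FeatureDescriptor(cls, "Dur", None, None, summary))
        for param in SPATIAL_PARAMETERS:
            for axis in AXES:
                for mode in MODES:
                    for summary in SUMMARIES:
                        desc.append(FeatureDescriptor(cls, param, axis, mode, summary))
    return FeatureSchema(tuple(desc))


def parse_feature_id(feature_id: str) -> FeatureDescriptor:
    """Parse a canonical id back to its descriptor (round trip of ``.id``)."""
    parts = feature_id.split(".")
    if len(parts) == 3 and parts[1] == "Dur":
        cls, _, summary = parts
        d = FeatureDescriptor(cls, "Dur", None, None, summary)
    elif len(parts) == 5:
        cls, param, axis, mode, summary = parts
        d = FeatureDescriptor(cls, param, axis, mode, summary)
    else:
        raise ValueError(f"malformed feature id: {feature_id!r}")
    if (
        d.event_class not in EVENT_CLASSES
        or d.summary not in SUMMARIES
        or (d.parameter != "Dur" and (d.parameter not in SPATIAL_PARAMETERS or d.axis not in AXES or d.mode not in MODES))
    ):
        raise ValueError(f"malformed feature id: {feature_id!r}")
    return d


@dataclass
class FeatureVector:
    """A subject's values on the schema, with empty-pool audit flags."""

    subject_id: str
    values: np.ndarray
    empty_class_flags: dict[str, bool]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def event_parameters(
    event: GazeEvent, signals: BinocularSignals, t: np.ndarray
) -> dict[str, float]:
    """Measure one event: Dur plus D/M/S/R/A on each of the four signals.

    Keys are ``"Dur"`` and ``"<param>.<axis>.<mode>"``.  Unusable samples
    inside the span are skipped; a single-sample event has all spatial
    parameters at their degenerate values (D = S = R = A = 0).
    """
    sl = slice(event.start_idx, event.end_idx + 1)
    out: dict[str, float] = {"Dur": float(t[event.end_idx] - t[event.start_idx])}
    for (axis, mode), series in signals.series().items():
        s = series[sl]
        s = s[np.isfinite(s)]
        suffix = f"{axis}.{mode}"
        if len(s) == 0:
            raise ValueError("event has no usable samples")
        out[f"D.{suffix}"] = float(s[-1] - s[0])
        out[f"M.{suffix}"] = float(s.mean())
        out[f"S.{suffix}"] = float(s.std())  # population SD
        out[f"R.{suffix}"] = float(s.max() - s.min())
        out[f"A.{suffix}"] = float(np.abs(np.diff(s)).sum()) if len(s) > 1 else 0.0
    return out


def _param_key(d: FeatureDescriptor) -> str:
    return "Dur" if d.parameter == "Dur" else f"{d.parameter}.{d.axis}.{d.mode}"


def extract_features(
    events: list[GazeEvent],
    rec: GazeRecording,
    schema: FeatureSchema | None = None,
) -> FeatureVector:
    """Summarize a subject's classified events into the 168-vector.

    Within each of the four pools, each parameter's distribution over
    events is summarized by its mean and population SD.  Empty pools are
    zero-filled and flagged.
    """
    if schema is None:
        schema = feature_schema()
    signals = binocular_signals(rec)
    pools: dict[str, list[dict[str, float]]] = {c: [] for c in EVENT_CLASSES}
    for ev in events:
        for cls, key in _CLASS_KEY.items():
            if (ev.kind, ev.direction) == key:
                pools[cls].append(event_parameters(ev, signals, rec.t))
                break

    flags = {cls: len(pool) == 0 for cls, pool in pools.items()}
    if all(flags.values()):
        logger.warning(
            "subject %s: no classified fixations or saccades; all-zero feature vector",
            rec.subject_id,
        )

    values = np.zeros(len(schema))
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for cls, pool in pools.items():
        if not pool:
            continue
        for key in pool[0]:
            arr = np.array([p[key] for p in pool])
            stats[(cls, key)] = (float(arr.mean()), float(arr.std()))
    for i, d in enumerate(schema.descriptors):
        pair = stats.get((d.event_class, _param_key(d)))
        if pair is not None:
            values[i] = pair[0] if d.summary == "mean" else pair[1]
    return FeatureVector(rec.subject_id, values, flags)


def cohort_feature_table(
    recordings: list[GazeRecording],
    cfg: DetectorConfig = DetectorConfig(),
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Detect events and extract features for a whole cohort.

    Returns a DataFrame indexed by subject id with the 168 canonical
    feature columns and a final ``label`` column.
    """
    if schema is None:
        schema = feature_schema()
    rows = []
    labels = []
    ids = []
    for rec in recordings:
        events = detect_events(rec, cfg)
        fv = extract_features(events, rec, schema)
        rows.append(fv.values)
        labels.append(rec.label)
        ids.append(rec.subject_id)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=schema.ids)
    df["label"] = labels
    return df
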