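"""Binocular gaze recordings and their plain-text file format.

A recording holds time-ordered samples of left/right eye position in
degrees of visual angle at a fixed sampling rate (100 Hz goggles-style
tracking).  Coordinates: x increases rightward, y increases downward
(text lines progress to larger y); origin at the start of the first line.

File format (UTF-8, comma-delimited, one header line)::

    time_ms,lx_deg,ly_deg,rx_deg,ry_deg,valid_l,valid_r

Samples lost by the tracker keep their row with validity 0 and ``nan``
positions.  A cohort is a directory of per-subject files plus a
``manifest.csv`` mapping ``filename,subject_id,label``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "GazeRecording",
    "GroundTruthEvent",
    "write_gaze_file",
    "read_gaze_file",
    "write_cohort",
    "read_cohort",
]

MANIFEST_NAME = "manifest.csv"
_COLUMNS = ["time_ms", "lx_deg", "ly_deg", "rx_deg", "ry_deg", "valid_l", "valid_r"]


@dataclass(frozen=True)
class GazeSample:
    """One binocular sample; invalid eyes carry no usable position."""

    t: float
    left_x: float
    left_y: float
    right_x: float
    right_y: float
    valid_l: bool
    valid_r: bool


@dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator-emitted truth for one rendered segment (inclusive span)."""

    kind: str  # fixation | saccade | sweep | transient | distortion
    direction: str  # progressive | regressive | none
    start_idx: int
    end_idx: int


@dataclass
class GazeRecording:
    """A subject's time-ordered binocular samples plus metadata.

    Attributes
    ----------
    subject_id : str
    label : str
        ``"HR"``, ``"LR"`` or ``"unknown"``.
    sampling_rate : float
        In Hz; must be positive.
    t : ndarray, shape (n,)
        Sample times in ms, strictly increasing.
    pos : ndarray, shape (n, 4)
        Columns ``lx, ly, rx, ry`` in degrees; nan where invalid.
    valid : ndarray of bool, shape (n, 2)
        Columns ``valid_l, valid_r``.
    ground_truth : list of GroundTruthEvent, optional
        Present on simulated recordings only; not persisted to disk.
    """

    subject_id: str
    label: str
    sampling_rate: float
    t: np.ndarray
    pos: np.ndarray
    valid: np.ndarray
    ground_truth: list[GroundTruthEvent] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("a recording needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.pos.shape != (len(self.t), 4) or self.valid.shape != (len(self.t), 2):
            raise ValueError("pos must be (n, 4) and valid (n, 2)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])

    def samples(self) -> list[GazeSample]:
        """Materialize the samples as row objects (convenience accessor)."""
        return [
            GazeSample(
                t=float(self.t[i]),
                left_x=float(self.pos[i, 0]),
                left_y=float(self.pos[i, 1]),
                right_x=float(self.pos[i, 2]),
                right_y=float(self.pos[i, 3]),
                valid_l=bool(self.valid[i, 0]),
                valid_r=bool(self.valid[i, 1]),
            )
            for i in range(len(self))
        ]


def _fmt(x: float) -> str:
    return "nan" if math.isnan(x) else f"{x:.4f}"


def write_gaze_file(rec: GazeRecording, path: str) -> None:
    """Write one recording to the delimited text format (deterministic bytes)."""
    lines = [",".join(_COLUMNS)]
    for i in range(len(rec)):
        lines.append(
            f"{rec.t[i]:.1f},"
            + ",".join(_fmt(rec.pos[i, j]) for j in range(4))
            + f",{int(rec.valid[i, 0])},{int(rec.valid[i, 1])}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gaze_file(
    path: str,
    subject_id: str | None = None,
    label: str = "unknown",
    sampling_rate: float | None = None,
) -> GazeRecording:
    """Read a recording; sampling rate is inferred from the median time step
    unless given explicitly."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_ms"].to_numpy(float)
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(np.median(np.diff(t)))
    return GazeRecording(
        subject_id=subject_id or os.path.splitext(os.path.basename(path))[0],
        label=label,
        sampling_rate=sampling_rate,
        t=t,
        pos=df[["lx_deg", "ly_deg", "rx_deg", "ry_deg"]].to_numpy(float),
        valid=df[["valid_l", "valid_r"]].to_numpy() > 0,
    )


def write_cohort(recordings: list[GazeRecording], out_dir: str) -> str:
    """Write per-subject gaze files plus a manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_gaze_file(rec, os.path.join(out_dir, fname))
        rows.append((fname, rec.subject_id, rec.label))
    manifest = os.path.join(out_dir, MANIFEST_NAME)
    with open(manifest, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("filename,subject_id,label\n")
        for fname, sid, lab in rows:
            fh.write(f"{fname},{sid},{lab}\n")
    return manifest


def read_cohort(path: str) -> list[GazeRecording]:
    """Read a cohort from a manifest file or a directory containing one."""
    if os.path.isdir(path):
        path = os.path.join(path, MANIFEST_NAME)
    base = os.path.dirname(path)
    manifest = pd.read_csv(path)
    recordings = []
    for row in manifest.itertuples(index=False):
        gaze_path = os.path.join(base, row.filename)
        if not os.path.exists(gaze_path):
            raise FileNotFoundError(
                f"manifest references missing gaze file: {gaze_path}"
            )
        recordings.append(
            read_gaze_file(gaze_path, subject_id=str(row.subject_id), label=row.label)
        )
    return recordings
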