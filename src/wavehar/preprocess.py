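"""Reading, resampling and windowing of labelled tri-axial recordings.

Recordings arrive as delimited text (one sample per row: timestamp, x, y,
z, activity label) whose column layout varies across public collections;
a :class:`RecordingSchema` maps any such layout onto the common
:class:`SensorRecording` container.  All recordings are brought to a
common sampling rate (default 50 Hz) by polyphase resampling and cut into
fixed-length, non-overlapping, label-pure windows (default 2.5 s, i.e.
125 samples) — the unit on which fitness statistics and features are
computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "GRAVITY_M_PER_S2",
    "RecordingSchema",
    "DATASET_SCHEMAS",
    "SensorRecording",
    "Segment",
    "read_recording",
    "resample",
    "segment",
    "convert_units",
    "write_segments",
]

logger = logging.getLogger(__name__)

GRAVITY_M_PER_S2 = 9.80665

Units = Literal["g", "m_per_s2"]
LabelPolicy = Literal["pure", "majority"]


@dataclass(frozen=True)
class RecordingSchema:
    """Column layout and metadata needed to parse one delimited file."""

    x: str
    y: str
    z: str
    label: str
    sampling_rate: float
    units: Units = "m_per_s2"
    timestamp: str | None = None
    subject: str | None = None
    delimiter: str = ","
    has_header: bool = True
    placement: str = "unknown"


# Template layouts for the public activities-of-daily-living collections;
# sampling rates and units follow each collection's documentation, column
# names are configurable per local export.
DATASET_SCHEMAS: dict[str, RecordingSchema] = {
    "wisdm": RecordingSchema(
        x="x", y="y", z="z", label="activity", subject="user",
        timestamp="timestamp", sampling_rate=20.0, units="m_per_s2",
        placement="front_pocket",
    ),
    "harsense": RecordingSchema(
        x="ax", y="ay", z="az", label="activity", sampling_rate=50.0,
        units="m_per_s2", placement="waist",
    ),
    "harth": RecordingSchema(
        x="back_x", y="back_y", z="back_z", label="label",
        timestamp="timestamp", sampling_rate=50.0, units="g", placement="back",
    ),
    "har70plus": RecordingSchema(
        x="back_x", y="back_y", z="back_z", label="label",
        timestamp="timestamp", sampling_rate=50.0, units="g", placement="back",
    ),
    "mhealth": RecordingSchema(
        x="acc_chest_x", y="acc_chest_y", z="acc_chest_z", label="label",
        delimiter="\t", has_header=False, sampling_rate=50.0,
        units="m_per_s2", placement="chest",
    ),
    "pamap2": RecordingSchema(
        x="hand_acc_x", y="hand_acc_y", z="hand_acc_z", label="activity_id",
        delimiter=" ", sampling_rate=100.0, units="m_per_s2", placement="hand",
    ),
    "realdisp": RecordingSchema(
        x="acc_x", y="acc_y", z="acc_z", label="label", delimiter="\t",
        sampling_rate=50.0, units="m_per_s2", placement="back",
    ),
    "daliac": RecordingSchema(
        x="wrist_acc_x", y="wrist_acc_y", z="wrist_acc_z", label="label",
        sampling_rate=204.8, units="g", placement="wrist",
    ),
    # layout written by wavehar's own synthetic benchmark
    "synthetic": RecordingSchema(
        x="x", y="y", z="z", label="label", timestamp="t", subject="subject",
        sampling_rate=50.0, units="m_per_s2", placement="simulated",
    ),
}


@dataclass(frozen=True)
class SensorRecording:
    """A labelled tri-axial acceleration time series at a fixed rate."""

    subject_id: str
    placement: str
    sampling_rate: float
    units: Units
    samples: np.ndarray = field(repr=False)  # (n_samples, 3)
    labels: np.ndarray = field(repr=False)  # (n_samples,) of str

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.labels) != len(self.samples):
            raise ValueError("labels length must equal sample count")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class Segment:
    """One fixed-duration, single-label window of a recording."""

    samples: np.ndarray = field(repr=False)  # (window_length, 3)
    label: str = "unknown"
    subject_id: str = "unknown"
    placement: str = "unknown"

    @property
    def window_length(self) -> int:
        return self.samples.shape[0]


def read_recording(path, schema: RecordingSchema) -> SensorRecording:
    """Parse one delimited file into a validated :class:`SensorRecording`.

    Rows whose acceleration values fail to parse to finite numbers are
    dropped with a logged count; a missing required column or an empty
    file raises ``ValueError``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep=schema.delimiter,
            header=0 if schema.has_header else None,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty recording file: {path}") from exc
    if frame.empty:
        raise ValueError(f"empty recording file: {path}")
    if not schema.has_header:
        # positional layout: t/x/y/z/label order as named in the schema
        names = [schema.timestamp, schema.x, schema.y, schema.z, schema.label]
        names = [n for n in names if n is not None]
        if frame.shape[1] < len(names):
            raise ValueError(
                f"{path}: expected at least {len(names)} columns, found {frame.shape[1]}"
            )
        frame.columns = list(frame.columns)
        frame = frame.rename(columns=dict(zip(frame.columns[: len(names)], names)))
    for col in (schema.x, schema.y, schema.z, schema.label):
        if col not in frame.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    xyz = frame[[schema.x, schema.y, schema.z]].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(xyz.to_numpy(dtype=float)).all(axis=1) & frame[schema.label].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", path.name, n_dropped)
    if not keep.any():
        raise ValueError(f"{path}: no parseable rows")
    subject = "unknown"
    if schema.subject and schema.subject in frame.columns:
        subject = str(frame.loc[keep, schema.subject].iloc[0])
    return SensorRecording(
        subject_id=subject,
        placement=schema.placement,
        sampling_rate=schema.sampling_rate,
        units=schema.units,
        samples=xyz.to_numpy(dtype=float)[keep],
        labels=frame[schema.label].astype(str).to_numpy()[keep],
    )


def resample(recording: SensorRecording, target_rate: float) -> SensorRecording:
    """Bring a recording to ``target_rate`` Hz by polyphase resampling.

    Rational-ratio polyphase filtering (anti-aliasing built in when
    decimating); per-sample labels are carried over from the nearest
    original sample.  Upsampling (target above source) is supported for
    low-rate sources and logged as a warning.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if np.isclose(target_rate, recording.sampling_rate):
        return recording
    if target_rate > recording.sampling_rate:
        logger.warning(
            "upsampling %s from %.6g Hz to %.6g Hz",
            recording.subject_id, recording.sampling_rate, target_rate,
        )
    ratio = Fraction(target_rate / recording.sampling_rate).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    samples = resample_poly(recording.samples, up, down, axis=0)
    n_out = samples.shape[0]
    # nearest original sample, by time
    src_idx = np.clip(
        np.round(np.arange(n_out) * recording.sampling_rate / target_rate).astype(int),
        0,
        recording.n_samples - 1,
    )
    return replace(
        recording,
        sampling_rate=float(target_rate),
        samples=samples,
        labels=recording.labels[src_idx],
    )


def segment(recording: SensorRecording, window_seconds: float = 2.5,
            target_rate: float | None = None, *, overlap: float = 0.0,
            label_policy: LabelPolicy = "pure") -> list[Segment]:
    """Cut a recording into fixed-length labelled windows.

    Consecutive windows of ``round(window_seconds * rate)`` samples with
    ``overlap`` fraction (default 0: non-overlapping).  Under the default
    ``"pure"`` policy the window grid restarts at every label change, so
    no window straddles an activity change and every label-pure run of
    length L yields floor(L / window) windows; ``"majority"`` instead cuts
    one global grid and labels each window by its most frequent label.
    Trailing partial windows are dropped.  A window longer than the
    recording yields an empty list.
    """
    rate = recording.sampling_rate if target_rate is None else target_rate
    if target_rate is not None and not np.isclose(recording.sampling_rate, target_rate):
        raise ValueError(
            f"recording is at {recording.sampling_rate} Hz, expected {target_rate} Hz; "
            "resample first"
        )
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    window = int(round(window_seconds * rate))
    if window < 1:
        raise ValueError("window too short for the sampling rate")
    step = max(1, int(round(window * (1.0 - overlap))))

    def emit(start: int, stop: int, label) -> None:
        for lo in range(start, stop - window + 1, step):
            out.append(
                Segment(
                    samples=recording.samples[lo: lo + window].copy(),
                    label=str(label),
                    subject_id=recording.subject_id,
                    placement=recording.placement,
                )
            )

    out: list[Segment] = []
    n = recording.n_samples
    if label_policy == "pure":
        run_start = 0
        for i in range(1, n + 1):
            if i == n or recording.labels[i] != recording.labels[run_start]:
                emit(run_start, i, recording.labels[run_start])
                run_start = i
    else:
        for lo in range(0, n - window + 1, step):
            labels = recording.labels[lo: lo + window]
            uniq, counts = np.unique(labels, return_counts=True)
            emit_label = uniq[np.argmax(counts)]
            out.append(
                Segment(
                    samples=recording.samples[lo: lo + window].copy(),
                    label=str(emit_label),
                    subject_id=recording.subject_id,
                    placement=recording.placement,
                )
            )
    return out


def convert_units(recording: SensorRecording, target: Units) -> SensorRecording:
    """Explicit g <-> m/s² conversion (factor 9.80665).

    Units are never converted silently: the energy-to-entropy ratio scales
    with the square of the signal amplitude, so unit choice changes its
    absolute scale (not rankings) and must be a deliberate step.
    """
    if recording.units == target:
        return recording
    factor = GRAVITY_M_PER_S2 if target == "m_per_s2" else 1.0 / GRAVITY_M_PER_S2
    return replace(recording, units=target, samples=recording.samples * factor)


def write_segments(segments: list[Segment], out_dir) -> Path:
    """Serialize segments to a directory of CSV files plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, seg in enumerate(segments):
        name = f"segment_{i:05d}.csv"
        pd.DataFrame(seg.samples, columns=["x", "y", "z"]).to_csv(
            out_dir / name, index=False
        )
        manifest.append(
            {"file": name, "label": seg.label, "subject": seg.subject_id,
             "placement": seg.placement, "window_length": seg.window_length}
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
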