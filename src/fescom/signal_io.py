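"""Reading, validation, preprocessing and segmentation of IMU motion recordings.

A recording is a 6-channel time series — tri-axial acceleration (in g) and
tri-axial angular velocity (in degrees per second) — sampled at a fixed rate
(20 Hz in the study protocol this package targets).  Recordings arrive as
delimited text with one row per sample; repetitions of an exercise are marked
by an annotation table of half-open ``[start, end)`` sample intervals, each
carrying a class label.  Preprocessing is a per-channel median filter that
suppresses isolated outlier samples before feature extraction.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical channel order: accelerometer axes then gyroscope axes.
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Long-form signal names used in canonical feature names.
SIGNAL_NAMES = (
    "acceleration_x",
    "acceleration_y",
    "acceleration_z",
    "angular_velocity_x",
    "angular_velocity_y",
    "angular_velocity_z",
)

_MAG_COLUMNS = ("mag_x", "mag_y", "mag_z")

#: Minimum window length admitting variance and spectral features.
MIN_WINDOW_SAMPLES = 4


@dataclass(frozen=True)
class MotionRecording:
    """A raw multi-channel IMU time series.

    Parameters
    ----------
    samples
        Array of shape ``(T, 6)``, columns in :data:`CHANNELS` order.
    sampling_rate_hz
        Sampling frequency in Hz; the study protocol uses 20.
    units
        ``(acceleration_unit, angular_velocity_unit)`` tags, default ``("g", "deg/s")``.
    subject_id
        Opaque participant identifier.
    exercise_label
        Optional exercise class if the whole recording is a single class.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    units: tuple[str, str] = ("g", "deg/s")
    subject_id: str = ""
    exercise_label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 6:
            raise ValidationError(
                f"recording must have exactly 6 channel columns, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            bad = int(np.argwhere(~np.isfinite(samples))[0, 0])
            raise ValidationError(f"non-finite sample at row {bad}")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class SignalWindow:
    """A labeled slice of a recording covering one exercise repetition."""

    samples: np.ndarray
    label: str
    sampling_rate_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 6:
            raise ValidationError(
                f"window must have exactly 6 channel columns, got shape {samples.shape}"
            )
        if samples.shape[0] < MIN_WINDOW_SAMPLES:
            raise ValidationError(
                f"window needs at least {MIN_WINDOW_SAMPLES} samples, got {samples.shape[0]}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValidationError("window contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class Annotation:
    """Half-open sample interval ``[start_index, end_index)`` with a class label."""

    start_index: int
    end_index: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValidationError(
                f"annotation requires 0 <= start < end, got [{self.start_index}, {self.end_index})"
            )


_FS_COMMENT = re.compile(r"^#\s*fs\s*=\s*([0-9.]+)")


def read_recording(
    path: str | Path,
    schema: dict[str, str] | None = None,
    sampling_rate_hz: float | None = None,
    **metadata: str,
) -> MotionRecording:
    """Read a delimited-text recording, returning channels in canonical order.

    The file must have a header row naming at least the six channel columns
    (``acc_x``..``gyr_z``, or the names mapped onto them by ``schema``), one
    row per sample.  A leading comment line ``# fs=20`` supplies the sampling
    rate when ``sampling_rate_hz`` is not given.  Extra columns are ignored;
    magnetometer columns are ignored with a logged notice, since magnetometer
    data play no role in this pipeline.

    Parameters
    ----------
    schema
        Optional map from file column name to canonical channel name.
    sampling_rate_hz
        Sampling rate override; required if the file has no ``# fs=`` line.
    """
    path = Path(path)
    text = path.read_text()
    fs = sampling_rate_hz
    body_lines = []
    for line in text.splitlines():
        m = _FS_COMMENT.match(line)
        if m:
            if fs is None:
                fs = float(m.group(1))
            continue
        if line.startswith("#"):
            continue
        body_lines.append(line)
    if fs is None:
        raise FormatError(
            f"{path}: sampling rate not found; supply sampling_rate_hz or a '# fs=' line"
        )

    frame = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if schema:
        frame = frame.rename(columns=schema)

    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s): {', '.join(missing)}")

    present_mag = [c for c in _MAG_COLUMNS if c in frame.columns]
    if present_mag:
        logger.info(
            "Ignoring magnetometer column(s) %s in %s: magnetometer data are not "
            "used by this pipeline.",
            present_mag,
            path,
        )

    channel_frame = frame[list(CHANNELS)]
    numeric = channel_frame.apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1) & ~channel_frame.isna().any(axis=1)
    if channel_frame.isna().any(axis=1).any() or bad_rows.any():
        mask = numeric.isna().any(axis=1)
        row = int(np.flatnonzero(mask.to_numpy())[0])
        raise ValidationError(f"{path}: non-numeric or missing value at data row {row}")
    samples = numeric.to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        row = int(np.argwhere(~np.isfinite(samples))[0, 0])
        raise ValidationError(f"{path}: non-finite value at data row {row}")

    return MotionRecording(samples=samples, sampling_rate_hz=float(fs), **metadata)


def median_filter(signal: np.ndarray, window_length: int = 3) -> np.ndarray:
    """Running median of odd window ``window_length``, shrinking at the edges.

    ``output[i]`` is the median of the samples in the window centred at ``i``;
    near the boundaries the window shrinks to the available samples rather
    than padding, so no values are fabricated.  Length is preserved and every
    output value lies within ``[min(signal), max(signal)]``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ParameterError("median_filter expects a 1-D signal")
    if window_length < 1 or window_length % 2 == 0:
        raise ParameterError(f"window_length must be odd and positive, got {window_length}")
    if window_length > x.size:
        raise ParameterError(
            f"window_length {window_length} exceeds signal length {x.size}"
        )
    if window_length == 1:
        return x.copy()
    out = (
        pd.Series(x)
        .rolling(window_length, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return out


def preprocess(recording: MotionRecording, window_length: int = 3) -> MotionRecording:
    """Median-filter each channel independently; metadata is preserved."""
    filtered = np.column_stack(
        [median_filter(recording.samples[:, c], window_length) for c in range(6)]
    )
    return MotionRecording(
        samples=filtered,
        sampling_rate_hz=recording.sampling_rate_hz,
        units=recording.units,
        subject_id=recording.subject_id,
        exercise_label=recording.exercise_label,
    )


def segment(
    recording: MotionRecording, annotations: Sequence[Annotation]
) -> list[SignalWindow]:
    """Slice a recording into labeled windows, one per annotation, in order.

    Annotations must be mutually non-overlapping and lie within the recording.
    """
    n = recording.n_samples
    for idx, ann in enumerate(annotations):
        if ann.end_index > n:
            raise ValidationError(
                f"annotation {idx} [{ann.start_index}, {ann.end_index}) exceeds "
                f"recording length {n}"
            )
    order = sorted(range(len(annotations)), key=lambda i: annotations[i].start_index)
    for a, b in zip(order, order[1:]):
        if annotations[a].end_index > annotations[b].start_index:
            raise ValidationError(f"annotations {a} and {b} overlap")
    return [
        SignalWindow(
            samples=recording.samples[ann.start_index : ann.end_index],
            label=ann.label,
            sampling_rate_hz=recording.sampling_rate_hz,
            subject_id=recording.subject_id,
        )
        for ann in annotations
    ]


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotation CSV with columns ``start,end,label`` (0-based, half-open)."""
    frame = pd.read_csv(path, comment="#")
    required = {"start", "end", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation column(s): {', '.join(sorted(missing))}")
    return [
        Annotation(int(r.start), int(r.end), str(r.label))
        for r in frame.itertuples(index=False)
    ]


def write_recording(path: str | Path, recording: MotionRecording) -> None:
    """Write a recording in the CSV dialect :func:`read_recording` accepts."""
    frame = pd.DataFrame(recording.samples, columns=list(CHANNELS))
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.sampling_rate_hz:g}\n")
        frame.to_csv(fh, index=False)


def write_annotations(path: str | Path, annotations: Sequence[Annotation]) -> None:
    frame = pd.DataFrame(
        [(a.start_index, a.end_index, a.label) for a in annotations],
        columns=["start", "end", "label"],
    )
    frame.to_csv(path, index=False)
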