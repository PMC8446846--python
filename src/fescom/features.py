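"""Time- and frequency-domain feature extraction from IMU signal windows.

Ten feature types are computed per channel: seven time-domain statistics
(mean, standard deviation, maximum, minimum, kurtosis, skewness, interquartile
range) and three frequency-domain statistics (average power, average
frequency, median frequency).  With six channels this yields a 60-dimensional
feature vector per window.

Conventions
-----------
* ``std`` is the sample standard deviation (divisor ``T - 1``).
* ``skewness`` is ``m3 / m2**1.5`` and ``kurtosis`` the excess form
  ``m4 / m2**2 - 3``, with ``mk`` the biased central sample moments; both are
  defined as 0 for zero-variance input (a :class:`DegenerateSignalWarning` is
  emitted).
* ``avg_power`` is the time-domain mean square ``(1/T) * sum(x**2)``, which by
  Parseval equals the integral of the periodogram.
* ``avg_frequency`` and ``median_frequency`` are computed on the one-sided,
  unwindowed, non-detrended periodogram with the DC bin excluded: the DC
  component dominates slow limb movements and would otherwise pin both
  statistics near 0.  ``median_frequency`` is the first bin at which the
  cumulative non-DC power reaches at least half the total non-DC power.
* For a constant signal ``c`` the degenerate convention is
  ``avg_power = c**2``, ``avg_frequency = 0``, ``median_frequency = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import DegenerateSignalWarning, ParameterError, ValidationError
from .signal_io import MIN_WINDOW_SAMPLES, SIGNAL_NAMES, SignalWindow

#: Fixed feature-type order within each channel block.
FEATURE_TYPES = (
    "mean",
    "std",
    "max",
    "min",
    "kurtosis",
    "skewness",
    "iqr",
    "avg_power",
    "avg_frequency",
    "median_frequency",
)

TIME_FEATURE_TYPES = FEATURE_TYPES[:7]
FREQ_FEATURE_TYPES = FEATURE_TYPES[7:]


def canonical_feature_names(signal_names: Sequence[str] = SIGNAL_NAMES) -> list[str]:
    """Feature names in canonical order: channel-major, then feature type.

    Names follow the ``"<type>(<signal>_<axis>)"`` convention, e.g.
    ``"min(angular_velocity_y)"``.
    """
    return [f"{ftype}({sig})" for sig in signal_names for ftype in FEATURE_TYPES]


def time_features(x: np.ndarray) -> dict[str, float]:
    """The seven time-domain statistics of a 1-D signal.

    Zero-variance input returns skewness and kurtosis of 0 and emits
    :class:`DegenerateSignalWarning`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_WINDOW_SAMPLES:
        raise ValidationError(f"need at least {MIN_WINDOW_SAMPLES} samples, got {x.size}")
    out = {
        "mean": float(np.mean(x)),
        "std": float(np.std(x, ddof=1)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
    }
    if np.var(x) == 0.0:
        warnings.warn(
            "zero-variance signal: skewness and kurtosis set to 0",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        out["kurtosis"] = 0.0
        out["skewness"] = 0.0
    else:
        out["kurtosis"] = float(sp_stats.kurtosis(x, fisher=True, bias=True))
        out["skewness"] = float(sp_stats.skew(x, bias=True))
    q75, q25 = np.percentile(x, [75, 25])  # linear interpolation (default)
    out["iqr"] = float(q75 - q25)
    return out


def freq_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Average power and the two spectral-location statistics of a 1-D signal."""
    x = np.asarray(x, dtype=float)
    if x.size < MIN_WINDOW_SAMPLES:
        raise ValidationError(f"need at least {MIN_WINDOW_SAMPLES} samples, got {x.size}")
    if not fs > 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")

    avg_power = float(np.mean(x**2))

    if np.var(x) == 0.0:
        warnings.warn(
            "zero-variance signal: spectral-location features set to 0",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return {"avg_power": avg_power, "avg_frequency": 0.0, "median_frequency": 0.0}

    freqs, pxx = sp_signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    f, p = freqs[1:], pxx[1:]  # exclude the DC bin
    total = float(np.sum(p))
    avg_frequency = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    median_frequency = float(f[np.searchsorted(cum, 0.5 * total)])
    return {
        "avg_power": avg_power,
        "avg_frequency": avg_frequency,
        "median_frequency": median_frequency,
    }


@dataclass(frozen=True)
class FeatureVector:
    """A named 60-dimensional feature vector with its class label."""

    values: np.ndarray
    names: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != len(self.names):
            raise ValidationError("values and names must align")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


def extract_features(window: SignalWindow, fs: float | None = None) -> FeatureVector:
    """The full feature vector of one window: 6 channels x 10 feature types.

    Channels are processed in canonical order; each channel contributes a
    block of ten features in :data:`FEATURE_TYPES` order.
    """
    fs = window.sampling_rate_hz if fs is None else fs
    values: list[float] = []
    for c, sig_name in enumerate(SIGNAL_NAMES):
        x = window.samples[:, c]
        try:
            feats = {**time_features(x), **freq_features(x, fs)}
        except (ValidationError, ParameterError) as err:
            raise type(err)(f"channel {sig_name}: {err}") from err
        values.extend(feats[ftype] for ftype in FEATURE_TYPES)
    return FeatureVector(
        values=np.array(values),
        names=tuple(canonical_feature_names()),
        label=window.label,
    )


@dataclass(frozen=True)
class FeatureTable:
    """An ``N x F`` labeled feature matrix with canonical column names."""

    matrix: np.ndarray
    names: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if matrix.shape != (len(self.labels), len(self.names)):
            raise ValidationError(
                f"shape {matrix.shape} inconsistent with {len(self.labels)} labels "
                f"and {len(self.names)} names"
            )
        if not np.all(np.isfinite(matrix)):
            raise ValidationError("feature matrix contains non-finite entries")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if len(self.class_set) < 2:
            raise ValidationError("feature table needs at least 2 classes")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def class_set(self) -> tuple[str, ...]:
        """Distinct classes in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def restrict(self, feature_indices: Sequence[int]) -> "FeatureTable":
        """A view of the table keeping only the given feature columns, in order."""
        idx = list(feature_indices)
        return FeatureTable(
            matrix=self.matrix[:, idx],
            names=tuple(self.names[i] for i in idx),
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, columns=list(self.names))
        frame["label"] = list(self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        if "label" not in frame.columns:
            raise ValidationError("feature table requires a 'label' column")
        names = [c for c in frame.columns if c != "label"]
        return cls(
            matrix=frame[names].to_numpy(dtype=float),
            names=tuple(names),
            labels=tuple(str(v) for v in frame["label"]),
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


def build_feature_table(
    windows: Sequence[SignalWindow], fs: float | None = None
) -> FeatureTable:
    """Extract features from every window and stack them into a table."""
    if not windows:
        raise ValidationError("cannot build a feature table from zero windows")
    vectors = [extract_features(w, fs) for w in windows]
    names = vectors[0].names
    return FeatureTable(
        matrix=np.vstack([v.values for v in vectors]),
        names=names,
        labels=tuple(v.label for v in vectors),
    )
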