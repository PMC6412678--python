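"""Transient-response feature extraction.

Five features per sensor summarise the baseline-corrected response curve:

* ``rmax``  — maximum absolute response, max_t |R(t)|;
* ``rint``  — integral of R(t) over the recorded window (trapezoid rule);
* ``ema_a{0.005,0.05,0.5}`` — maximum absolute exponential moving average
  of the first difference of R, at three smoothing factors.

With a 16-sensor array this yields the 80-dimensional fingerprint used by
the classifiers.  All five features are positively homogeneous of degree 1
in R: scaling a response curve scales every feature by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from enosecp.preprocess import CorrectedRecording

__all__ = [
    "EMA_SMOOTHING_FACTORS",
    "FeatureTable",
    "feature_rmax",
    "feature_rint",
    "feature_ema_max",
    "extract_features",
    "extract_feature_table",
    "feature_names",
    "default_feature_names",
]

#: Smoothing factors for the EMA-derivative features.
EMA_SMOOTHING_FACTORS = (0.005, 0.05, 0.5)

_FEATURE_SUFFIXES = ("rmax", "rint") + tuple(
    f"ema_a{a}" for a in EMA_SMOOTHING_FACTORS
)


@dataclass
class FeatureTable:
    """Rectangular feature matrix with column names and optional labels."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [specimen x feature]")
        if self.values.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must match number of rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.names)
        if self.labels is not None:
            frame["label"] = self.labels
        return frame

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "FeatureTable":
        labels = None
        if "label" in frame.columns:
            labels = frame["label"].to_numpy()
            frame = frame.drop(columns="label")
        return cls(
            values=frame.to_numpy(dtype=float),
            names=list(frame.columns),
            labels=labels,
        )

    def subset(self, idx) -> "FeatureTable":
        labels = None if self.labels is None else self.labels[idx]
        return FeatureTable(self.values[idx], list(self.names), labels)


def feature_rmax(series: np.ndarray) -> float:
    """Maximum absolute response max_t |R(t)|."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return float(np.max(np.abs(series)))


def feature_rint(series: np.ndarray, dt: float) -> float:
    """Trapezoidal integral of R(t) over the sampled window."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.trapezoid(series, dx=dt))


def feature_ema_max(series: np.ndarray, a: float) -> float:
    """Maximum absolute EMA of the first difference of R.

    With d(k) = R(k) - R(k-1) and y(0) = 0, the recurrence
    y(k) = (1 - a) * y(k-1) + a * d(k) is run over the full series and the
    maximum |y(k)| returned.  At a = 1 this reduces to the maximum absolute
    first difference; small a averages the derivative over ~1/a samples.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("series must have at least 2 samples")
    if not 0 < a <= 1:
        raise ValueError("smoothing factor a must be in (0, 1]")
    d = np.diff(series)
    # y(k) = (1-a) y(k-1) + a d(k) via scipy's linear filter
    from scipy.signal import lfilter

    y = lfilter([a], [1.0, -(1.0 - a)], d)
    return float(np.max(np.abs(y)))


def feature_names(n_sensors: int) -> list[str]:
    """Sensor-major feature names: S1_rmax, S1_rint, S1_ema_a0.005, ..."""
    return [
        f"S{s + 1}_{suffix}"
        for s in range(n_sensors)
        for suffix in _FEATURE_SUFFIXES
    ]


def default_feature_names(n_features: int) -> list[str]:
    """Names for a feature table not derived from recordings.

    Uses the sensor-major naming when the count factors into sensors of
    five features each, otherwise generic ``f<i>`` columns.
    """
    if n_features % len(_FEATURE_SUFFIXES) == 0:
        return feature_names(n_features // len(_FEATURE_SUFFIXES))
    return [f"f{i + 1}" for i in range(n_features)]


def extract_features(
    recording: CorrectedRecording,
    *,
    decimate_to: int | None = None,
) -> FeatureTable:
    """Extract the five per-sensor features from one corrected recording.

    Returns a one-row :class:`FeatureTable` in sensor-major order.  The
    integral spans the whole recorded window; ``decimate_to`` optionally
    subsamples each trace to that many evenly spaced points before the EMA
    recurrence (off by default — the EMA maximum is dominated by the
    injection transient either way).
    """
    timing = recording.timing
    dt = 1.0 / timing.sampling_rate
    row = []
    for s in range(recording.n_sensors):
        series = recording.signal[s]
        if decimate_to is not None and decimate_to < series.size:
            idx = np.linspace(0, series.size - 1, decimate_to).round().astype(int)
            ema_series = series[idx]
        else:
            ema_series = series
        row.append(feature_rmax(series))
        row.append(feature_rint(series, dt))
        for a in EMA_SMOOTHING_FACTORS:
            row.append(feature_ema_max(ema_series, a))
    labels = None if recording.label is None else np.array([recording.label])
    return FeatureTable(
        values=np.array([row]),
        names=feature_names(recording.n_sensors),
        labels=labels,
    )


def extract_feature_table(
    recordings, *, decimate_to: int | None = None
) -> FeatureTable:
    """Extract features from a sequence of corrected recordings."""
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    tables = [extract_features(r, decimate_to=decimate_to) for r in recordings]
    values = np.vstack([t.values for t in tables])
    names = tables[0].names
    if any(t.names != names for t in tables):
        raise ValueError("recordings have inconsistent sensor counts")
    if all(t.labels is not None for t in tables):
        labels = np.concatenate([t.labels for t in tables])
    else:
        labels = None
    return FeatureTable(values=values, names=names, labels=labels)
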