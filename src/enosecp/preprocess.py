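"""Raw-signal preprocessing: voltage-divider conversion and baseline correction.

MOS sensor readout circuits report a voltage across a load resistor; the
sensor resistance follows from the divider relation.  Classification works
on the dimensionless relative response R = (Rs - Rb) / Rb, where Rb is the
per-sensor mean over the pre-injection baseline window.  This normalisation
removes the per-sensor baseline level (and with it slow multiplicative
drift between measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from enosecp.synthetic import SensorRecording, TimingConfig

__all__ = ["CorrectedRecording", "voltage_to_resistance", "baseline_correct"]


@dataclass
class CorrectedRecording:
    """Baseline-normalised relative response, dimensionless.

    ``signal[s, t]`` is R(t) for sensor ``s``; on noiseless input the mean
    over the baseline window is zero to numerical precision.
    """

    signal: np.ndarray
    timing: TimingConfig
    label: int | None = None
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("corrected signal contains non-finite values")

    @property
    def n_sensors(self) -> int:
        return self.signal.shape[0]


def voltage_to_resistance(
    recording: SensorRecording,
    supply_voltage: float = 5.0,
    load_resistance: float = 10_000.0,
) -> SensorRecording:
    """Convert divider voltages to sensor resistances.

    The sensor and load resistor form a voltage divider driven at
    ``supply_voltage``; the recorded voltage V across the load gives
    Rs = R_load * (V_supply - V) / V.  Every sample must lie strictly
    inside (0, V_supply).
    """
    v = recording.signal
    bad = (v <= 0) | (v >= supply_voltage)
    if np.any(bad):
        s, t = np.argwhere(bad)[0]
        raise ValueError(
            f"voltage sample out of (0, {supply_voltage}) V for sensor S{s + 1} "
            f"at index {t}: {v[s, t]!r}"
        )
    rs = load_resistance * (supply_voltage - v) / v
    return SensorRecording(
        signal=rs,
        timing=recording.timing,
        label=recording.label,
        specimen_id=recording.specimen_id,
        unit="resistance",
    )


def baseline_correct(recording: SensorRecording) -> CorrectedRecording:
    """Normalise each sensor trace by its pre-injection baseline.

    R(t) = (Rs(t) - Rb) / Rb with Rb the per-sensor mean over the first
    ``baseline_duration`` seconds.  Invariant to scaling a sensor's whole
    trace by any positive constant.
    """
    timing = recording.timing
    n_base = int(round(timing.baseline_duration * timing.sampling_rate))
    if n_base < 1:
        raise ValueError("baseline window is empty")
    baseline = recording.signal[:, :n_base].mean(axis=1)
    if np.any(baseline == 0):
        s = int(np.argwhere(baseline == 0)[0][0])
        raise ValueError(f"zero baseline mean for sensor S{s + 1}")
    corrected = (recording.signal - baseline[:, None]) / baseline[:, None]
    return CorrectedRecording(
        signal=corrected,
        timing=timing,
        label=recording.label,
        specimen_id=recording.specimen_id,
    )
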