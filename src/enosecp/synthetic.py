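"""Synthetic e-nose data generator.

Emulates the measurement cycle of a metal-oxide-semiconductor (MOS) sensor
array: a pre-injection baseline phase, a reaction phase in which each sensor
rises toward a class-specific saturated response, and a cleaning phase in
which the signal decays back to baseline.  Class identity is encoded as a
per-sensor relative-response amplitude pattern; specimens of one class share
the pattern up to multiplicative lognormal variation.  A fast shortcut
(:func:`simulate_feature_table`) draws class-conditional Gaussian feature
vectors directly, bypassing the signal simulation.

All randomness flows from an explicit integer seed; identical inputs and
seed produce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MODERATE_SEPARATION",
    "TimingConfig",
    "ClassSignatureSet",
    "SensorRecording",
    "make_signatures",
    "simulate_recording",
    "simulate_dataset",
    "simulate_feature_table",
    "write_recording",
    "read_recording",
]

#: Default measurement cycle: 20 s baseline, 200 s reaction, 120 s cleaning.
DEFAULT_PHASES = (20.0, 200.0, 120.0)

#: Class-mean scale of the Gaussian feature generator that produces moderate
#: class overlap: 10-class forced accuracy lands in the realistic 70-80% band
#: for the default conformal predictors.
MODERATE_SEPARATION = 0.35


@dataclass(frozen=True)
class TimingConfig:
    """Measurement-cycle timing.

    The default phase durations follow the standard e-nose protocol of a
    20 s pre-injection baseline, 200 s of reaction, and 120 s of cleaning
    (340 s total).  The default sampling rate is 10 Hz; the features depend
    on curve shape, not on the raw rate, so a lower rate keeps simulated
    datasets small.
    """

    sampling_rate: float = 10.0
    baseline_duration: float = DEFAULT_PHASES[0]
    reaction_duration: float = DEFAULT_PHASES[1]
    cleaning_duration: float = DEFAULT_PHASES[2]

    def __post_init__(self) -> None:
        for name in (
            "sampling_rate",
            "baseline_duration",
            "reaction_duration",
            "cleaning_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def total_duration(self) -> float:
        return (
            self.baseline_duration + self.reaction_duration + self.cleaning_duration
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.total_duration))

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class ClassSignatureSet:
    """Per-class sensor response amplitudes plus shared kinetic parameters.

    ``amplitude[c, s]`` is the dimensionless relative-response amplitude of
    sensor ``s`` for class ``c`` (the saturated fractional resistance change).
    ``rise_tau``/``decay_tau`` are per-sensor first-order time constants in
    seconds.  ``within_class_cv`` is the coefficient of variation of the
    lognormal multiplicative perturbation applied to amplitudes per specimen.
    """

    amplitude: np.ndarray
    rise_tau: np.ndarray
    decay_tau: np.ndarray
    baseline: np.ndarray
    within_class_cv: float = 0.1
    noise_sd: float = 0.01
    drift_slope_sd: float = 1e-4

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.ndim != 2:
            raise ValueError("amplitude must be a [class x sensor] matrix")
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitude matrix must be finite")
        if np.any(np.asarray(self.rise_tau) <= 0) or np.any(
            np.asarray(self.decay_tau) <= 0
        ):
            raise ValueError("time constants must be positive")
        if self.within_class_cv < 0:
            raise ValueError("within_class_cv must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.amplitude.shape[1]


@dataclass
class SensorRecording:
    """One specimen's raw multichannel time series.

    ``signal`` has shape ``[n_sensors, n_samples]`` in signal units; the
    ``unit`` flag records whether samples are voltages or resistances.
    """

    signal: np.ndarray
    timing: TimingConfig
    label: int | None = None
    specimen_id: str = ""
    unit: str = "resistance"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be a [sensor x time] matrix")
        if sig.shape[1] != self.timing.n_samples:
            raise ValueError(
                f"signal has {sig.shape[1]} samples, timing implies "
                f"{self.timing.n_samples}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        self.signal = sig

    @property
    def n_sensors(self) -> int:
        return self.signal.shape[0]


def make_signatures(
    n_classes: int,
    n_sensors: int,
    separation: float = 1.0,
    seed: int = 0,
    *,
    within_class_cv: float = 0.1,
    noise_sd: float = 0.01,
    drift_slope_sd: float = 1e-4,
) -> ClassSignatureSet:
    """Draw a reproducible set of class signatures.

    Each sensor has a shared base amplitude; class rows deviate from it by
    ``separation`` times a standard-normal offset (scaled by 0.2), so the
    mean pairwise between-class row distance is exactly linear in
    ``separation`` and ``separation=0`` collapses all classes onto the base
    pattern.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if n_sensors < 1:
        raise ValueError("n_sensors must be at least 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, size=n_sensors)
    offsets = rng.standard_normal(size=(n_classes, n_sensors)) * 0.2
    amplitude = base[None, :] + separation * offsets
    rise_tau = rng.uniform(15.0, 30.0, size=n_sensors)
    decay_tau = rng.uniform(20.0, 40.0, size=n_sensors)
    baseline = np.ones(n_sensors)
    return ClassSignatureSet(
        amplitude=amplitude,
        rise_tau=rise_tau,
        decay_tau=decay_tau,
        baseline=baseline,
        within_class_cv=within_class_cv,
        noise_sd=noise_sd,
        drift_slope_sd=drift_slope_sd,
    )


def _phase_curve(
    timing: TimingConfig,
    baseline: float,
    amplitude: float,
    rise_tau: float,
    decay_tau: float,
) -> np.ndarray:
    """Noiseless first-order response curve for one sensor."""
    t = timing.time_axis()
    t_inject = timing.baseline_duration
    t_clean = timing.baseline_duration + timing.reaction_duration
    curve = np.full(t.shape, baseline)
    reacting = (t >= t_inject) & (t < t_clean)
    curve[reacting] = baseline * (
        1.0 + amplitude * (1.0 - np.exp(-(t[reacting] - t_inject) / rise_tau))
    )
    r_end = amplitude * (1.0 - np.exp(-timing.reaction_duration / rise_tau))
    cleaning = t >= t_clean
    curve[cleaning] = baseline * (
        1.0 + r_end * np.exp(-(t[cleaning] - t_clean) / decay_tau)
    )
    return curve


def simulate_recording(
    signatures: ClassSignatureSet,
    class_id: int,
    timing: TimingConfig | None = None,
    seed: int = 0,
    *,
    specimen_id: str = "",
) -> SensorRecording:
    """Simulate one specimen's recording for the given class.

    The noiseless curve is baseline during the baseline phase, a saturating
    exponential rise ``baseline * (1 + A_eff * (1 - exp(-t/rise_tau)))``
    during the reaction phase, and an exponential decay toward baseline in
    the cleaning phase.  ``A_eff`` is the class amplitude perturbed by a
    lognormal factor with coefficient of variation ``within_class_cv``.
    Linear baseline drift and white Gaussian noise are added on top.
    """
    if timing is None:
        timing = TimingConfig()
    if not 0 <= class_id < signatures.n_classes:
        raise ValueError(
            f"unknown class_id {class_id}; expected 0..{signatures.n_classes - 1}"
        )
    rng = np.random.default_rng(seed)
    n_sensors = signatures.n_sensors
    cv = signatures.within_class_cv
    if cv > 0:
        # lognormal with unit mean and coefficient of variation cv
        sigma = np.sqrt(np.log1p(cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_sensors)
    else:
        factors = np.ones(n_sensors)
    drift_slopes = (
        rng.normal(0.0, signatures.drift_slope_sd, size=n_sensors)
        if signatures.drift_slope_sd > 0
        else np.zeros(n_sensors)
    )
    t = timing.time_axis()
    signal = np.empty((n_sensors, timing.n_samples))
    for s in range(n_sensors):
        a_eff = signatures.amplitude[class_id, s] * factors[s]
        curve = _phase_curve(
            timing,
            signatures.baseline[s],
            a_eff,
            signatures.rise_tau[s],
            signatures.decay_tau[s],
        )
        signal[s] = curve + drift_slopes[s] * t
    if signatures.noise_sd > 0:
        signal += rng.normal(0.0, signatures.noise_sd, size=signal.shape)
    return SensorRecording(
        signal=signal,
        timing=timing,
        label=class_id,
        specimen_id=specimen_id,
        unit="resistance",
    )


def simulate_dataset(
    signatures: ClassSignatureSet,
    per_class: int,
    timing: TimingConfig | None = None,
    seed: int = 0,
) -> list[SensorRecording]:
    """Simulate a balanced labelled dataset, deterministically shuffled."""
    if per_class < 1:
        raise ValueError("per_class must be at least 1")
    if timing is None:
        timing = TimingConfig()
    rng = np.random.default_rng(seed)
    specs = [
        (c, i) for c in range(signatures.n_classes) for i in range(per_class)
    ]
    order = rng.permutation(len(specs))
    # independent per-recording seeds derived from the master seed
    rec_seeds = rng.integers(0, 2**31 - 1, size=len(specs))
    recordings = []
    for pos, idx in enumerate(order):
        c, i = specs[idx]
        recordings.append(
            simulate_recording(
                signatures,
                c,
                timing,
                seed=int(rec_seeds[pos]),
                specimen_id=f"class{c}_rep{i}",
            )
        )
    return recordings


def simulate_feature_table(
    n_classes: int,
    per_class: int,
    n_features: int = 80,
    separation: float = MODERATE_SEPARATION,
    seed: int = 0,
):
    """Draw a labelled feature table directly from class-conditional Gaussians.

    Class means are ``separation`` times standard-normal vectors; rows are
    the class mean plus unit-variance isotropic noise.  ``separation=0``
    makes the rows exchangeable across labels (all classes share one
    distribution), the basis for downstream validity tests.
    """
    from enosecp.features import FeatureTable, default_feature_names

    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if per_class < 1:
        raise ValueError("per_class must be at least 1")
    if n_features < 1:
        raise ValueError("n_features must be at least 1")
    rng = np.random.default_rng(seed)
    means = separation * rng.standard_normal(size=(n_classes, n_features))
    labels = np.repeat(np.arange(n_classes), per_class)
    x = means[labels] + rng.standard_normal(size=(labels.size, n_features))
    order = rng.permutation(labels.size)
    names = default_feature_names(n_features)
    return FeatureTable(values=x[order], names=names, labels=labels[order])


# ---------------------------------------------------------------------------
# Disk I/O: wide CSV (time_s, S1..Sn) with a JSON metadata sidecar.

def write_recording(recording: SensorRecording, path: str | Path) -> None:
    path = Path(path)
    cols = {"time_s": recording.timing.time_axis()}
    for s in range(recording.n_sensors):
        cols[f"S{s + 1}"] = recording.signal[s]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "label": None if recording.label is None else int(recording.label),
        "specimen_id": recording.specimen_id,
        "unit": recording.unit,
        "sampling_rate": recording.timing.sampling_rate,
        "baseline_duration": recording.timing.baseline_duration,
        "reaction_duration": recording.timing.reaction_duration,
        "cleaning_duration": recording.timing.cleaning_duration,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> SensorRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    timing = TimingConfig(
        sampling_rate=meta["sampling_rate"],
        baseline_duration=meta["baseline_duration"],
        reaction_duration=meta["reaction_duration"],
        cleaning_duration=meta["cleaning_duration"],
    )
    sensors = [c for c in frame.columns if c != "time_s"]
    signal = frame[sensors].to_numpy().T
    return SensorRecording(
        signal=signal,
        timing=timing,
        label=meta.get("label"),
        specimen_id=meta.get("specimen_id", ""),
        unit=meta.get("unit", "resistance"),
    )
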