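"""Deterministic EEG conditioning: resampling, re-referencing, filtering, epoching.

The conditioning chain mirrors standard clinical-EEG practice: anti-aliased
downsampling to 500 Hz, common average reference, zero-phase Butterworth
band-pass (0.1–45 Hz for resting data, 1–30 Hz for the auditory task),
decomposition into the five canonical bands, and stimulus-locked epoch
extraction with pre-stimulus baseline correction and a 75 μV amplitude
rejection criterion. All steps are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import signal

from .recording import RawRecording


@lru_cache(maxsize=256)
def _butter_sos(order: int, low_hz: float, high_hz: float,
                fs: float) -> np.ndarray:
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs, output="sos")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band {self.name}: "
                             f"{self.low_hz}-{self.high_hz} Hz")


#: The five canonical EEG bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Delta", 1.0, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 13.0),
    BandDefinition("Beta", 13.0, 30.0),
    BandDefinition("Gamma", 30.0, 45.0),
)

#: Wide analysis bands used before band decomposition.
REST_BAND = BandDefinition("rest-wide", 0.1, 45.0)
TASK_BAND = BandDefinition("task-wide", 1.0, 30.0)


def resample(rec: RawRecording, target_fs: float) -> RawRecording:
    """Anti-aliased polyphase resampling; events are remapped by the ratio.

    Only downsampling (or the identity) is supported; the sample count scales
    by ``target_fs / fs`` rounded down.
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz not supported")
    if target_fs == rec.fs:
        return rec.copy_with()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    n_out = int(rec.n_samples * target_fs / rec.fs)
    data = data[:, :n_out]
    ratio = target_fs / rec.fs
    events = [(int(idx * ratio), cond) for idx, cond in rec.events]
    events = [(i, c) for i, c in events if i < data.shape[1]]
    return rec.copy_with(data=data, fs=float(target_fs), events=events)


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean over channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def butterworth_bandpass(rec: RawRecording, low_hz: float, high_hz: float,
                         order: int = 4) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band {low_hz}-{high_hz} Hz invalid for Nyquist {nyq} Hz")
    sos = _butter_sos(order, float(low_hz), float(high_hz), float(rec.fs))
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def band_decompose(rec: RawRecording,
                   bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   order: int = 4) -> dict[str, RawRecording]:
    """One band-pass filtered copy of the recording per band definition."""
    return {b.name: butterworth_bandpass(rec, b.low_hz, b.high_hz, order)
            for b in bands}


@dataclass
class Epochs:
    """Stimulus-locked epochs: ``data`` is (epochs, channels, samples) in μV.

    ``times_ms`` is relative to stimulus onset; ``rejected`` marks epochs
    excluded by the amplitude criterion; ``dropped_events`` records events
    whose window did not fit in the recording.
    """

    data: np.ndarray
    times_ms: np.ndarray
    conditions: list[str]
    fs: float
    labels: list[str]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_corrected: bool = False
    dropped_events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def extract_epochs(rec: RawRecording, pre_ms: float = 100.0,
                   post_ms: float = 400.0) -> Epochs:
    """Cut half-open windows ``[onset - pre, onset + post)`` around events.

    The sample at the onset belongs to the post-stimulus interval. Events
    whose window falls outside the recording are dropped and logged in
    ``dropped_events``.
    """
    if rec.state != "task":
        raise ValueError("epoch extraction requires a task-state recording")
    if not rec.events:
        raise ValueError("recording has no events")
    n_pre = int(round(pre_ms / 1000.0 * rec.fs))
    n_post = int(round(post_ms / 1000.0 * rec.fs))
    epochs, conds, dropped = [], [], []
    for onset, cond in rec.events:
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > rec.n_samples:
            dropped.append((onset, cond))
            continue
        epochs.append(rec.data[:, lo:hi])
        conds.append(cond)
    if not epochs:
        raise ValueError("no event window fits inside the recording")
    times = (np.arange(n_pre + n_post) - n_pre) / rec.fs * 1000.0
    return Epochs(data=np.stack(epochs), times_ms=times, conditions=conds,
                  fs=rec.fs, labels=list(rec.labels), dropped_events=dropped)


def baseline_and_reject(ep: Epochs, threshold_uV: float = 75.0) -> Epochs:
    """Baseline-correct to the pre-stimulus mean, then apply amplitude rejection.

    Per epoch and channel the mean over the pre-stimulus interval
    ``[-pre, 0)`` ms is subtracted; any epoch where any channel exceeds
    ``threshold_uV`` in absolute value after correction is marked rejected
    (the epoch is rejected globally, across all channels).
    """
    if ep.n_epochs == 0:
        raise ValueError("no epochs to correct")
    pre_mask = ep.times_ms < 0
    if not pre_mask.any():
        raise ValueError("zero-length baseline interval")
    base = ep.data[:, :, pre_mask].mean(axis=2, keepdims=True)
    data = ep.data - base
    rejected = (np.abs(data) > threshold_uV).any(axis=(1, 2))
    return Epochs(data=data, times_ms=ep.times_ms.copy(),
                  conditions=list(ep.conditions), fs=ep.fs,
                  labels=list(ep.labels), rejected=rejected,
                  baseline_corrected=True,
                  dropped_events=list(ep.dropped_events))


def preprocess_rest(rec: RawRecording, target_fs: float = 500.0,
                    order: int = 4) -> RawRecording:
    """Standard resting-state chain: resample -> CAR -> 0.1–45 Hz band-pass."""
    out = resample(rec, target_fs) if rec.fs > target_fs else rec
    out = common_average_reference(out)
    return butterworth_bandpass(out, REST_BAND.low_hz, REST_BAND.high_hz, order)


def preprocess_task(rec: RawRecording, target_fs: float = 500.0,
                    order: int = 4) -> RawRecording:
    """Standard task-state chain: resample -> CAR -> 1–30 Hz band-pass."""
    out = resample(rec, target_fs) if rec.fs > target_fs else rec
    out = common_average_reference(out)
    return butterworth_bandpass(out, TASK_BAND.low_hz, TASK_BAND.high_hz, order)
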