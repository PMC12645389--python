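"""Auditory ERP measurement (N1, MMN) and task-state SC/NI (ESC, ENI).

N1 is measured on the standard-stimulus average (the obligatory auditory
negativity around 100 ms); MMN on the deviant-minus-standard difference
wave (the deviance-detection negativity). Component amplitude is the
negative peak inside a search window; latency is the time of that peak.
Task-state spatiotemporal correlation entropy and neuromodulation intensity
(ESC/ENI) reuse the resting-state machinery with 1-second segments anchored
at stimulus onsets, so each segment spans one stimulus-onset asynchrony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .ndf import BandFeatures, DEFAULT_RHO_GRID, NIResult, SCVector, \
    sc_ni_from_stack
from .preprocess import Epochs
from .recording import RawRecording, segment_at_events

#: Default component search windows (ms post-stimulus).
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "N1": (60.0, 160.0),
    "MMN": (100.0, 250.0),
}

#: Electrode sets over which subject-level scalar features are averaged;
#: the electrodes where the group differences concentrate.
N1_ELECTRODES: tuple[str, ...] = ("C3", "C4", "CZ")
MMN_ELECTRODES: tuple[str, ...] = ("FZ", "FC1", "C3")


@dataclass
class ERPWaveform:
    """Condition-average waveform: ``data`` is (channels, samples) in μV."""

    data: np.ndarray
    times_ms: np.ndarray
    condition: str  # "STD", "DEV" or "MMN"
    labels: list[str]
    n_epochs_averaged: int

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass(frozen=True)
class ComponentMeasure:
    component: str  # "N1" or "MMN"
    channel: str
    amplitude_uV: float  # negative peak value
    latency_ms: float  # time of the peak
    search_window_ms: tuple[float, float]


def wavelet_denoise(ep: Epochs, wavelet: str = "db4", level: int = 4) -> Epochs:
    """Per-epoch/channel wavelet shrinkage (soft universal threshold).

    Daubechies-4 decomposition to the given level; detail coefficients are
    soft-thresholded at ``σ̂·sqrt(2·ln n)`` with σ̂ the median-absolute-
    deviation estimate from the finest detail level; reconstruction is
    truncated to the input length. Deterministic; an all-zero epoch maps to
    an all-zero epoch.
    """
    n = ep.data.shape[2]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"epoch of {n} samples supports at most {max_level} levels "
            f"for {wavelet} (requested {level})")
    out = np.empty_like(ep.data)
    for e in range(ep.data.shape[0]):
        for c in range(ep.data.shape[1]):
            x = ep.data[e, c]
            coeffs = pywt.wavedec(x, wavelet, level=level)
            sigma = np.median(np.abs(coeffs[-1])) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(n))
            if thr > 0:
                coeffs = [coeffs[0]] + [pywt.threshold(c_, thr, mode="soft")
                                        for c_ in coeffs[1:]]
            out[e, c] = pywt.waverec(coeffs, wavelet)[:n]
    return Epochs(data=out, times_ms=ep.times_ms.copy(),
                  conditions=list(ep.conditions), fs=ep.fs,
                  labels=list(ep.labels), rejected=ep.rejected.copy(),
                  baseline_corrected=ep.baseline_corrected,
                  dropped_events=list(ep.dropped_events))


def average_erp(ep: Epochs, condition: str) -> ERPWaveform:
    """Arithmetic mean over the non-rejected epochs of one condition."""
    sel = [i for i, c in enumerate(ep.conditions)
           if c == condition and not ep.rejected[i]]
    if not sel:
        raise ValueError(f"no usable epochs of condition {condition!r}")
    return ERPWaveform(data=ep.data[sel].mean(axis=0),
                       times_ms=ep.times_ms.copy(), condition=condition,
                       labels=list(ep.labels), n_epochs_averaged=len(sel))


def mmn_difference(dev: ERPWaveform, std: ERPWaveform) -> ERPWaveform:
    """Deviant-minus-standard difference wave (the MMN)."""
    if dev.labels != std.labels or dev.data.shape != std.data.shape \
            or not np.array_equal(dev.times_ms, std.times_ms):
        raise ValueError("DEV and STD waveforms must share channels and times")
    return ERPWaveform(data=dev.data - std.data, times_ms=dev.times_ms.copy(),
                       condition="MMN", labels=list(dev.labels),
                       n_epochs_averaged=min(dev.n_epochs_averaged,
                                             std.n_epochs_averaged))


def peak_measure(w: ERPWaveform, component: str,
                 window_ms: tuple[float, float] | None = None,
                 ) -> list[ComponentMeasure]:
    """Negative-peak amplitude and latency per channel inside a search window.

    The amplitude is the minimum value in the window (these are negative
    components); the latency is the time of that minimum, with ties broken
    toward the earliest sample.
    """
    if window_ms is None:
        window_ms = DEFAULT_WINDOWS[component]
    lo, hi = window_ms
    mask = (w.times_ms >= lo) & (w.times_ms <= hi)
    if not mask.any():
        raise ValueError(f"empty search window {window_ms} ms")
    times = w.times_ms[mask]
    seg = w.data[:, mask]
    idx = seg.argmin(axis=1)  # argmin returns the first minimum: earliest tie
    return [ComponentMeasure(component=component, channel=lb,
                             amplitude_uV=float(seg[c, idx[c]]),
                             latency_ms=float(times[idx[c]]),
                             search_window_ms=(float(lo), float(hi)))
            for c, lb in enumerate(w.labels)]


def task_sc_ni(rec: RawRecording, T: float = 1.0,
               kernel_factor: float = 1.5,
               rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
               ) -> tuple[SCVector, NIResult]:
    """ESC and ENI: SC/NI with T-second segments anchored at stimulus onsets.

    Delegates to the same kernel/entropy/decomposition machinery as the
    resting-state features; the only difference is the stimulus-locked
    segmentation grid (each segment spans one SOA at the default T = 1 s).
    """
    stack = segment_at_events(rec, T)
    feats: BandFeatures = sc_ni_from_stack(stack, kernel_factor, rho_grid)
    return feats.sc, feats.ni


def erp_scalar_features(std: ERPWaveform, mmn: ERPWaveform,
                        n1_window: tuple[float, float] | None = None,
                        mmn_window: tuple[float, float] | None = None,
                        n1_electrodes: tuple[str, ...] = N1_ELECTRODES,
                        mmn_electrodes: tuple[str, ...] = MMN_ELECTRODES,
                        ) -> dict[str, float]:
    """Subject-level scalar ERP features averaged over fixed electrode sets."""
    n1 = {m.channel: m for m in peak_measure(std, "N1", n1_window)}
    mm = {m.channel: m for m in peak_measure(mmn, "MMN", mmn_window)}
    return {
        "N1-Amplitude": float(np.mean([n1[c].amplitude_uV
                                       for c in n1_electrodes])),
        "N1-Latency": float(np.mean([n1[c].latency_ms
                                     for c in n1_electrodes])),
        "MMN-Amplitude": float(np.mean([mm[c].amplitude_uV
                                        for c in mmn_electrodes])),
        "MMN-Latency": float(np.mean([mm[c].latency_ms
                                      for c in mmn_electrodes])),
    }
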