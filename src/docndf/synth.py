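"""Seeded synthetic two-group EEG cohorts (rest + auditory oddball task).

The generator produces the statistical structure the analysis method
assumes, so every downstream stage can be exercised and validated without
patient data:

* **Background activity** — per canonical band, a shared sinusoidal source
  with slow random phase drift plus an independent per-channel copy, mixed
  by a ``synchrony`` weight that controls inter-channel correlation, plus
  additive Gaussian sensor noise. Higher synchrony ⇒ more similar channel
  dynamics ⇒ higher spatiotemporal correlation entropy.

* **Transient bursts** — in a fraction ≈ ``transient_prob`` of
  non-overlapping T-second windows aligned to the analysis segmentation
  grid, an amplitude-modulated spike train with Gamma-distributed (hence
  positively skewed, non-Gaussian) spike amplitudes is injected on all
  channels. The injected window set is recorded in the ground-truth log, so
  the neuromodulation-intensity estimate can be checked against the exact
  injected proportion.

* **Auditory ERPs** — every stimulus adds a negative Gaussian-windowed N1
  deflection with a central (C3/CZ-peaked) topography; deviant stimuli
  additionally add an MMN deflection with a frontal (FZ/FC1-peaked)
  topography. Template amplitudes/latencies are group parameters and are
  logged for exact recovery tests.

All generators are deterministic functions of their seed. Amplitudes are in
μV throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np

from .montage import CHANNELS_30, topography_gains
from .recording import RawRecording, save_recording

#: Default per-band oscillation amplitudes (μV), dominated by slow activity
#: as is typical of severely brain-injured patients.
DEFAULT_BAND_POWERS: dict[str, float] = {
    "Delta": 4.0, "Theta": 3.0, "Alpha": 2.5, "Beta": 1.5, "Gamma": 0.8,
}

_BAND_EDGES: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 4.0), "Theta": (4.0, 8.0), "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0), "Gamma": (30.0, 45.0),
}

#: ERP topography centroids.
_N1_CENTER = ("C3", "CZ")
_MMN_CENTER = ("FZ", "FC1")


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one diagnostic group."""

    group_label: str  # "MCS" or "UWS"
    n_subjects: int = 1
    synchrony: float = 0.5  # shared-source mixing weight in [0, 1]
    transient_prob: float = 0.2  # per-window burst probability (ground-truth NI)
    band_powers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS))
    n1_amp_uV: float = -5.0
    n1_lat_ms: float = 110.0
    mmn_amp_uV: float = -4.0
    mmn_lat_ms: float = 170.0
    noise_sd_uV: float = 2.0
    burst_amp_uV: float = 25.0  # Gamma-mean spike amplitude of bursts
    burst_T_s: float = 2.0  # burst windows align to this segmentation grid
    task_synchrony_boost: float = 0.25  # extra shared-source coupling under
    # auditory stimulation (the task state recruits shared networks, raising
    # spatiotemporal synchrony relative to rest)

    def __post_init__(self) -> None:
        if not 0.0 <= self.synchrony <= 1.0:
            raise ValueError("synchrony must lie in [0, 1]")
        if not 0.0 <= self.transient_prob <= 1.0:
            raise ValueError("transient_prob must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n1_amp_uV > 0 or self.mmn_amp_uV > 0:
            raise ValueError("N1/MMN amplitudes are negative components")
        for lat in (self.n1_lat_ms, self.mmn_lat_ms):
            if not 0.0 <= lat <= 400.0:
                raise ValueError("component latency must lie in 0-400 ms")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be non-negative")


#: Study-condition defaults for the two groups: higher synchrony, more
#: transient activity and larger/faster N1 plus larger/later MMN in the
#: minimally conscious group.
MCS_DEFAULTS = GroupParams(group_label="MCS", n_subjects=61, synchrony=0.7,
                           transient_prob=0.30, n1_amp_uV=-6.0,
                           n1_lat_ms=100.0, mmn_amp_uV=-5.0,
                           mmn_lat_ms=180.0)
UWS_DEFAULTS = GroupParams(group_label="UWS", n_subjects=96, synchrony=0.3,
                           transient_prob=0.15, n1_amp_uV=-3.0,
                           n1_lat_ms=130.0, mmn_amp_uV=-2.5,
                           mmn_lat_ms=150.0)


@dataclass(frozen=True)
class StimulusSequence:
    """An oddball stimulus schedule with strictly increasing onsets."""

    onsets_ms: tuple[float, ...]
    conditions: tuple[str, ...]
    soa_ms: float
    tone_dur_ms: float = 200.0

    def __post_init__(self) -> None:
        if len(self.onsets_ms) != len(self.conditions):
            raise ValueError("onsets and conditions must align")
        d = np.diff(self.onsets_ms)
        if len(d) and not np.allclose(d, self.soa_ms):
            raise ValueError("onsets must be spaced by soa_ms")

    @property
    def n_stimuli(self) -> int:
        return len(self.conditions)


def generate_oddball_sequence(n_std: int = 800, n_dev: int = 100,
                              min_gap: int = 3, soa_ms: float = 1000.0,
                              seed: int = 0) -> StimulusSequence:
    """Pseudorandom oddball order with ≥ ``min_gap`` standards before each deviant.

    The constraint also applies before the first deviant. Raises if
    ``n_std < min_gap * n_dev`` (infeasible), naming the required minimum.
    """
    if n_std < min_gap * n_dev:
        raise ValueError(
            f"infeasible oddball sequence: {n_dev} deviants with a minimum "
            f"gap of {min_gap} require at least {min_gap * n_dev} standards "
            f"(got {n_std})")
    rng = np.random.default_rng(seed)
    # Gap g_i >= min_gap of standards before deviant i; trailing gap >= 0.
    extra = n_std - min_gap * n_dev
    # Distribute the surplus standards uniformly over the n_dev + 1 slots.
    cuts = np.sort(rng.integers(0, extra + 1, size=n_dev))
    gaps = np.diff(np.concatenate(([0], cuts, [extra]))) + np.array(
        [min_gap] * n_dev + [0])
    conds: list[str] = []
    for i in range(n_dev):
        conds.extend(["STD"] * int(gaps[i]))
        conds.append("DEV")
    conds.extend(["STD"] * int(gaps[n_dev]))
    onsets = tuple(float(i * soa_ms) for i in range(len(conds)))
    return StimulusSequence(onsets_ms=onsets, conditions=tuple(conds),
                            soa_ms=float(soa_ms))


def _band_noise(lo: float, hi: float, fs: float, n_samples: int, n_sources: int,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise rows (spectral shaping).

    White Gaussian noise is shaped in the frequency domain with a
    raised-cosine band edge (10 % of the band width), which keeps the rows
    exactly Gaussian and is much cheaper than time-domain filtering.
    """
    hi = min(hi, 0.49 * fs)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    roll = 0.1 * (hi - lo)
    gain = np.ones_like(freqs)
    gain[freqs < lo] = 0.0
    gain[freqs > hi] = 0.0
    rise = (freqs >= lo) & (freqs < lo + roll)
    gain[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - lo) / roll))
    fall = (freqs > hi - roll) & (freqs <= hi)
    gain[fall] = 0.5 * (1 - np.cos(np.pi * (hi - freqs[fall]) / roll))
    spec = np.fft.rfft(rng.standard_normal((n_sources, n_samples)), axis=1)
    x = np.fft.irfft(spec * gain[None, :], n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _background(params: GroupParams, n_channels: int, fs: float,
                n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian background oscillations plus sensor noise (μV).

    Each band contributes one shared source and one private source per
    channel, both unit-RMS band-limited Gaussian noise, mixed as
    ``synchrony * shared + (1 - synchrony) * private`` and scaled by the
    band amplitude. The per-sample distribution of the background is
    therefore Gaussian, matching the model's background assumption, while
    the injected bursts are the only non-Gaussian component.
    """
    data = np.zeros((n_channels, n_samples))
    syn = params.synchrony
    for band, amp in params.band_powers.items():
        if amp == 0:
            continue
        lo, hi = _BAND_EDGES.get(band, (1.0, 45.0))
        src = _band_noise(lo, hi, fs, n_samples, n_channels + 1, rng)
        shared, private = src[0], src[1:]
        data += amp * (syn * shared[None, :] + (1.0 - syn) * private)
    if params.noise_sd_uV > 0:
        data += rng.normal(0.0, params.noise_sd_uV,
                           size=(n_channels, n_samples))
    return data


def _burst_waveform(n: int, fs: float, amp_uV: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated spike train with Gamma (positively skewed) amplitudes."""
    t = np.arange(n) / fs
    dur = n / fs
    n_spikes = max(5, int(round(10 * dur)))
    centers = rng.uniform(0.05 * dur, 0.95 * dur, size=n_spikes)
    amps = rng.gamma(shape=2.0, scale=amp_uV / 2.0, size=n_spikes)
    w = np.zeros(n)
    for c, a in zip(centers, amps):
        w += a * np.exp(-((t - c) ** 2) / (2 * 0.025**2))
    return w


def _inject_bursts(data: np.ndarray, params: GroupParams, fs: float,
                   rng: np.random.Generator, window_samples: int,
                   offsets: np.ndarray) -> list[int]:
    """Inject bursts into a random subset of the given windows; return indices.

    Each burst carries a random per-channel gain topography (Gamma, mean 1),
    so the event is present on every channel but not identical across
    channels — a spatially uniform burst would be cancelled exactly by
    common average referencing.
    """
    injected: list[int] = []
    n_channels = data.shape[0]
    for w_idx, start in enumerate(offsets):
        if rng.uniform() >= params.transient_prob:
            continue
        n = min(window_samples, data.shape[1] - start)
        if n <= 0:
            continue
        wave = _burst_waveform(n, fs, params.burst_amp_uV, rng)
        gains = rng.gamma(shape=2.0, scale=0.5, size=n_channels)
        data[:, start:start + n] += gains[:, None] * wave[None, :]
        injected.append(w_idx)
    return injected


def generate_resting_recording(params: GroupParams, n_channels: int = 30,
                               fs: float = 500.0, duration_s: float = 600.0,
                               seed: int = 0) -> RawRecording:
    """Eyes-closed resting recording with grid-aligned transient bursts.

    Burst windows are the non-overlapping ``burst_T_s``-second windows of
    the analysis segmentation grid; the injected window indices are logged
    in ``meta["burst_windows"]`` so the ground-truth transient proportion is
    exactly recoverable.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    hi_edge = max((_BAND_EDGES.get(b, (0, 45.0))[1]
                   for b, a in params.band_powers.items() if a > 0),
                  default=0.0)
    if fs <= 2 * hi_edge:
        raise ValueError(f"fs {fs} Hz too low for band edge {hi_edge} Hz")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    data = _background(params, n_channels, fs, n_samples, rng)
    K = int(round(params.burst_T_s * fs))
    n_windows = n_samples // K
    offsets = np.arange(n_windows) * K
    injected = _inject_bursts(data, params, fs, rng, K, offsets)
    labels = list(CHANNELS_30[:n_channels])
    meta = {
        "group": params.group_label,
        "burst_windows": injected,
        "n_burst_windows": n_windows,
        "burst_T_s": params.burst_T_s,
        "transient_prob": params.transient_prob,
        "seed": seed,
    }
    return RawRecording(data=data, fs=fs, labels=labels, state="rest",
                        meta=meta)


def _gaussian_template(times_ms: np.ndarray, amp_uV: float, lat_ms: float,
                       width_ms: float) -> np.ndarray:
    return amp_uV * np.exp(-((times_ms - lat_ms) ** 2) / (2 * width_ms**2))


def generate_task_recording(params: GroupParams,
                            sequence: StimulusSequence,
                            n_channels: int = 30, fs: float = 500.0,
                            seed: int = 0,
                            n1_width_ms: float = 18.0,
                            mmn_width_ms: float = 28.0) -> RawRecording:
    """Oddball-task recording: background + per-stimulus ERP templates + bursts.

    Every stimulus adds the N1 template (negative Gaussian deflection at
    ``n1_lat_ms``, C3/CZ-weighted topography); deviants additionally add the
    MMN template (FZ/FC1-weighted) at ``mmn_lat_ms``. Burst windows are
    aligned to stimulus onsets and span one SOA. Events and the injected
    templates/gains are stored with the recording.
    """
    if sequence.n_stimuli == 0:
        raise ValueError("stimulus sequence is empty")
    for lat in (params.n1_lat_ms, params.mmn_lat_ms):
        if lat >= sequence.soa_ms:
            raise ValueError(
                f"template latency {lat} ms beyond SOA {sequence.soa_ms} ms")
    rng = np.random.default_rng(seed)
    soa_samples = int(round(sequence.soa_ms / 1000.0 * fs))
    lead_in = int(round(0.5 * fs))
    tail = int(round(0.5 * fs))
    n_samples = lead_in + sequence.n_stimuli * soa_samples + tail
    task_params = replace(
        params, synchrony=min(1.0, params.synchrony
                              + params.task_synchrony_boost))
    data = _background(task_params, n_channels, fs, n_samples, rng)
    labels = list(CHANNELS_30[:n_channels])

    # ERP templates over one post-stimulus window of 400 ms.
    tpl_len = int(round(0.4 * fs))
    tpl_times = np.arange(tpl_len) / fs * 1000.0
    n1 = _gaussian_template(tpl_times, params.n1_amp_uV, params.n1_lat_ms,
                            n1_width_ms)
    mmn = _gaussian_template(tpl_times, params.mmn_amp_uV, params.mmn_lat_ms,
                             mmn_width_ms)
    g_n1 = topography_gains(labels, _N1_CENTER)
    g_mmn = topography_gains(labels, _MMN_CENTER)

    events: list[tuple[int, str]] = []
    onsets = lead_in + np.arange(sequence.n_stimuli) * soa_samples
    for onset, cond in zip(onsets, sequence.conditions):
        data[:, onset:onset + tpl_len] += g_n1[:, None] * n1[None, :]
        if cond == "DEV":
            data[:, onset:onset + tpl_len] += g_mmn[:, None] * mmn[None, :]
        events.append((int(onset), cond))

    injected = _inject_bursts(data, params, fs, rng, soa_samples, onsets)
    meta = {
        "group": params.group_label,
        "n1_template": n1, "mmn_template": mmn, "template_times_ms": tpl_times,
        "n1_gains": g_n1, "mmn_gains": g_mmn,
        "n1_amp_uV": params.n1_amp_uV, "n1_lat_ms": params.n1_lat_ms,
        "mmn_amp_uV": params.mmn_amp_uV, "mmn_lat_ms": params.mmn_lat_ms,
        "burst_windows": injected, "n_burst_windows": len(onsets),
        "transient_prob": params.transient_prob,
        "seed": seed,
    }
    return RawRecording(data=data, fs=fs, labels=labels, events=events,
                        state="task", meta=meta)


@dataclass
class Subject:
    """One cohort member: group label, seeds, and lazy recording factories."""

    subject_id: str
    group: str
    params: GroupParams
    rest_seed: int
    task_seed: int
    n_channels: int
    fs: float
    rest_duration_s: float
    oddball: tuple[int, int, int, float]  # (n_std, n_dev, min_gap, soa_ms)

    def make_rest(self) -> RawRecording:
        return generate_resting_recording(
            self.params, self.n_channels, self.fs, self.rest_duration_s,
            seed=self.rest_seed)

    def make_task(self) -> RawRecording:
        n_std, n_dev, min_gap, soa = self.oddball
        seq = generate_oddball_sequence(n_std, n_dev, min_gap, soa,
                                        seed=self.task_seed)
        return generate_task_recording(self.params, seq, self.n_channels,
                                       self.fs, seed=self.task_seed)


@dataclass
class Cohort:
    """A labelled two-group cohort with per-subject derived seeds."""

    subjects: list[Subject]
    master_seed: int

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]

    def manifest(self) -> list[dict]:
        return [{"subject_id": s.subject_id, "group": s.group,
                 "rest_seed": s.rest_seed, "task_seed": s.task_seed}
                for s in self.subjects]

    def write(self, outdir: str | Path) -> None:
        """Materialize all recordings as CSV/TSV/JSON under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            save_recording(s.make_rest(), outdir / f"{s.subject_id}_rest")
            save_recording(s.make_task(), outdir / f"{s.subject_id}_task")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"master_seed": self.master_seed,
                       "subjects": self.manifest()}, fh, indent=1)


def generate_cohort(mcs: GroupParams = MCS_DEFAULTS,
                    uws: GroupParams = UWS_DEFAULTS,
                    n_channels: int = 30, fs: float = 500.0,
                    rest_duration_s: float = 600.0,
                    oddball: tuple[int, int, int, float] = (800, 100, 3, 1000.0),
                    seed: int = 0) -> Cohort:
    """Two-group cohort with per-subject seeds derived from the master seed.

    Recordings are generated lazily (``Subject.make_rest`` /
    ``Subject.make_task``) so large cohorts need not be held in memory; the
    derivation is deterministic, so the same master seed yields byte-identical
    recordings.
    """
    n_total = mcs.n_subjects + uws.n_subjects
    state = np.random.SeedSequence(seed).generate_state(2 * n_total)
    child = [int(s) & 0x7FFFFFFF for s in state]
    subjects: list[Subject] = []
    i = 0
    for params in (mcs, uws):
        per_subject = replace(params, n_subjects=1)
        for k in range(params.n_subjects):
            subjects.append(Subject(
                subject_id=f"{params.group_label.lower()}{k:03d}",
                group=params.group_label, params=per_subject,
                rest_seed=child[2 * i], task_seed=child[2 * i + 1],
                n_channels=n_channels, fs=fs,
                rest_duration_s=rest_duration_s, oddball=oddball))
            i += 1
    return Cohort(subjects=subjects, master_seed=seed)
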