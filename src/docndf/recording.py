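"""Core containers: multichannel recordings and fixed-length segment stacks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RawRecording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` amplitude matrix in μV.
    fs
        Sampling rate in Hz.
    labels
        Channel names (10/20 system), unique, one per row of ``data``.
    events
        ``(sample_index, condition)`` pairs for task recordings; conditions
        are ``"STD"`` / ``"DEV"``.
    state
        ``"rest"`` or ``"task"``.
    meta
        Free-form metadata; the synthetic generator stores its ground-truth
        log here (injected burst windows, ERP templates, gains).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    state: str = "rest"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for idx, _cond in self.events:
            if not (0 <= idx < self.data.shape[1]):
                raise ValueError(f"event index {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy_with(self, **kwargs) -> "RawRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class SegmentStack:
    """A recording cut into N equal segments of T seconds.

    ``X`` has shape ``(N, J, K)`` with ``K = round(T * fs)`` samples per
    segment. A trailing partial segment is discarded at construction.
    """

    X: np.ndarray
    T: float
    fs: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("X must be (segments, channels, samples)")
        if self.X.shape[2] != int(round(self.T * self.fs)):
            raise ValueError("segment sample count must equal T*fs")

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def samples_per_segment(self) -> int:
        return self.X.shape[2]


def segment_recording(rec: RawRecording, T: float) -> SegmentStack:
    """Cut ``rec`` into consecutive T-second segments from sample 0.

    The trailing remainder shorter than T is dropped. At least two full
    segments are required.
    """
    K = int(round(T * rec.fs))
    n = rec.n_samples // K
    if n < 2:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s yields {n} segment(s) of "
            f"{T} s; at least 2 required")
    X = rec.data[:, : n * K].reshape(rec.n_channels, n, K).transpose(1, 0, 2)
    return SegmentStack(X=np.ascontiguousarray(X), T=T, fs=rec.fs,
                        labels=list(rec.labels))


def segment_at_events(rec: RawRecording, T: float) -> SegmentStack:
    """Cut ``rec`` into T-second segments anchored at its event onsets.

    Segments extending beyond the recording end are dropped. Used for the
    task-state features, where each segment spans one stimulus-onset
    asynchrony.
    """
    if not rec.events:
        raise ValueError("recording has no events to anchor segments at")
    K = int(round(T * rec.fs))
    segs = [rec.data[:, onset: onset + K]
            for onset, _cond in rec.events
            if onset + K <= rec.n_samples]
    if len(segs) < 2:
        raise ValueError("fewer than 2 full event-anchored segments")
    X = np.ascontiguousarray(np.stack(segs, axis=0))
    return SegmentStack(X=X, T=T, fs=rec.fs, labels=list(rec.labels))


# ---------------------------------------------------------------------------
# Plain-text I/O: data CSV (columns = channels), events TSV, metadata JSON.

def save_recording(rec: RawRecording, prefix: str | Path) -> None:
    """Write ``<prefix>_data.csv``, ``<prefix>_events.tsv``, ``<prefix>_meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(
        f"{prefix}_data.csv", index=False, float_format="%.6f")
    pd.DataFrame(rec.events, columns=["onset_sample", "condition"]).to_csv(
        f"{prefix}_events.tsv", sep="\t", index=False)
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump({"fs": rec.fs, "state": rec.state, "labels": rec.labels},
                  fh, indent=1)


def load_recording(prefix: str | Path) -> RawRecording:
    """Read a recording previously written by :func:`save_recording`."""
    prefix = Path(prefix)
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(f"{prefix}_data.csv")
    ev = pd.read_csv(f"{prefix}_events.tsv", sep="\t")
    events = [(int(r.onset_sample), str(r.condition)) for r in ev.itertuples()]
    return RawRecording(data=df.to_numpy().T, fs=float(meta["fs"]),
                        labels=list(df.columns), events=events,
                        state=meta["state"])
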