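"""Nonlinear dynamics features: correlation entropy, SC, and NI.

The method models multichannel EEG as the sum of a temporally dense,
near-Gaussian background component and sparse, non-Gaussian transient
"neuromodulatory" events. Three quantities operationalize this:

* the **correlation-entropy matrix** ``C`` — for every segment *n* and
  channel *j*, the accumulated Gaussian-kernel similarity between that
  segment and all segments of the same channel (time-domain entropy
  sequence). Background segments resemble each other and score high;
  sparse transients score low.

* **spatiotemporal correlation entropy (SC)** ``Z_j`` — the kernel
  similarity of channel *j*'s entropy sequence to every channel's entropy
  sequence, summed; averaging over channels gives a whole-brain synchrony
  index.

* **neuromodulation intensity (NI)** ``P_j`` — the fraction of segments on
  channel *j* classified as transient by a percentile sweep over the
  entropy column combined with a skewness test of Gaussianity: the
  candidate background is the set of segments above the ρ-th percentile of
  ``C(:, j)``; the sweep keeps the ρ* whose concatenated background samples
  are closest to symmetric (minimum |skewness|); segments below that
  percentile are the transient set.

The Gaussian kernel width σ1 is 1.5 × the Silverman bandwidth of the pooled
amplitude samples, estimated once per recording and band and reused in both
the temporal and the spatial kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._kernels import _channel_entropy
from .preprocess import BandDefinition, DEFAULT_BANDS, butterworth_bandpass
from .recording import RawRecording, SegmentStack, segment_recording

#: Default percentile sweep for the two-component decomposition: 10–90 % in
#: steps of 5 %.
DEFAULT_RHO_GRID: tuple[float, ...] = tuple(np.arange(10.0, 95.0, 5.0))


@dataclass(frozen=True)
class KernelWidth:
    """Silverman bandwidth and the derived kernel width σ1 = factor × σ*."""
    sigma_star: float
    sigma1: float


@dataclass
class EntropyMatrix:
    """``C[n, j]``: correlation entropy of segment n on channel j; ``C ∈ (0, N]``."""
    C: np.ndarray  # (N, J)

    @property
    def n_segments(self) -> int:
        return self.C.shape[0]

    @property
    def n_channels(self) -> int:
        return self.C.shape[1]


@dataclass
class SCVector:
    """Per-channel spatiotemporal correlation entropy ``Z_j ∈ (0, J·N]``."""
    Z: np.ndarray  # (J,)
    whole_brain: float

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)


@dataclass
class NIResult:
    """Per-channel neuromodulation intensity and its decomposition bookkeeping.

    ``P[j] = |S_j| / (|S_j| + |L_j|)`` counts segments; ``rho_star[j]`` is the
    selected percentile; ``background_idx`` / ``transient_idx`` are the
    per-channel L / S segment index sets (disjoint; segments exactly at the
    percentile value belong to neither).
    """
    P: np.ndarray  # (J,)
    rho_star: np.ndarray  # (J,)
    background_idx: list[np.ndarray] = field(default_factory=list)
    transient_idx: list[np.ndarray] = field(default_factory=list)

    @property
    def whole_brain(self) -> float:
        return float(np.mean(self.P))


@dataclass
class BandFeatures:
    """SC + NI of one frequency band, with the kernel width used."""
    band: str
    sc: SCVector
    ni: NIResult
    kernel: KernelWidth


def estimate_kernel_width(values: np.ndarray, factor: float = 1.5) -> KernelWidth:
    """Silverman's rule-of-thumb bandwidth, scaled by ``factor``.

    ``σ* = 0.9 · min(sd, IQR/1.34) · n^(-1/5)`` with the sample standard
    deviation; ``σ1 = factor · σ*``. Degenerate input (fewer than two
    values, non-finite values, or zero spread) raises rather than silently
    substituting an epsilon.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("kernel width needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("kernel width input contains non-finite values")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero spread: kernel width undefined")
    sigma_star = 0.9 * spread * x.size ** (-0.2)
    return KernelWidth(sigma_star=sigma_star, sigma1=factor * sigma_star)


def correlation_entropy(stack: SegmentStack, sigma1: float) -> EntropyMatrix:
    """Correlation-entropy matrix of a segment stack.

    ``C[n, j] = (1/(T·fs)) Σ_i Σ_k exp(-(X[n,j,k] - X[i,j,k])² / (2σ1²))``,
    with the sum over all segments i = 1…N including i = n, so each entry
    lies in (0, N] and equals N exactly when every segment of the channel is
    identical. Note the normalization is by the segment sample count only,
    so C scales with N; comparisons across recordings must use equal N.
    """
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    N, J, K = stack.X.shape
    if N < 2:
        raise ValueError("at least 2 segments required")
    inv = 1.0 / (2.0 * sigma1 * sigma1)
    C = np.empty((N, J))
    for j in range(J):
        C[:, j] = _channel_entropy(np.ascontiguousarray(stack.X[:, j, :]), inv)
    return EntropyMatrix(C=C)


def spatiotemporal_entropy(C: EntropyMatrix, sigma1: float) -> SCVector:
    """Spatial kernel similarity of the per-channel entropy sequences.

    ``Z_j = Σ_k Σ_n exp(-(C[n,j] - C[n,k])² / (2σ1²))`` over all channels k
    (including k = j); the whole-brain value is the mean over channels.
    """
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    M = C.C  # (N, J)
    diff = M[:, :, None] - M[:, None, :]  # (N, J, J)
    Z = np.exp(-(diff**2) / (2.0 * sigma1 * sigma1)).sum(axis=(0, 2))
    return SCVector(Z=Z, whole_brain=float(np.mean(Z)))


def skewness(values: np.ndarray) -> float:
    """Population skewness ``(1/(N·σ³)) Σ (x_i − μ)³`` (σ the population sd)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    sd = np.std(x)
    if sd == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(stats.skew(x, bias=True))


def _subset_skew(s1: np.ndarray, s2: np.ndarray, s3: np.ndarray,
                 K: int) -> float | None:
    """Population skewness of a segment union from per-segment power sums.

    Algebraically identical to :func:`skewness` on the concatenated raw
    samples. Returns None for zero-variance input.
    """
    n = s1.size * K
    mu = s1.sum() / n
    m2 = s2.sum() / n - mu**2
    if m2 <= 0:
        return None
    m3 = s3.sum() / n - 3 * mu * s2.sum() / n + 2 * mu**3
    return float(m3 / m2**1.5)


def _jackknife_skew_se(s1: np.ndarray, s2: np.ndarray, s3: np.ndarray,
                       K: int) -> float:
    """Delete-one-segment jackknife standard error of the subset skewness."""
    m = s1.size
    if m < 2:
        return 0.0
    n = (m - 1) * K
    r1, r2, r3 = (s1.sum() - s1) / n, (s2.sum() - s2) / n, (s3.sum() - s3) / n
    m2 = r2 - r1**2
    ok = m2 > 0
    if ok.sum() < 2:
        return 0.0
    m3 = r3 - 3 * r1 * r2 + 2 * r1**3
    v = m3[ok] / m2[ok] ** 1.5
    return float(np.sqrt((m - 1) / m * ((v - v.mean()) ** 2).sum()))


def two_component_decompose(stack: SegmentStack, C: EntropyMatrix,
                            rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
                            min_segments: int = 3) -> NIResult:
    """Split each channel's segments into background (L) and transient (S).

    For every channel j and every percentile ρ in the grid, the candidate
    background ``L(ρ)`` is the concatenated raw samples of segments whose
    entropy ``C[:, j]`` is strictly above the ρ-th percentile (linear
    interpolation between closest ranks). The selected ρ* minimizes
    ``|skewness(L(ρ))|``; candidates indistinguishable from the minimum
    within skewness sampling error count as ties, and ties resolve toward
    smaller ρ, i.e. the largest background set that is statistically as
    symmetric as the best one. The sampling error is estimated per
    candidate by a delete-one-segment jackknife, which respects the strong
    within-band autocorrelation of the samples. This keeps the estimate at
    the transition point where the skewed transient segments have just been
    excluded, instead of drifting into the flat noise region beyond it,
    and sends an uncontaminated (all-Gaussian) channel to the grid floor.
    The transient set
    ``S_j`` is the segments strictly below the ρ*-th percentile, and
    ``P_j = |S_j| / (|S_j| + |L_j|)`` counting segments. Candidates with
    fewer than ``min_segments`` segments or zero sample spread are skipped;
    a channel where every candidate is skipped raises.
    """
    N, J, K = stack.X.shape
    P = np.empty(J)
    rho_star = np.empty(J)
    bg_idx: list[np.ndarray] = []
    tr_idx: list[np.ndarray] = []
    # Per-segment raw power sums; the skewness of any segment union follows
    # from the aggregated moments, which makes the sweep and its jackknife
    # error estimate cheap.
    s1 = stack.X.sum(axis=2)  # (N, J)
    s2 = (stack.X**2).sum(axis=2)
    s3 = (stack.X**3).sum(axis=2)
    grid = np.asarray(rho_grid, dtype=float)
    for j in range(J):
        col = C.C[:, j]
        thresholds = np.percentile(col, grid)
        cands: list[tuple[float, float, float]] = []  # (rho, |skew|, se)
        for rho, thr in zip(rho_grid, thresholds):
            sel = np.nonzero(col > thr)[0]
            if sel.size < min_segments:
                continue
            sk = _subset_skew(s1[sel, j], s2[sel, j], s3[sel, j], K)
            if sk is None:
                continue
            se = _jackknife_skew_se(s1[sel, j], s2[sel, j], s3[sel, j], K)
            cands.append((rho, abs(sk), se))
        if not cands:
            raise ValueError(
                f"channel {j}: no admissible background candidate in the "
                f"percentile sweep")
        m_sk, m_se = min(((sk, se) for _rho, sk, se in cands),
                         key=lambda t: t[0])
        rho = next(r for r, sk, _se in cands if sk <= m_sk + 2.0 * m_se)
        thr = np.percentile(col, rho)
        L = np.nonzero(col > thr)[0]
        S = np.nonzero(col < thr)[0]
        P[j] = S.size / (S.size + L.size)
        rho_star[j] = rho
        bg_idx.append(L)
        tr_idx.append(S)
    return NIResult(P=P, rho_star=rho_star, background_idx=bg_idx,
                    transient_idx=tr_idx)


def sc_ni_from_stack(stack: SegmentStack, kernel_factor: float = 1.5,
                     rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
                     ) -> BandFeatures:
    """SC + NI of one prepared segment stack (kernel width from pooled samples)."""
    kw = estimate_kernel_width(stack.X, factor=kernel_factor)
    C = correlation_entropy(stack, kw.sigma1)
    sc = spatiotemporal_entropy(C, kw.sigma1)
    ni = two_component_decompose(stack, C, rho_grid=rho_grid)
    return BandFeatures(band="full", sc=sc, ni=ni, kernel=kw)


def compute_sc_ni(rec: RawRecording,
                  bands: tuple[BandDefinition, ...] | None = DEFAULT_BANDS,
                  T: float = 2.0, kernel_factor: float = 1.5,
                  rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
                  ) -> dict[str, BandFeatures]:
    """Per-band SC and NI of a (preprocessed) recording.

    Each band is band-pass filtered, segmented into T-second segments, its
    kernel width estimated from the pooled band samples, and the entropy
    matrix, SC vector and NI decomposition computed. ``bands=None`` skips
    the band filter and analyzes the recording as a single ``"full"`` band
    (used for the full-band resting comparison and the task-state features).
    """
    if rec.duration_s < 2 * T:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s shorter than 2·T = {2 * T} s")
    out: dict[str, BandFeatures] = {}
    if bands is None:
        stack = segment_recording(rec, T)
        out["full"] = sc_ni_from_stack(stack, kernel_factor, rho_grid)
        return out
    for band in bands:
        filtered = butterworth_bandpass(rec, band.low_hz, band.high_hz)
        stack = segment_recording(filtered, T)
        feats = sc_ni_from_stack(stack, kernel_factor, rho_grid)
        feats.band = band.name
        out[band.name] = feats
    return out
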