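# Methods

## The model

The package implements a multimodal EEG marker set for grading residual
consciousness in severely brain-injured patients (minimally conscious
state, MCS, versus unresponsive wakefulness syndrome, UWS). Its core is a
two-component model of multichannel EEG,

    X = L + S,

where `L` is temporally dense background activity whose sample
distribution is (approximately) Gaussian, and `S` is sparse transient
"neuromodulatory" activity whose distribution deviates from Gaussianity.
Three statistics operationalize the model:

**Correlation-entropy matrix.** The recording is cut into `N` consecutive
segments of `T` seconds (`T = 2 s` at rest, `T = 1 s` — one
stimulus-onset asynchrony — during the auditory task). For segment `n` and
channel `j`,

    C[n,j] = (1 / (T·fs)) · Σ_{i=1..N} Σ_{k=1..T·fs}
             exp( −(X[n,j,k] − X[i,j,k])² / (2σ₁²) ),

a Gaussian-kernel similarity between segment `n` and *all* segments of the
same channel, accumulated sample-wise. The sum runs over all `i` including
`i = n` (the self term contributes exactly 1), and the normalization is by
the segment sample count only, so `C ∈ (0, N]` and scales with `N`:
whole-brain comparisons are always made at equal segment counts.
Background segments resemble one another and score high; sparse transients
score low.

**Spatiotemporal correlation entropy (SC).** The per-channel entropy
sequences are compared across channels with the same kernel:

    Z[j] = Σ_{k=1..J} Σ_{n=1..N} exp( −(C[n,j] − C[n,k])² / (2σ₁²) ),

including `k = j`, so `Z ∈ (0, J·N]`. The whole-brain SC is the mean of
`Z` over channels; it rises with inter-regional synchrony.

**Neuromodulation intensity (NI).** Per channel, a percentile sweep over
the entropy column separates background from transients. For each ρ in
10 %…90 % (step 5 %), the candidate background `L(ρ)` is the concatenated
raw samples of segments whose entropy lies strictly above the ρ-th
percentile (linear interpolation between closest ranks). The selected ρ*
minimizes the absolute population skewness of `L(ρ)` — the Gaussianity
test — and the transient set `S` is the segments strictly below that
percentile. `P[j] = |S| / (|S| + |L|)` counting segments; the whole-brain
NI is the channel mean. Segments exactly at the percentile value belong to
neither set and are excluded from the denominator.

**Kernel width.** `σ₁ = 1.5 · σ*`, with `σ*` the Silverman rule-of-thumb
bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` computed once per recording
and band from all pooled samples, and reused in both kernels. Degenerate
input (zero spread) raises rather than substituting an epsilon.

### Numerical choices in the ρ* selection

Once every transient segment has been excluded from `L(ρ)`, all remaining
candidates are samples from the same (symmetric) background, and their
|skewness| values are exchangeable noise around zero; a bare argmin over
them is ill-determined and drifts toward arbitrary large ρ, inflating the
NI estimate. The implementation therefore treats candidates whose
|skewness| lies within two standard errors of the minimum as ties and
resolves ties toward the smallest ρ (the largest background set that is
statistically as symmetric as the best one). The standard error is
estimated per candidate by a delete-one-segment jackknife, which respects
the strong within-band autocorrelation of EEG samples (an analytic
√(6/n) i.i.d. formula underestimates it badly). Two consequences, both
verified by tests: a channel with no transient activity lands at the grid
floor (P̂ = 0.10, the smallest admissible ρ), and with injected bursts the
estimate sits at the transition point, recovering the injected proportion
with mean absolute error ≲ 0.05 at the study conditions.

Candidates with fewer than 3 segments or zero sample variance are skipped;
a channel with no admissible candidate raises. Skewness of segment unions
is computed from per-segment power sums (algebraically identical to the
concatenated-sample formula), which makes the sweep and its jackknife
cheap. Segmentation drops the trailing partial segment.

## ERP analysis

Task recordings are epoched into half-open windows `[−100, +400)` ms
around each stimulus onset (the onset sample belongs to the post-stimulus
side); the pre-stimulus mean is subtracted per epoch and channel; epochs
exceeding 75 μV absolute on any channel after correction are rejected
globally. N1 is measured on the standard-stimulus average as the minimum
value in 60–160 ms; MMN on the deviant-minus-standard difference wave in
100–250 ms. Latency is the time of the minimum, ties broken toward the
earliest sample; both windows are configurable (the source literature
fixes neither). Subject-level scalars average amplitude/latency over fixed
electrode sets (N1: C3, C4, CZ; MMN: FZ, FC1, C3 — the electrodes where
the group effects concentrate). An optional wavelet-shrinkage step
(Daubechies-4, 4 levels, soft universal threshold per epoch/channel with a
MAD noise estimate) can stabilize single-trial waveforms; it is not
applied in the exactness tests, which require bit-exact template recovery.

Task-state SC/NI (ESC, ENI) reuse the resting machinery with 1-second
segments anchored at stimulus onsets, so each segment spans one SOA;
material before the first and after the last stimulus is discarded.

## Preprocessing

Resample (polyphase, anti-aliased, events remapped by the rate ratio) →
common average reference → zero-phase 4th-order Butterworth band-pass
(0.1–45 Hz rest, 1–30 Hz task) → optional decomposition into Delta 1–4,
Theta 4–8, Alpha 8–13, Beta 13–30, Gamma 30–45 Hz. Manual artifact steps
of clinical practice (ICA, visual bad-segment marking) are deliberately
replaced by the deterministic 75 μV criterion: only reproducible
computation is implemented. Rejection is global across channels (the
criterion is ambiguous between global and per-channel; global is the
stricter reading).

## Feature selection (MFFS) and classification

Subset selection over the 16 assembled features (whole-brain SC and NI in
five bands from rest; N1/MMN amplitude and latency, ESC, ENI from the
task) uses a two-population evolutionary wrapper:

* **Form A** — bi-objective (CV error, selected-feature fraction),
  survival by Chebyshev decomposition: `subpop_size` evenly spread weight
  vectors λ each keep the union member minimizing
  `max_i λ_i·|f_i − z*_i|`, `z*` the ideal point.
* **Form B** — single objective: the fixed-weight Chebyshev scalarization
  `max(0.9·error, 0.1·fraction)`, survival by truncation.

Knowledge transfers implicitly (one crossover parent drawn from the
partner population with probability 0.2) and explicitly (every 5
generations the top-5 of each population replace the worst of the other).
Offspring come from binary tournaments, uniform crossover (p = 0.9) and
per-bit mutation (p = 1/length). Fitness is the stratified k-fold CV error
of an RBF-SVM (C = 1, γ = scale) on the selected columns, with
standardization fitted on training folds only; folds are fixed once per
run from the seed, so fitness is deterministic and cached per bitstring.
The empty subset scores error 1 by convention. Both populations are seeded
with the all-features chromosome, so the returned subset can never score
below the full set on the shared folds. The answer is the minimum-error
member of the first Pareto front of the merged final populations, ties
broken toward fewer features, then the lexicographically smaller
bitstring. Reference settings follow the study design (two subpopulations
of 100, 100 iterations, 5-fold CV); tests and the pipeline use scaled
budgets (subpopulations of 20, 20–30 iterations), which saturate the small
search spaces involved.

Evaluation pools fold predictions into one confusion matrix; MCS is the
positive class (recall = MCS sensitivity, specificity = UWS true-negative
rate); AUC is trapezoidal over pooled decision values. Group statistics
use Welch two-sample t-tests per feature/channel with Benjamini–Hochberg
FDR correction at α = 0.05.

## The synthetic cohort generator

No patient data ships with the package; a seeded generator produces
cohorts with the statistical structure the method assumes, plus a complete
ground-truth log for recovery tests.

* **Background**: per canonical band, one shared and one per-channel
  private source of unit-RMS band-limited Gaussian noise (FFT spectral
  shaping with raised-cosine edges), mixed as
  `synchrony·shared + (1−synchrony)·private`, scaled by per-band
  amplitudes (defaults 4/3/2.5/1.5/0.8 μV Delta→Gamma, slow-dominated as
  in severe brain injury), plus Gaussian sensor noise (2 μV). Gaussian
  sources are a model requirement: the Gaussianity test that separates the
  two components presumes a symmetric background.
* **Transients**: in each T-second window of the analysis grid,
  independently with probability `transient_prob`, a burst is injected on
  all channels — an amplitude-modulated spike train (10 pulses/s, 25 ms
  Gaussian pulses) with Gamma-distributed (positively skewed) amplitudes,
  mean 25 μV, scaled per channel by a random Gamma gain topography
  (mean 1). The topography matters: a spatially uniform burst would be
  cancelled exactly by the common average reference. Aligning bursts to
  the segmentation grid makes the injected proportion the exact ground
  truth for NI.
* **ERPs**: every stimulus adds a negative Gaussian-windowed N1 template
  (default widths 18 ms) with a C3/CZ-peaked gain topography; deviants add
  an MMN template (28 ms) with an FZ/FC1-peaked topography. Gains derive
  from approximate 10/20 electrode positions and are logged with the
  recording, so noiseless runs recover templates bit-exactly.
* **Task synchrony boost** (default +0.25): during the oddball run the
  shared-source mixing is raised, modelling stimulus-driven recruitment of
  shared networks. This is what makes task-state SC exceed resting SC: a
  template added identically to every stimulus-locked segment cancels
  exactly in the pairwise entropy differences, so evoked waveforms alone
  cannot change ESC.
* **Group defaults**: MCS — synchrony 0.7, transient probability 0.30,
  N1 −6 μV @ 100 ms, MMN −5 μV @ 180 ms; UWS — 0.3, 0.15, −3 μV @ 130 ms,
  −2.5 μV @ 150 ms; 61/96 subjects. The directions (higher synchrony and
  transient rate, larger/faster N1, larger/later MMN in MCS) follow the
  reported group contrasts; the magnitudes are chosen for testability —
  the source study reports no quantitative effect sizes, so these are
  deliberately large, well-separated effects, and accuracies near 1 on
  synthetic cohorts say nothing about clinical performance.

What the generator does **not** emulate: volume conduction / realistic
forward models, ocular and muscle artifacts, non-stationary band power,
skull-defect noise, inter-subject anatomical variability. Passing tests
demonstrate the estimators recover what the model injects — not that the
markers separate real patient groups.

## Problem sizes

Desk-scale defaults keep the full evaluation tractable on one CPU: the
end-to-end pipeline uses 30 subjects per group, 36 s of rest (18 two-second
segments), 54-stimulus oddball runs (46 STD / 8 DEV), 30 channels at
500 Hz; recovery and ordering measurements use 3–8-channel montages. The
generator's own defaults retain the full study design (10-min rest,
900-stimulus runs) for users who want full-scale recordings. The
quadratic-in-N entropy kernel is the dominant cost and is implemented as a
compiled symmetric pairwise loop.

## Known limitations

* Per-band NI is insensitive at the defaults: zero-phase band-pass
  filtering symmetrizes the burst waveform, so the skewness test loses its
  signal inside narrow bands and per-band NI sits near the 10 % grid
  floor. NI carries its information in the full band — consistent with NI
  being the weaker marker in the source study.
* `C[n,j]` scales with `N`; the package never compares SC across different
  segment counts, and neither should users.
* The ρ grid's lower bound floors detectable NI at ~0.10; channels with
  truly no transient activity are reported at the floor, not at zero.
* MFFS is a stochastic search; on deceptive landscapes (isolated optima
  whose neighbors are all worse) small budgets can return a near-optimal
  subset one fold-accuracy step above the exhaustive optimum.
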