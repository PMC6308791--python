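# Methods

## Problem setting

`biokey` implements identity verification from wearable biosignals.  A
session is either (a) a pair of simultaneously sampled series — single-lead
ECG and blood-oxygen saturation (SpO2) — or (b) a J-lead ECG recording.  An
individual is enrolled from one session and verified (or identified) from
another; the question each method answers is "how similar are two sessions?",
reduced to a scalar distance and a decision threshold.

## QSMI: quantized sparse co-occurrence matrices

For a session with paired samples (e(t_k), b(t_k)), both channels are binned
to integer indices 1..n by affine min–max scaling with round-half-up and
clamping, and each sample pair increments cell (idx_e, idx_b) of an n×n
counting matrix M.  The matrix total therefore always equals the number of
sample pairs.

The published mapping indexes M directly by the sample values and leaves the
amplitude-to-index rule open.  We scale per record by default; the enrollment
pipeline instead stores each template's training-session ranges and maps
probes with the *template's* ranges, so a probe is always binned on the same
grid as the template it is compared with.

M is then reduced: it is tiled into non-overlapping m×m windows (ragged
edges zero-padded), each window sum (plus the sum of an optional m×m additive
bias mask, zero by default) is mapped to a quantization level —

    level = 0 if s <= a,  1 if s <= c,  2 if s <= d,  3 otherwise

for four levels, or 0/1/2 with thresholds a, c for three.  The published
rule leaves the interval (a, b] unassigned; we tie b := a so the levels
partition the line.  The reduced matrix is stored in coordinate (COO) form —
1-based (row, col, value) triples in column-major order — and two sessions
are scored by the Pearson correlation of their reduced matrices flattened
over the full dense grid (correlation over the triple lists alone is
undefined when supports differ).  A zero-variance matrix scores 0 with a
warning.

Defaults: n = 32, m = 2, three levels with a = 0, c = 2.  Three-level
quantization is the reported best configuration; its thresholds were never
published, so a = 0 is chosen to make level 0 exactly "empty window" and
c = 2 to separate singly- from multiply-occupied windows.

## MDI: multi-dimensional sparse elements + DTW

Each sample of a J-lead session maps to a point in the integer space
[1, u]^J by d = round(s / R + Δθ), clamped at both ends.  Occupied
coordinates are summarized as sparse elements ((d_1..d_J), v) with occupancy
count v; a window reduction coarsens every axis by factor m
(tile = ceil(d / m)), summing merged occupancies.  Two sessions are compared
by DTW over their sparse-element sequences with local cost = squared
Euclidean distance over the coordinates plus the occupancy as an extra
unweighted component (a coordinates-only cost is flag-selectable):
equal-length sequences are scored by the direct position-wise sum, unequal
lengths by the recurrence D(i,j) = cost(i,j) + min(D(i−1,j), D(i,j−1),
D(i−1,j−1)).  The DP kernel is numba-jitted with a pure-Python fallback.

Sparse elements carry no inherent order, so the "sequence" is a canonical
serialization: lexicographic by coordinate (default) or by time of first
occupancy.  DTW over an unordered set is ill-defined; fixing the order makes
the distance deterministic.  A consequence of the equal-length direct rule is
that two similar sessions whose element counts happen to coincide can score
a large distance (their sorted lists shift by one position); this shows up as
occasional heavy-tailed genuine distances and is faithful to the published
rule rather than a defect of the implementation.

Defaults: u = 32, m = 2, Δθ = 20, J = 5 (the best-reported configuration,
"Num_32_Red_2" at five leads).  The reduction level R was never published;
R = 0.1 is chosen so that millivolt-scale ECG amplitudes (≈ ±1 mV) span a
useful band of the u = 32 grid around the Δθ = 20 offset.

## Comparison algorithms

* **RBP** — y_i = 1 iff x_{i+1} ≥ x_i; overlapping m-bit words (default
  m = 4, the experiment's word length was not published); dissimilarity
  D_m = (1/(2^m−1)) Σ|R1−R2| p1 p2 / Σ p1 p2 over shared words, 1 on
  disjoint supports.  Ranks are always computed, ties broken by ascending
  word value.
* **Waveform** — R peaks from an adaptive-threshold peak search on a
  0.5–40 Hz zero-phase Butterworth band-pass (this baseline's only
  pre-processing); Q/S as nearest minima within ±0.10 R-R of R, P/T as
  maxima in the pre-Q ([R−0.30 RR, Q)) and post-S ((S, R+0.45 RR]) windows;
  19 features (10 absolute amplitude differences, 5 durations, 3 slopes,
  QRS triangle area by the shoelace formula) averaged over beats; sessions
  scored by Euclidean distance of feature vectors.
* **Wavelet** — R-R cycles resampled to 284 points; the first 85 and last
  43 points form a 128-point segment; groups of four segments are
  transformed (Daubechies-4, level 3 by default — family and block choice
  were not published) and the four approximation blocks concatenated; group
  vectors averaged; Euclidean scoring.
* **Sparse baseline** — b = ΣΣ (SM1 − SM2)² over the dense grid, as
  printed (sum of squares); a square-root variant is flag-selectable.
  Sessions are scored by b directly (the published "correlation coefficient
  between two b's" is undefined for scalars).
* **PCA** — sessions as concatenated ECG-then-SpO2 vectors; variables
  centered, C = (1/n)XXᵀ eigendecomposed, top-k (default k = 5)
  eigenvectors projecting; Euclidean scoring in the projected space.

All methods satisfy one `fit(train) / score(probe, id)` contract with
distance polarity, so a single evaluation harness serves every method.

## Evaluation protocol

Every probe session is scored against every enrolled template (all-vs-all).
FA = accepted impostor trials / impostor trials; FR = rejected genuine
trials / genuine trials; Acc = 1 − (FA+FR)/2 identically.  The operating
threshold δ minimizes (FA+FR)/2 over a candidate grid, smallest δ on ties.
The classical grid 0.001..0.030 (step 0.001) is the sweep's documented
default, coherent for distance scores of magnitude ≲ 0.03; the experiment
pipelines instead pass a data-driven grid (midpoints of adjacent distinct
observed scores plus flanking values), which represents every achievable
(FA, FR) trade-off regardless of the score scale.  QSMI correlations are
converted to distances 1 − r before thresholding so one sweep convention
serves all methods.

## Synthetic cohort generator

The generator emulates only the statistical structure the classifiers
assume, not clinical realism:

* **ECG** — five Gaussian bumps (P, Q, R, S, T) per cardiac cycle with
  per-individual amplitudes, widths and timing offsets drawn once from a
  continuous prior (so two individuals almost surely differ), repeated
  quasi-periodically at the individual's heart rate (0.9–1.5 Hz prior) with
  white session noise (default sd 0.05 of the ≈1 mV R amplitude).  Distinct
  bumps are required so the fiducial baseline has detectable landmarks.
* **SpO2** — a per-individual mean (94–99 %) plus a slow bounded
  mean-reverting walk (stationary sd 0.3 %, ≈10 s reversion time), clipped
  to 85–100 %.  The published system characterizes its blood-oxygen channel
  no further than "sampled at the same times", so this is the package's own
  minimal model.
* **Multi-lead** — one base morphology per individual scaled per lead
  (gains drawn from [0.5, 1.5]) with independent per-lead noise.

Defaults: 18 individuals × 2 sessions (one enrollment, one probe), 30 s at
100 Hz — the 18×2 design mirrors the original verification study; its
sampling rate and session length were never published, so 100 Hz / 30 s are
package defaults, not inferred facts.  One master seed; per-individual and
per-session sub-seeds derived by fixed integer arithmetic, so cohorts are
reproducible and individual i's data is unchanged when the cohort grows.

What the generator does **not** model: baseline wander, electrode artifacts,
arrhythmia, heart-rate variability within a session, respiratory coupling
between channels, or any ECG–SpO2 dependence beyond shared timing.  Passing
tests therefore demonstrate the algorithms' internal consistency and their
discriminative behavior under the assumed structure — not field accuracy on
real recordings.

## Numerical choices and degenerate inputs

* Binning and the Eq-style reduction both round half up and clamp.
* Constant series (zero amplitude range) bin everything to index 1 with a
  logged warning instead of failing.
* DTW refuses empty sequences and mismatched J or u.
* Distance ties in identification keep the first-enrolled template (logged).
* PCA eigenvector signs are fixed so the largest-magnitude loading is
  positive.
* Threshold sweeps are permutation-invariant and deterministic.

## Problem sizes

The shipped experiments use 18×2 paired cohorts (30 s, 100 Hz) for QSMI and
10-individual × 2-session five-lead cohorts (30 s, 100 Hz, five seeds) for
MDI — the sizes at which the package's distributional claims (genuine vs
impostor separation, self- vs cross-match distances) are stable across
seeds.

## Known limitations

* The amplitude-to-index rule, MDI's R, the RBP word length, the wavelet
  family and the quantization thresholds are all unpublished details of the
  original system; the defaults here are documented decisions, not
  reconstructions.
* MDI's equal-length direct-comparison rule (above) makes a small fraction
  of distances heavy-tailed.
* The waveform baseline's fiducial windows assume a single dominant R peak
  per cycle; heavily distorted morphologies fall back to fewer (or zero)
  usable beats.
* No ROC/EER analysis beyond the (FA+FR)/2 criterion, and no statistical
  significance testing.
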