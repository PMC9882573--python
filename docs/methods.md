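# Methods

This note documents the models, estimators and numerical choices behind
`gpecg`, what the synthetic data generator does and does not emulate, and
the known limitations.

## Measurement model and phase-domain statistics

A record is assumed baseline-wander- and powerline-free (the preprocessing
module exists to make that true); each beat is clean ECG plus additive white
Gaussian noise of variance `v_n`.  Beats are delimited at the midpoints
between successive R-peaks (floor tie-break on even gaps, a fixed
convention), so the beats partition the record and per-beat outputs
concatenate back to the input length exactly.

Each beat of length `N` is warped to a fixed phase length `𝒯 ≥ N` by a
binary matrix with one 1 per phase row: knot `k` (0-based) replicates
sample `⌊k(N−1)/(𝒯−1)⌋`.  The printed index range of the defining rule
leaves the final knot without a sample; we close it onto the last sample —
otherwise one Gramian count would be zero and the back-transformation would
not exist.  Rows are phase indices and columns time indices, the only
orientation consistent with `ξ = Θx` and `diag(ΘΘᵀ) = 1`.  The Gramian
`ΘᵀΘ = diag(g)` counts knots per sample; the back-map `Ψ = G⁻¹Θᵀ`
scatter-averages, making time→phase→time exact (bit-exact for
integer-valued beats, one rounding ulp otherwise).

Two alignment modes exist.  `single` applies the rule to the whole beat.
`r_aligned` (default) applies it independently to the pre-R and post-R
segments so every beat's R-peak lands on one common phase knot, chosen as
the median relative R position, clamped to feasibility; this matches the
requirement that phase-domain beats have aligned R-peaks, which the
single-segment rule alone does not guarantee.  The default phase length is
`⌈1.1·(max pre-R span + max post-R span)⌉` — at least the longest beat,
with headroom so that a common R knot is always feasible and slightly
longer unseen beats do not violate the `𝒯 ≥ N` precondition.

Phase statistics are the sample mean and sample covariance of the warped
beats with `1/B` normalisation (the printed estimator; `ddof=1` is a flag).
Per-lead models are fitted independently; the leads of a record share only
the segmentation.  Partial first/last beats join the ensemble like any
other beat (an `exclude_edge_beats` flag drops them from the fit).

## The two filter paths

The **diagonal** path keeps the phase variance vector and filters each beat
with element-wise operations; the gain `k_s ⊘ k_x` lies in `[0, 1]`, so the
posterior is a per-sample convex combination of measurement and template.
It is computed in the convex-combination form `g·x + (1−g)·μ`, which is
exact at both limits (`v_n = 0` returns the measurement bit-for-bit,
`v_n ≥ max k̄` returns the template).  Negative signal variances — possible
when the noise variance is overestimated — are clamped at zero, keeping the
gain in `[0, 1]`; samples with zero measurement variance get gain 0 (the
template passes through; the only value consistent with the clamped limit).
The per-sample posterior variance `k_s(1 − k_s/k_x)` follows from standard
Gaussian conditioning and is exposed as the filter's confidence.

The **full** path carries the complete phase covariance, back-maps it
through `Ψ`, and solves the per-beat linear system by Cholesky
factorisation — never inverting explicitly.  Because the ensemble
covariance is typically very ill-conditioned, a ridge jitter of
`1e−10·trace/N`, doubled up to six times, is added when the condition
number exceeds `1e12` (logged); a beat that stays singular raises.  The
full path serves as the reference implementation and test oracle; the
diagonal path is the production filter.

One genuine discrepancy between the two printed forms is worth recording:
the full form's noise term `v_n ΘΘᵀ` back-maps to `v_n I` in time, while
the diagonal model's `k_η = v_n 1_𝒯` back-maps to `v_n / g` — for
replicated knots (`g > 1`) the diagonal model treats the replicas as
independent noise draws although they are copies of one sample.  The two
paths therefore coincide exactly only for identity maps (`N = 𝒯`) or
`v_n = 0`, and the tests compare them in those regimes.  In practice
`𝒯 ≈ 1.1·N`, so at most ~10% of knots are replicated and the difference is
second-order.

## Noise-variance estimation

`v̂_n` is estimated from the PQ segment (default window 60–20 ms before
each R-peak), where the heart is electrically silent.  The literal
per-window variance is biased upward by deterministic content reaching into
the window — the Q-wave onset, and after baseline filtering a smeared copy
of neighbouring-beat energy.  Since that content repeats every beat, the
estimator first subtracts the across-beat mean window profile with a
per-beat fitted scale (absorbing beat-to-beat amplitude variation), then
removes a per-window linear trend, and averages the unbiased residual
variances (`n−3` degrees of freedom, times `b/(b−1)` for the template
subtraction).  On the synthetic ladder this tracks the injected variance
within ~10–20% from −5 to 30 dB.  An `oracle` mode accepts a known variance
for simulation studies.  The estimate is global per record and lead; the
model does not attempt per-beat noise levels.

## R-peak detection

A Pan–Tompkins-style cascade: zero-phase bandpass (8–25 Hz), tanh
saturation, square-root moving average of the squared signal (100 ms), an
adaptive threshold at 0.7× the rolling 98th percentile of the envelope
(2 s window) with a floor at 10% of the global maximum, a 300 ms refractory
rule, and two-stage refinement of each candidate to the extremum of the
bandpassed and then the raw signal.  The saturation scale is
`8·median(|y|)` floored at half the 99.5th percentile: on low-noise records
the unfloored median tracks the quiet baseline and would clamp the QRS
itself down to T-wave amplitude, producing T-wave double-detections.  On
default synthetic records the detector finds every beat with no extras from
0 dB upward and degrades gracefully at −5 dB.  External annotations can
bypass detection entirely.

## Benchmark wavelet denoiser

Symlet-5, four decomposition levels, symmetric extension, soft
thresholding with the per-level SURE-minimising threshold on
sigma-normalised coefficients, sigma estimated once from the finest detail
level (`median|d1|/0.6745`).  A per-level sigma and a heuristic
SURE/universal fallback for sparse levels are flags; the defaults follow
the standard single-estimate SURE recipe.

## QT estimation and the evaluation harness

The QT estimator is deliberately simple plumbing for *relative*
comparisons: QRS onset is where the derivative magnitude falls below 10% of
its in-window maximum scanning back from the R-peak (80 ms window,
sub-sample interpolation); T-wave offset is the tangent method — steepest
tangent on the T wave's trailing limb intersected with the PQ-estimated
isoelectric level.  Signal and derivative come from a Savitzky–Golay fit
(30 ms window, order 2): a slope read from single-sample differences is
systematically steepened by noise, which biases QT short on noisy inputs
and, in comparisons, rewards any filter that smooths.  On clean default
synthetic records the estimator lands within ±4 ms of the analytic truth;
note the tangent method's geometry alone already differs from a 3-sigma
"true end" by one Gaussian T-width, so agreement at that level depends on
the smoothing compensating the tangent's early crossing — which is why the
harness always differences two estimates (filtered minus clean, same
segmentation, computed on the clean record) so estimator bias cancels.

The experiment grid contaminates clean records at −5…30 dB (5 dB steps,
default 5 repetitions), derives every noise seed deterministically from one
master seed via `SeedSequence` spawn keys (so methods see identical noise —
paired comparisons — and the whole grid is bit-reproducible), detects
R-peaks on the noisy record, runs all methods, and scores per-lead SNR
improvement (`10·log10` of residual-power ratio versus the known clean
signal, epsilon-floored) and per-beat QT error.  Synthetic records are
generated baseline-free, so the benchmark grid is run with the
baseline-removal stage disabled: the first-order 5 Hz stage would smear
QRS energy into the PQ segments in an RR-dependent way, inflating `v̂_n`
several-fold at high SNR while removing nothing that the synthetic data
contains.  For real records the stage is on by default.

## Synthetic generator

Each beat is a sum of five Gaussian bumps in a per-beat linear phase with
the R-peak at phase zero; waves before/after the R-peak scale with the
preceding/following RR interval, so the midpoint-segmented, R-aligned
warping places each wave at a fixed phase fraction — the generator
satisfies the filter's alignment assumption exactly, by construction.
Defaults (amplitudes 0.15/−0.10/1.00/−0.25/0.35 mV, centers
−1.00/−0.12/0/0.15/2.00 rad, widths 0.15/0.03/0.09/0.04/0.11 rad, mean RR
0.8 s, RR jitter 40 ms, 5% amplitude jitter, 250 Hz) resemble a lead-II
morphology at 75 bpm with a ~320 ms QT.  R-peak times are snapped to the
sample grid so the R sample is the exact beat maximum.  RR intervals are
i.i.d. truncated normal (redrawn on non-positive values, at most 100
times); noise is rescaled to the drawn vector's realized power so the
requested SNR holds exactly, and the realized variance is returned as an
oracle for estimator tests.  QRS onset and T offset are defined at the
3-sigma points of the Q and T bumps, converted through the adjacent RR
interval.

What the generator does **not** emulate: 12-lead geometry, ectopic beats or
morphology regime changes, colored/muscle-artifact noise, respiratory
modulation, or measurement quantisation.  Tests passing on this data show
the filter behaves as designed when its assumptions hold; they do not show
robustness to multi-morphology records (the single-Gaussian-process
assumption is the method's main modelling limitation) or to colored
in-band noise.

## Known limitations

- The posterior leaves a small systematic footprint on waveform-derived
  intervals: blending a beat with the integer-warped template (whose T limb
  is smeared by the ±0.5-sample segment-length quantisation) shifts the
  measured QT by about −0.2 ms (1/20 of a sample at 250 Hz) even with an
  oracle noise variance.  Below ~15 dB this is negligible against the
  benchmark's multi-millisecond distortions; above ~20 dB, where a
  SURE-thresholded wavelet approaches the identity, the wavelet's QT
  distortion can be smaller than the posterior's.
- The noise-variance estimate is global; records whose noise level drifts
  within the record are mis-modelled.
- Detection failures at very low SNR (< 0 dB) merge beats; the filter then
  treats merged beats as long beats, which dilutes the template rather than
  breaking the pipeline.
- Problem sizes used in the shipped tests and benchmark scripts (30–90 s
  records, 2 repetitions per level) are chosen to exercise every code path
  with stable statistics at interactive runtimes; the harness scales to
  longer grids unchanged.
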