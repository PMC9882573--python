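# gpecg — data-driven Gaussian-process ECG denoising in the beat phase domain

ECG denoising with Gaussian-process (GP) models usually demands two awkward
choices: a kernel family with hand-tuned hyperparameters, and the inversion
of covariance matrices that grow with record length.  `gpecg` implements a
data-driven alternative that sidesteps both.  Every heartbeat is warped onto
a common *phase axis* — a fixed number of samples 𝒯 with the R-peaks aligned
— so the beats of a record become an ensemble of draws from one process.
The process's mean and covariance are then simply the phase-domain **sample**
mean and covariance; no kernel is chosen, and in the diagonal form the
filter needs no matrix inversion at all, so records of arbitrary length are
cheap to process.

## The model

A measured beat is clean ECG plus white noise, `x_i = s_i + n_i` with
`n ~ N(0, v_n)`.  The binary warping matrix `Θ_i ∈ {0,1}^{𝒯×N_i}` places 𝒯
equidistant knots over the beat (`ξ_i = Θ_i x_i`), its Gramian
`G_i = Θ_iᵀΘ_i = diag(g_i)` counts knots per sample, and
`Ψ_i = G_i⁻¹Θ_iᵀ` warps back by scatter-averaging, so time→phase→time is
lossless.  With the phase beats modelled as `ξ_i ~ N(μ_ξ, K_ξ)` and the
moments estimated by the ensemble sample statistics, the denoised beat is
the Gaussian posterior mean

    ŝ_i = μ_s_i + K_s_i K_x_i⁻¹ (x_i − μ_s_i),

whose diagonal form is the per-sample convex blend
`ŝ = μ_s + (k_s ⊘ k_x) ∘ (x − μ_s)` with
`μ_s = (Θᵀμ̄_ξ) ⊘ g`, `k_x = (Θᵀk̄_ξ) ⊘ g²` and
`k_s = (Θᵀ(k̄_ξ − v̂_n·1)) ⊘ g²` (clamped at zero).  The noise variance `v̂_n`
is estimated from the isoelectric PQ segment before each R-peak, where the
heart is electrically silent.  Both the back-warped template (`prior`) and
the posterior mean (`posterior`) are returned, along with the per-sample
posterior variance — the filter's own confidence band.

The package also provides the supporting cast: a synthetic ECG generator
with analytic ground truth (sum-of-Gaussians P/Q/R/S/T morphology, RR and
amplitude variability, exactly power-matched noise), zero-phase
baseline-wander removal, a Pan–Tompkins-style R-peak detector with midpoint
beat segmentation, the standard Symlet-5 / soft / SURE wavelet denoiser as
a benchmark, and an evaluation harness measuring SNR improvement and
QT-interval distortion over a reproducible noise ladder.

## Worked example

```sh
python examples/simulate_and_denoise.py
```

```
37 beats, injected noise variance 0.008651 mV^2
detected 37 R-peaks
estimated noise variance 0.0102 mV^2 (phase length 314, R-peak knot 140)
SNR improvement, prior (template)  :   7.31 dB
SNR improvement, posterior         :   9.95 dB
SNR improvement, wavelet benchmark :   6.62 dB
posterior sd: up to 0.091 mV around the QRS, ~0.00 uV in isoelectric segments
```

A 30 s synthetic record is contaminated at 5 dB; the detector finds all 37
beats; the PQ-segment estimator recovers the injected noise variance within
~18%.  The posterior gains ~10 dB — more than the pure template (which
ignores this beat's measurement) and more than the wavelet benchmark.  The
posterior standard deviation concentrates where beats genuinely differ (the
QRS) and vanishes in the electrically silent segments.

Other examples: `phase_domain_warping.py` (the lossless warp),
`noise_ladder_benchmark.py` (the SNR/QT benchmark grid),
`qt_preservation.py` (clinical-parameter distortion).

## Command line

```sh
gpecg simulate --duration 30 --snr 5 --seed 1 --out rec.csv
gpecg filter rec.csv --out-prefix out         # prior/posterior/variance CSVs
gpecg benchmark rec.csv --levels -5..30:5 --reps 5 --seed 7
gpecg inspect out.model.json
```

Records are CSV (one column per lead, sampling frequency embedded in the
header); ground truth, model state and results are JSON/CSV sidecars.

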