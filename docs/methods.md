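# Methods

## Signal model

The analysis treats the 40 Hz auditory steady-state response as a
narrowband oscillation riding on broadband background activity:

    R(t) = A(t) cos(2π f t + φ(t)) + N(t),      f = 40 Hz

where `A(t)` is a slowly varying envelope, `φ(t)` a slowly varying phase,
and `N(t)` everything else.  All stages follow from this decomposition: the
RESS spatial filter concentrates the oscillation into one channel, complex
demodulation estimates `A(t)` and `φ(t)`, and the MCGF summarizes their
trial-averaged time courses in five interpretable parameters.

## Preprocessing

Filters are Chebyshev type-II IIR designs realized as cascaded second-order
sections and applied forward-backward (zero phase), so response latencies
are not biased by group delay.  The `order` argument is the overall filter
order (for bandpass/bandstop the underlying prototype has half that order,
matching the usual convention in which an "order 18 bandpass" has 18
poles).  Stopband attenuation defaults to 40 dB; it is the one free
parameter of the stated designs and is configurable.

Epoch windows are half-open `[start, stop)` with the onset sample at
`round(t0 · fs)`, which makes every epoch exactly `round((stop−start)·fs)`
samples long.  The per-epoch, per-channel scalar mean over the
(−0.5, −0.25) s pre-stimulus window is subtracted; an event whose window
does not fit in the recording is dropped and counted.  Artifact removal by
trained classifiers (ICA/ICLabel-style) is outside the package's scope; a
hook accepts externally cleaned recordings and defaults to the identity.

Filtering happens on the continuous recording, before epoching, so epoch
edges carry no filter transients from the cut itself; the narrowband
demodulation filters applied later do produce settling transients at epoch
edges, discussed below.

## RESS

The signal covariance S averages per-trial channel covariances of the
epochs filtered by a spectral Gaussian at 40 Hz (FWHM 0.5 Hz, defined on
the amplitude spectrum: gain 1 at the center, 0.5 at ±FWHM/2); the
reference covariance R averages the covariances at 39 and 41 Hz (FWHM
1 Hz).  Covariances are computed over the 6 s stimulation window only,
per trial and then averaged — one filter per subject, estimated from all
trials jointly and applied to each trial.

The generalized eigenproblem `S V = R V Λ` is solved in its
symmetric-definite form after shrinkage regularization
`R ← (1−γ) R + γ · mean(diag R) · I` with γ = 0.01 by default; 0.5 Hz-wide
filtered data are close to rank one per trial, and the shrinkage guards the
solve without visibly moving the leading eigenvector.  Eigenvalues are
returned in descending order; eigenvectors are unit-norm with the
largest-magnitude element made positive (the sign of a generalized
eigenvector is arbitrary; fixing it makes runs reproducible).  Eigenvectors
of a non-symmetric product are not orthogonal and are not forced to be.

The component SNR is the power at the FFT bin nearest 40 Hz divided by the
mean power of flanking bins within ±2 Hz but outside ±0.5 Hz, on the
trial-averaged spectrum of the stimulation window.  Noise-free input makes
the denominator vanish; the ratio is then capped at 1e12 and flagged.

## Complex demodulation

Per trial: zero-phase bandpass → multiply by `e^{−j2πft}` (t relative to
stimulus onset) → zero-phase lowpass.  Then `2·|R̃|` estimates `A(t)` and
`arg R̃` estimates `φ(t)`.

Filter geometry required a design decision.  The stimulation band is
39.5–40.5 Hz and the envelope smoother a 2 Hz lowpass (order 6); the
bandpass (order 8) takes 39.5/40.5 Hz as its *passband corners*, with
stopband edges 3.5 Hz further out.  The envelope of the response is carried
by spectral sidebands at `f ± B` for envelope bandwidth B, so a bandpass
whose stopband hugs the stimulation band removes exactly the modulation the
method measures: with stopband edges at 39.5/40.5 Hz the effective passband
is ±0.15 Hz, the recovered envelope is distorted by ~75% of its peak, and
stimulus energy smears across the pre-stimulus baseline.  With the chosen
geometry the envelope of the study's synthetic signals is reproduced to
within 5% of its peak away from the epoch edges, and the 2 Hz lowpass — not
the bandpass — sets the envelope bandwidth, which is also what makes that
lowpass necessary at all.  The corollary is that a tone 1 Hz from the
carrier (inside the envelope band) is passed by design; rejection of
out-of-band tones begins beyond ±2 Hz, where the post-shift lowpass
attenuates them by ≥ 40 dB.

A narrowband zero-phase filter rings for roughly the reciprocal of its
bandwidth (~0.5 s here), so profile values within ~0.5 s of the epoch edges
are settling transients.  The MCGF fitting window (0, 5) s of a (−1, 6) s
epoch keeps 1 s of margin at the tail.

AM(t) is the trial mean of `2·|R̃|` minus its own mean over the epoching
baseline window (the only pre-stimulus window the protocol defines; the
subtraction happens after trial averaging, following the order of the
defining expression).  ITPC(t) is the resultant length of the unit phasors
`R̃/|R̃|` across trials, similarly baseline-subtracted.  Samples whose
modulus is below 1e−12 of the series maximum are excluded from the phasor
average (0/0 guard — only silent synthetic inputs are affected); a sample
with no valid trial is carried as NaN and excluded from fitting.  The
resultant mathematically cannot exceed 1, and floating-point normalization
overshoot is clamped to the bound.

Average ASSR band power integrates the per-epoch periodogram over
40 ± 0.5 Hz across the stimulation window and averages over epochs (a pure
sine of amplitude a gives a²/2).  Topographies evaluate the same quantity
per channel.  ERSP maps are trial-mean squared moduli of a short-time
Fourier transform (0.5 s Hann window, 90% overlap), optionally resampled to
a 224×224 grid for image-classifier export.

## MCGF

    MCGF(t) = A·d/(d+1) · e^{μα + σ²α²/2 − αt} · G(t; μ+σ²α, σ)
            + A/(d+1) · G(t; μ, σ)

with `G` the cumulative Gaussian.  The first term is an
exponential-times-shifted-CDF (the ex-Gaussian identity), giving a rise at
latency μ over scale σ followed by decay at rate α toward the sustained
asymptote A/(d+1).  The exponential grows without bound for t ≪ μ while G
vanishes; the product is evaluated in log space
(`exp(μα + σ²α²/2 − αt + log G)`) to avoid overflow.

Fitting is bounded nonlinear least squares (trust-region reflective) over
the window (0, 5) s with pre-onset samples treated as zero.  The
deterministic initialization is A₀ = max of the profile in the window,
μ₀ = first half-maximum crossing, σ₀ = 0.2 s, d₀ = 1, α₀ = 0.05 1/s;
bounds are A ∈ [0, 10·max], d ∈ [1e−3, 1e3], μ ∈ window, σ ∈ [1e−3, 5] s,
α ∈ [0, 5] 1/s, keeping the exponential finite.  The surface is multi-modal
in (d, α); if the first solve fails, up to five seeded jittered restarts
are tried and the `converged` flag reports the outcome honestly.  AM and
ITPC are fitted independently (their parameters are reported separately
downstream).

## Statistics

Responses are transformed before Gaussian identity-link fitting:
z-scored midlife IQ; reciprocal mean moves on 4-move planning problems
(larger = better); reflected log `log(max − solved)` for problems solved in
minimum moves (larger = worse), with `max = 12`.  A subject at the sample
maximum would hit log 0; a half-count offset (`log 0.5`) is used for those
subjects only — an explicit convention the transform requires, configurable.
Back-transforms `E[z(IQ)] = Xβ`, `E[moves] = 1/Xβ`, `E[solved] = 12 − e^{Xβ}`
are provided for interpretation.

The design has an intercept, shared decay and slope main effects (α, σ for
AM and ITPC), an indicator for the stable group (the declining group is the
reference absorbed into the intercept — a global intercept plus both
indicators would be rank deficient), and per group level the magnitude A,
latency μ, interaction A·μ (for AM and ITPC) and band power P: 20 columns.
Only A×μ interactions enter, reflecting the magnitude-latency focus of the
modeling.  The fit reports per-term estimate/SE/t/p, R², log-likelihood,
the overall F test against the intercept-only model and the equivalent
likelihood-ratio χ² (both are reported for every model since either may be
quoted), the design condition number, and names any collinear columns it
drops.

Two-sample comparisons use Student's t (equal variances) for
normally-distributed scores and the Wilcoxon rank-sum / Mann-Whitney test
otherwise, exact enumeration when min(n) ≤ 8 without ties; Bonferroni
thresholds are α/m with the family size m supplied by the caller (the
relevant family depends on which comparisons a study runs).  Topography
comparisons shuffle group labels channel-wise with the difference of group
means as statistic and the add-one permutation p-value
`(1 + #{|perm| ≥ |obs|}) / (1 + n_perm)` — exploratory maps, deliberately
without multiplicity correction.

## Synthetic data generator

Each trial carries `gain_c · A(t) cos(2π·40·t + φ_k)`: the envelope A(t) is
an MCGF restricted to the 6 s stimulation window, φ_k is a per-trial
wrapped-normal phase offset (its SD controls ITPC; only cross-trial
dispersion matters, making wrapped normal and von Mises interchangeable
here), `gain_c` is a phenomenological per-channel map built from template
electrode positions, and 1/f^β Gaussian noise (β = 1 by default, the
standard EEG background assumption) is added independently per channel with
SD = `noise_scale · A` (default 0.5).  The sampling rate defaults to 250 Hz
and must stay ≥ 100 Hz for Nyquist margin above the carrier.

Group presets encode the qualitative contrast the analysis targets:

* `highCog` (stable): focal temporal gains (Gaussian falloff, spread
  0.045 m, centered on T7/T8), envelope A = 1 µV, μ = 0.3 s, σ = 0.15 s,
  α = 0.1 1/s, phase jitter SD 0.5 rad.
* `lowCog` (declining): diffuse frontocentral gains (spread 0.10 m,
  centered on FCz — higher summed band power over the scalp), envelope
  A = 1.2 µV, μ = 0.6 s (a +0.3 s latency delay), phase jitter SD 0.8 rad.

Directions (more diffuse entrainment, delayed assembly, less stable phase
in the declining group) are the contrast of interest; the magnitudes are
free parameters of the simulator chosen to give realistic single-trial SNR,
not empirical claims.  Default cohort size is 12 per group — the smallest
round size that keeps the 20-column GLM design comfortably identified.

Cognition tables are generated by applying declared coefficient maps to the
design built from the ASSR features, adding Gaussian noise on the
transformed scale (per-response SDs, since the transformed scales differ by
an order of magnitude), and back-transforming.  SOC outcomes are rounded
and clipped to their native ranges (moves ≥ 4, problems solved an integer
in 0..12) because the instrument reports integers and means of integers;
exact-recovery oracles disable rounding via `integer_outcomes=False`.
z-scoring renormalizes per cohort, so exact coefficient recovery holds for
the reciprocal and reflected-log responses, and up to an affine map for the
z-scored one.

What the generator does *not* emulate: volume conduction from dipolar
sources (gain maps are phenomenological, not forward-modeled), eye/muscle
artifacts, line-noise harmonics, non-stationary background, between-trial
envelope variability, and the auditory stimulus waveform itself (only the
40 Hz cortical component is modeled, not the 1 kHz carrier click train).
Passing tests therefore demonstrate correctness of the pipeline's
mathematics and its statistical calibration under the stated model — not
robustness to real-data artifacts.

## Problem sizes and determinism

Unit tests run on single subjects or constructed arrays; cohort-level
checks use 10–12 subjects per group with 10–40 trials each, sizes at which
every planted effect is comfortably detectable.  All randomness flows
through `numpy.random.default_rng` seeds carried in configs; identical
configuration and seed give bit-identical epochs, tables and permutation
p-values.  Pipeline runs cache per-subject results keyed by a hash of the
full configuration, so an interrupted cohort run resumes without
recomputation, and every output directory carries `provenance.json` with
the config hash, seed and package version.

## Known limitations

* The EDF writer emits 16-bit EDF with one-second records and
  integer sampling rates; round-trip accuracy is bounded by quantization at
  ~peak/32767 per channel.
* The demodulation bandpass cannot simultaneously pass the envelope band
  and reject tones within ±2 Hz of the carrier (time-bandwidth tradeoff
  discussed above); studies with interference near 40 Hz need a different
  carrier or notch strategy.
* MCGF parameters d and α are weakly identified when the decay is shallow;
  the fit is honest about convergence but confidence intervals are not
  provided.
* The GLM layer fits the full declared design; it performs no model
  selection or pruning.
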