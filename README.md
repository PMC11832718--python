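# assr-entrain

A tested, reusable pipeline for analyzing the **40 Hz auditory steady-state
response (ASSR)** in multichannel EEG, and for relating its entrainment
characteristics to cognitive and executive-function scores.  It is aimed at
neurophysiology groups studying gamma-band entrainment as a candidate marker
of cognitive decline: the same per-subject features (entrainment magnitude,
latency, phase stability, band power, scalp spread) that separate
cognitively stable from declining adults can be extracted from any 40 Hz
amplitude-modulated stimulation protocol.

Because clinical EEG cohorts are typically confidential, the package ships a
first-class synthetic-data module that generates seeded recordings with the
statistical structure the analysis assumes — so every stage is testable and
demonstrable without any data download.

## The analysis

1. **Preprocessing** — common-average re-referencing, downsampling to
   250 Hz, zero-phase Chebyshev type-II filtering (0.5–90 Hz bandpass of
   order 18; 50 Hz notch of order 8), epoching around stimulus onsets
   (−1 s to 6 s) and baseline correction over (−0.5, −0.25) s.
2. **RESS spatial filtering** — per-trial channel covariances of the epochs
   narrowband-filtered at the stimulation frequency (S) and at neighboring
   frequencies (R) enter a generalized eigendecomposition `S v = λ R v`;
   the leading eigenvector is a spatial filter that returns one maximally
   40 Hz "virtual channel" per subject.
3. **Complex demodulation** — modeling the component as
   `R(t) = A(t) cos(2πft + φ(t)) + N(t)`, a narrow bandpass, a frequency
   shift by `e^{−j2πft}` and a 2 Hz lowpass recover the envelope `A(t)` and
   phase `φ(t)`.  Trial-averaging yields the amplitude-modulation profile
   AM(t) and the inter-trial phase coherence ITPC(t) ∈ [0, 1] (resultant
   length of unit phasors across trials), each baseline-subtracted.
4. **MCGF fitting** — both profiles are summarized by the five-parameter
   modified cumulative Gaussian

   `MCGF(t) = A·d/(d+1) · e^{μα + σ²α²/2 − αt} · G(t; μ+σ²α, σ) + A/(d+1) · G(t; μ, σ)`

   where `G` is the cumulative Gaussian: `A` is the response magnitude,
   `μ` the latency (s), `σ` the slope of the rise (s) and `α` the decay
   rate (1/s).
5. **Statistics** — average 40 Hz band power and per-channel topographies
   with channel-wise permutation tests; two-sample t / Wilcoxon rank-sum
   tests with Bonferroni correction; and Gaussian GLMs on transformed
   responses (z-scored IQ, reciprocal planning moves, reflected-log
   problems-solved) with group-specific magnitude × latency interaction
   terms.

## Worked example

```python
import assr_entrain as ae
from assr_entrain.demod import complex_demodulate, modulation_profile

timeline = ae.make_session_timeline(n_trials=40, stim_dur=6, iti=5)
print(f"session: {timeline.n_trials} trials, {timeline.total_dur:.0f} s total")

cfg = ae.group_preset("highCog", seed=42)       # focal-temporal, mu = 0.3 s
epochs = ae.simulate_assr_epochs(cfg, timeline)
mixed = ae.select_channels(epochs, ae.REGIONS["mixed"])
result = ae.ress_analysis(mixed)
print(f"RESS: top eigenvalue {result.eigenvalues[0]:.1f}, 40 Hz SNR {result.snr:.0f}")

profile = modulation_profile(complex_demodulate(result.component))
fit = ae.fit_mcgf(profile, "am")
p = fit.params
print(f"AM MCGF: A={p.A:.2f}, mu={p.mu:.3f} s, sigma={p.sigma:.3f} s, "
      f"alpha={p.alpha:.3f} 1/s (R2={fit.r2:.3f})")
print(f"40 Hz band power: {ae.assr_bandpower(result.component):.2f} uV^2")
```

prints

```
session: 40 trials, 435 s total
RESS: top eigenvalue 94.5, 40 Hz SNR 966
AM MCGF: A=1.99, mu=0.308 s, sigma=0.162 s, alpha=0.117 1/s (R2=0.998)
40 Hz band power: 1.51 uV^2
```

The 40-trial schedule spans 435 s (7 min 15 s).  The top generalized
eigenvalue ≫ 1 says the spatial filter found a direction with ~95× more
power at 40 Hz than at neighboring frequencies.  The fitted latency
`mu = 0.308 s` recovers the 0.3 s envelope latency planted by the
stable-group preset; the fitted magnitude reflects the envelope scaled by
the spatial-filter gain.  A cohort-level run (`assr-entrain run-all`, or
`assr_entrain.pipeline.run_pipeline`) repeats this per subject for two
groups, simulates cognition scores from declared GLM relations, and fits
the three response models.

The same stages are available as CLI verbs on files:

```bash
assr-entrain simulate  --out sim --seed 2
assr-entrain preprocess --edf sim/highCog_2.edf --events sim/highCog_2_events.csv --out epochs
assr-entrain ress      --epochs epochs --region mixed --out ressout
assr-entrain demod     --component ressout/component --out profile.csv
assr-entrain fit-mcgf  --profile profile.csv --which am --out fit.json
```

## Documentation

`docs/methods.md` describes the signal model, the synthetic-data
generator's assumptions, parameter defaults with units, numerical choices
and known limitations.
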