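# envtrack

Neural envelope tracking of natural speech, packaged as a tested analysis
pipeline for clinical EEG research. `envtrack` takes a speech stimulus (or
its precomputed temporal envelope) and artefact-cleaned multichannel EEG,
and quantifies how strongly — and at which latencies — the brain tracks the
slow amplitude modulations of speech. Its target use case is group studies
and individual-level screening of post-stroke aphasia, where envelope
tracking in the delta, theta and gamma bands is reduced relative to healthy
ageing controls.

## What it computes

1. **Envelope extraction** — 28-channel gammatone filterbank (50–5000 Hz,
   1-ERB spacing), per-subband `|x|^0.6` compression, subband averaging,
   anti-alias resampling to 512 Hz.
2. **Band filtering** — least-squares linear-phase FIR filters per band
   (delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–49, broad
   0.5–49 Hz; ≤0.25 dB passband ripple, ≥10 dB stopband attenuation at the
   ±10% transition edges, zero-phase application), then z-scoring and
   downsampling to 128 Hz. EEG is common-average referenced and conditioned
   with the identical filters.
3. **TMIF** — the temporal mutual information function: Gaussian-copula MI

       I(X;Y) = 1/(2 ln 2) · ln( |Σ_X||Σ_Y| / |Σ_XY| )   [bits]

   between envelope and EEG at every lag in −200…500 ms, per channel
   (single-channel variant) or with all selected channels jointly
   (multivariate variant).
4. **Significance** — a per-subject null from 1000 spectrum-matched
   (phase-randomized) surrogate envelopes; significance level = 95th
   percentile of surrogate statistics.
5. **Group statistics** — temporal and spatio-temporal cluster-based
   permutation tests on the TMIFs (Welch-t bins, max-cluster-mass
   correction).
6. **Classification** — nested cross-validated RBF-SVM (leave-one-subject-
   out outside, 5-fold accuracy-based selection of C and TMIF pruning
   inside) on per-band multivariate TMIFs + age, with grouped Shapley
   feature attribution.
7. **Reliability** — recording-length analyses (performance and
   within/between-subject stability vs duration, Kneedle knee points) and
   split-half ICC(1,1) reliability with Fisher-z group comparisons.

A synthetic-data module generates two-group cohorts (envelope ⊛ two-peaked
response kernel at 50/170 ms, fronto-central topography, 1/f noise, second
peak attenuated in delta/theta/gamma for the "aphasia" group), so the whole
chain is testable without clinical recordings.

## Worked example

```python
import numpy as np
from envtrack import (CohortSpec, gen_cohort, band_envelope, condition_eeg,
                      select_channels, compute_tmif, mean_mi,
                      cluster_permutation_test)

spec = CohortSpec(n_control=8, n_aphasia=8, duration_min=3.0, n_channels=6,
                  seed=7)
cohort = gen_cohort(spec)
env = band_envelope(cohort.envelope, "theta", rate_in=512.0, band_name="theta")

tmifs = {"control": [], "aphasia": []}
for subject in cohort.subjects:
    eeg = select_channels(condition_eeg(subject.eeg, "theta", band_name="theta"),
                          ["Fp1", "C5", "PO3"])
    tmifs[subject.group].append(compute_tmif(eeg, env))

print(f"control mean MI : {np.mean([mean_mi(t) for t in tmifs['control']]):.4f} bits")
print(f"aphasia mean MI : {np.mean([mean_mi(t) for t in tmifs['aphasia']]):.4f} bits")
res = cluster_permutation_test(tmifs["control"], tmifs["aphasia"],
                               n_permutations=500, seed=1)
best = min(res.clusters, key=lambda c: c.p_value)
print(f"largest cluster : {best.lag_start_ms:.0f}-{best.lag_end_ms:.0f} ms, "
      f"p = {best.p_value:.3f}")
```

prints

```
control mean MI : 0.0149 bits
aphasia mean MI : 0.0035 bits
largest cluster : 234-305 ms, p = 0.006
```

— the patient group tracks the theta-band envelope less, and the group
difference clusters around the second response peak (~170 ms), where the
generator attenuated the patients' response.

There is also a CLI for shell pipelines (`envtrack simulate|envelope|tmif|
nulldist|groupstats|classify|reliability|run`); `envtrack run --out dir`
executes the whole chain on a synthetic cohort and renders a Markdown
report with TMIF, ROC, attribution and stability figures.

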