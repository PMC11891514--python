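# Methods

## Signal model and processing chain

The package assumes the standard continuous-speech EEG paradigm: a listener
hears a narrated story while EEG is recorded, and the analysis relates the
story's temporal envelope to the EEG. The envelope is extracted with a
28-channel gammatone filterbank, centre frequencies from 50 Hz upward in
one-ERB steps on the Glasberg–Moore scale (which lands the last channel
just under 5 kHz), per-subband magnitude compressed with exponent 0.6
(loudness-like), averaged over subbands, and anti-alias resampled to the
intermediate rate of 512 Hz. The gammatone stage uses scipy's 4th-order IIR
gammatone in second-order sections; the transfer-function form is
numerically unstable for the lowest centre frequencies at audio rates.

Envelope and EEG are then filtered into delta (0.5–4 Hz), theta (4–8),
alpha (8–12), beta (12–30), gamma (30–49) and broad (0.5–49) bands,
z-scored, and downsampled to the 128 Hz analysis rate. EEG is
common-average referenced before filtering (referencing and filtering are
both linear, so the order is immaterial; a regression test asserts this).
Because z-scoring precedes the final downsample, post-downsample moments
are only approximately (0, 1); they stay within 0.02 for in-band signals,
and a `restandardize` flag (default off) re-tightens them exactly.

### Band filters

Each band is a cascade of a linear-phase highpass and lowpass FIR. The
design criteria: transition bands extend 10% below the highpass and 10%
above the lowpass edge; passband ripple ≤ 0.25 dB; stopband attenuation
≥ 10 dB at the transition's outer edge — both verified from the measured
transfer function, never assumed. The design itself is the closed-form
least-squares solution under uniform spectral weighting for a desired
response with a raised-cosine transition: its impulse response is known
analytically (a sinc multiplied by a raised-cosine factor), so the filter
is the truncated inverse Fourier transform and costs O(order) time and
memory at any order. Orders start at 2000 for edges below 30 Hz and 500
otherwise and double until the measured bounds hold; the 0.5 Hz edge
settles at order 32000 (a 0.05 Hz transition simply needs ~60 s of impulse
response — shorter filters cannot satisfy both bounds, whatever the design
method), 4 Hz edges at 4000, all others at their starting order. Designs
are cached per (edge, rate). Filtering is zero-phase: symmetric taps,
group delay compensated, reflection padding of one filter order (the input
must be longer than the filter order; recording-time crops are therefore
taken at the analysis rate *after* filtering, which also keeps short crops
free of startup transients).

## Gaussian-copula TMIF

Each variable (the band envelope; each selected EEG channel) is ranked,
mapped to (0, 1) by r/(n+1), and transformed with the inverse
standard-normal CDF, giving exact standard-normal marginals. The mutual
information of the gaussianized variables is the closed-form Gaussian MI
on covariance determinants, in bits. The temporal MI function (TMIF)
evaluates this at every integer sample shift covering −200…500 ms
(outward-rounded to shifts −26…64 at 128 Hz); positive lags mean the EEG
follows the envelope, so the TMIF reads like an evoked response with peaks
near 50 and 170 ms. Two variants exist: single-channel (one MI trace per
channel; spatial information) and multivariate (all selected channels
jointly; statistically more sensitive, temporal information only).

Choices that were genuinely open:

* **Per-lag copula (default).** Ranks are recomputed on each lag-aligned
  overlap rather than once globally; a `per_lag=False` flag selects global
  gaussianization. The per-lag default follows from applying the estimator
  independently at each lag.
* **Plug-in estimator.** MI is the plug-in determinant formula with a tiny
  ridge (1e-12 of the mean diagonal) guarding near-singular joints. No
  small-sample bias correction is applied; all calibration is empirical
  (surrogates, permutations), which absorbs the bias.
* **Dimensionality guard.** The multivariate variant requires the overlap
  to exceed 10·(channels+1) samples.
* **Channel selection.** The multivariate analysis defaults to a named
  22-channel fronto-central + parieto-occipital set over the BioSemi-64
  cap (10-20 labels; A1…B32 aliases accepted, matching case-insensitive).
  The exact membership is a visible config value, not a constant in code.
  Note that a common-average-referenced recording loses one rank: never
  select *all* channels of a CAR'd montage for the multivariate TMIF.

The naive per-lag implementation (explicit re-rank + covariance per lag)
is kept as a reference path; the production path updates ranks
incrementally as the overlap shrinks by one sample per lag and reads
gaussianized values from per-length quantile tables (each column of a
gaussianized slice is a permutation of a fixed vector, so means and
variances are known constants and only cross-products are computed). The
two paths agree to 1e-10 in tests; the fast path is ~three orders of
magnitude faster, which is what makes the calibration simulations below
tractable.

Prior to visualization (and only there), TMIFs are smoothed along the lag
axis with a 9-tap Gaussian (SD 2 samples, unit sum, reflect padding). All
statistics run on unsmoothed TMIFs except peak-latency readouts, which use
the smoothed trace. Scalar summaries use the 0–400 ms integration window
(mean MI by default; peak MI available).

## Surrogate null

Per subject and band, 1000 surrogate envelopes are built by full phase
randomization: the Fourier amplitude spectrum is kept exactly, phases are
i.i.d. uniform, and the result is re-z-scored — stationary noise with the
envelope's band-specific spectrum. Each surrogate is scored against the
subject's real EEG with the same multivariate window statistic used
downstream (mean MI over 0–400 ms; configurable to peak MI). The
significance level is the nearest-rank 95th percentile; a pooled
(across-subjects) level is also provided. Because the real envelope is
scored by the identical code path, real and surrogate statistics are
exchangeable when the EEG carries no envelope response, so the false-
positive rate of "subject is significant" is ~5% by construction — the
test-suite verifies 200 no-response subjects land inside the binomial
interval.

## Cluster-based permutation tests

Group comparisons use the max-cluster-mass permutation framework: a Welch
t per lag bin (rank-sum z available), two-sided threshold at the t critical
value for the group sizes at α = 0.05, supra-threshold bins joined by lag
contiguity (plus channel adjacency for the single-channel variant —
Delaunay neighbours on the azimuthally projected montage), positive and
negative clusters tracked separately, and cluster mass = summed statistic.
Group labels are permuted preserving group sizes (default 1000 draws);
p = (1 + #{perm max ≥ |mass|})/(1 + n_perm). Pooled subjects are
canonicalized by content hash before permutation so p-values are invariant
to subject listing order.

## Classification

Features are the multivariate TMIFs of the five narrow bands, truncated to
nonnegative lags, concatenated, plus age (326 columns at full pruning).
The classifier is an RBF SVM with inverse-frequency class weights.
Evaluation is leave-one-subject-out; inside each fold a stratified 5-fold
CV selects (C, pruning length) jointly by accuracy over a 9-point
logarithmic C grid (1e-2…1e2) and pruning grid {100,…,500} ms, ties going
to the shortest prune and smallest C; per-column standardization is learned
on training subjects only (a leakage canary test asserts this). Metrics
(accuracy, F1, AUC, sensitivity, specificity, ROC) treat aphasia as the
positive class and come from the pooled held-out predictions.

Feature contribution uses Shapley values over feature *groups* (one per
band, plus age): the coalition value is the mean decision over a background
sample with out-of-coalition groups replaced by background rows. With six
groups the 64 coalitions are enumerated, so attributions are exact and
additivity (sum of contributions = decision − baseline) holds to machine
precision; a Monte-Carlo permutation estimator covers larger groupings.

## Reliability and recording length

Recordings are cropped to their first 1, 3, 5, … 25 minutes (at the
analysis rate, post-filtering) and the TMIF recomputed per duration.
Within-subject stability is the ICC between each cropped TMIF and the
full-recording TMIF over lag bins, averaged over subjects; between-subject
stability is the ICC across subjects between cropped-duration and
full-duration mean MI; classifier performance is recomputed per duration.
Knee points come from an in-package Kneedle implementation (concave
increasing curves, sensitivity 1, no smoothing or interpolation),
cross-checked in tests against an independently coded oracle. Split-half
reliability computes the mean MI of the first and second half of the
recording and an ICC across subjects per band and group.

Everywhere "intraclass correlation" appears, it is ICC(1,1) — one-way
random effects, single rater — for internal consistency; confidence
intervals and p-values come from the one-way ANOVA F ratio (verified
against pingouin). ICC p-value families are Holm-corrected (Bonferroni and
BH configurable); group ICCs are compared with a Fisher-z test using
variance 1/(n−3) per group.

## Synthetic cohorts

The generator exists so that every downstream stage can be tested against
known ground truth; it is deliberately the *minimal* model with that
property:

* **Stimulus.** A nonnegative "story" envelope from rectified filtered
  noise: a syllable-rate (2.5–5.5 Hz) band plus slower prosodic and faster
  components; modulation spectrum peaks in the 1–8 Hz range.
* **Response.** EEG = Σ_bands scale_b · (band-filtered envelope ⊛ kernel_b)
  projected onto channels by a raised-cosine fronto-central topography,
  plus 1/f Gaussian noise (exponent 1, 0.1 Hz spectral floor). The kernel
  has Gaussian peaks at 50 ms (width 15 ms, amplitude 0.5) and 170 ms
  (width 30 ms, amplitude 1.0) — the second peak dominant, consistent with
  the response morphology the analysis is designed to resolve.
* **Group effect.** For the "aphasia" group the second kernel peak is
  scaled by an attenuation factor per band (default 0.5 in delta, theta
  and gamma; alpha and beta identical across groups). With all factors at
  1 the two groups are generatively identical — the basis of the type-I
  calibration tests.
* **SNR.** Per-band SNR (dB), quoted at the topography peak for a
  unit-gain subject, calibrated against the analytic in-band power of the
  1/f noise. Defaults decrease with frequency (delta +2 … gamma −5 dB),
  emulating the lower SNR of high-frequency EEG; this is what makes
  split-half reliability higher in the low bands.
* **Subjects.** Ages ~ N(72, 10²) truncated to [40, 95]; a log-normal
  tracking-strength gain (log-SD 0.3) gives cohorts true between-subject
  variance, without which between-subject ICCs would be meaningless.
  Per-subject seeds derive from the cohort seed by counter.

What the generator does **not** emulate: artefacts (blinks, muscle, line
noise), nonstationarity, lesioned topographies, inter-channel noise
correlations, or any nonlinearity in the envelope response. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the linear-convolution model — not that effect sizes or absolute MI
values transfer to clinical recordings.

## Problem sizes in tests and the acceptance script

Calibration and power simulations run at reduced nuisance dimensions — 4–8
generated channels with 2–3 selected, recordings of 45 s–3 min, a reduced
C × prune grid for the repeated classifier fits — while keeping the
quantities that define each check (subject counts, surrogate/permutation
counts, cohort counts, group sizes, tolerance bands) at their stated
values. The acceptance script's study uses 12+12 subjects, 2.5-minute
recordings, 6 channels (3 selected), 200 surrogates and 500 cluster
permutations.

## Known limitations

* EDF/BDF input is read through MNE but the package writes only its own
  `.npz` container; round-trip tests cover the container.
* The multivariate TMIF is undefined for a full CAR'd montage (rank
  deficiency); select a strict channel subset.
* The surrogate null and the recording-time analyses assume stationarity;
  real EEG drifts.
* Kneedle on coarse grids (13 points) can only resolve knees to grid
  resolution, and a curve without curvature returns the last grid point
  with an explicit no-knee flag.
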