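# Methods

## The measurement model

A subject watches/hears a 3 Hz stream of four stimuli whose transition
probabilities switch between an ordered regime (forward transition 0.75,
repetition 0.25, nothing else) and a random regime (uniform 0.25) every 700
trials. The quantity of interest is a per-subject scalar capturing how
strongly the predictable context makes the subject pre-activate the
*expected* (forward) stimulus before it appears.

The estimator follows the classical decoding logic:

* A multiclass LDA is trained at every time sample, using **only ordered
  forward trials** (the trial and its predecessor non-omitted, outside the
  20-trial post-switch burn-in). Training on forward trials exposes the
  classifier to any prediction-related pattern preceding a foreseeable
  stimulus, in addition to the evoked response.
* It is tested on **self-repetition trials preceded by a forward
  transition** (t−2→t−1 forward, t−1→t repetition, t/t−1/t−2 non-omitted),
  in both entropy contexts. Repetitions occur with probability 0.25 in both
  regimes, and the matching (exact, stratified by stimulus identity, the
  larger condition randomly subselected) equates the bottom-up history at
  t−1 and t−2 across contexts. At 3 Hz adjacent epochs overlap, so the
  previous trial's evoked tail leaks into the prestimulus window by
  construction; the matching makes that leak common to both conditions.
* Per test trial and time sample the four decision values are re-labelled
  as transition evidence given the previous stimulus (d_c →
  forward/repetition/backward/other). The **tendency curve** is the mean
  forward-transition evidence, ordered − random, per time sample; the
  **tendency score** is its sum over prestimulus samples in [−0.3, 0) s.

The default curve statistic is the forward-transition decision value (the
contrast an ordered−random difference plot displays); a
`forward_minus_repetition` within-trial contrast is available behind the
`contrast` option for users who prefer an explicit two-transition contrast.
Training/test disjointness is structural (forward trials train, repetition
trials test) and additionally asserted at decode time.

## Synthetic data generator

Each stimulus projects to the sensors through a fixed unit-norm random
pattern (pairwise |r| ≤ 0.3 by rejection sampling) — a stand-in for the
sensor projection of a stimulus-specific source. A recording is a
superposition of:

* **Evoked responses** on non-omitted trials: amplitude 1.0 ×
  pattern(stimulus) × a Gaussian-windowed half-sine kernel supported on
  [0, 0.7] s, peak near 0.17 s — matching the observation that stimulus
  identity is decodable from roughly 0.1 to 0.7 s after onset.
* **Pre-activation** in ordered segments only: for every trial whose
  predecessor was s, the pattern of forward(s) rises along a linear ramp
  over [−0.3, 0) s, scaled by the subject's β. Omitted trials still carry
  the prediction (expectation needs no bottom-up input). The temporal shape
  of real pre-activation is unconstrained by sensor data; the ramp is a
  modelling choice and only its prestimulus support matters downstream.
* **Sensor noise**: i.i.d. Gaussian, sd 0.7 per channel and sample at the
  native 300 Hz rate.

Simulation runs natively at 300 Hz (an integer multiple of the 3 Hz
stimulation rate) so the resample-to-100 Hz step is genuinely exercised;
the hardware-scale 1 kHz rate adds nothing at this level of abstraction.

Cohorts draw (β_aud, β_vis) from a bivariate Gaussian with mean 0.4, sd
0.15 and configurable correlation ρ, redrawn until non-negative (an option
allows signed betas). Each modality gets an independent forward model and
sequence, mirroring distinct sensory systems.

**Choice of SNR.** With these defaults a simulated subject shows ~0.5–0.75
post-stimulus 4-class accuracy and cohorts show split-half reliabilities
(Spearman–Brown ~0.4–0.85 depending on design size) — the ranges real
recordings of this paradigm exhibit. The β→score mapping is convex: the
classifier can only weight the pre-activation pattern to the extent that
pattern was present in its own training data, so sensitivity grows with β.
This is a faithful consequence of the train-on-ordered design, not an
artifact.

**What the generator does not emulate**: physiological artifacts, 1/f
background spectra (optional hook omitted by default), head geometry,
magnetometer/gradiometer unit mixing, source-space structure. Passing
tests therefore demonstrate the *estimator's* correctness and calibration,
not robustness to real-world artifact regimes.

## Statistics

* **Cluster-based permutation t-test** (one-sample, subjects × time):
  cluster-forming threshold at the two-sided 0.025 t-quantile per tail,
  cluster mass = summed t, null = distribution of the maximum |mass| over
  seeded whole-subject sign flips, p = (1 + exceedances)/(1 + N) so no
  p-value is exactly zero. Defaults: 10,000 permutations, Monte-Carlo
  critical alpha 0.025. Positive and negative clusters are tracked
  separately; multiple clusters get individual p-values with no further
  multiplicity correction. The statistics window defaults to the
  epoch-supported [−0.3, 0.3] s and is configurable.
* **Reliability**: Pearson r between modalities; covariance-based
  Cronbach's α (two-item identity 4·cov/(var₁+var₂+2·cov)); Spearman–Brown
  ρ = 2r/(1+r); split-half reliability splits the *matched test trials*
  (condition-balanced, training shared) — splitting training trials would
  change the classifier itself and conflate two sources of noise; the
  time-by-time matrix applies the Spearman–Brown transform to every
  prestimulus (auditory i, visual j) sample pair.
* **Attenuation correction**: the cross-modal correlation of measured
  scores underestimates the latent correlation of the βs by the factor
  √(rel_aud·rel_vis). The rho-recovery study therefore reports both the raw
  pooled estimate and the classical disattenuated estimate
  r/√(rel_aud·rel_vis) (clipped to [−1, 1]), with reliabilities taken from
  split-half halves pooled across replicates.

## Numerical conventions

* Epoch grid: half-open [tmin, tmax), 0-based samples, onset at t = 0;
  −0.4..0.8 s at 100 Hz → 120 samples. Decoding window endpoints inclusive
  ([−0.3, 0.3] → 61 samples); the prestimulus score window [−0.3, 0) is
  half-open (30 samples).
* Filtering happens in the continuous domain before epoching (no epoch-edge
  transients); zero-phase FIR via the standard MNE filter design. The
  0.1 Hz high-pass edge implies a long kernel; recordings are padded.
* LDA: lsqr solver with Ledoit–Wolf analytic shrinkage by default; the
  intensity is configurable and λ = 0 fails loudly on singular covariance.
  λ = 1 reduces to nearest-class-mean scoring.
* Degenerate inputs are rejected with named errors and diagnostic counts
  (empty trial selections report per-criterion totals). The paired t-test
  returns t = 0 for identical score vectors.
* Every stochastic step (sequence, omissions, noise, subselection, splits,
  permutations) takes an explicit seed; a config determines every output
  byte. Miniature fixtures regenerate bit-identically against a frozen
  SHA-256.

## Validation-study problem sizes

The studies are sized for a single CPU:

* **Design arithmetic** uses the full two-block, 5600-trial geometry.
* **β recovery**: 35 subjects, one modality, reduced geometry (one block of
  4 × 700 trials, 32 channels), decoding restricted to the prestimulus
  window that defines the score.
* **ρ recovery**: 20 replicate cohorts × 15 subjects × 2 modalities per ρ
  at a scaled design (one block of 4 × 250 trials, 16 channels) — enough
  matched test trials (~20 per condition) for a stable pooled estimate once
  attenuation is corrected.
* **Null calibrations**: label-shuffled decoding on 3 subjects at the
  scaled design; cluster type-I error over 250 Gaussian null cohorts
  (20 subjects × 30 samples, 1000 permutations each).

## Known limitations

* The ideal observer is a Dirichlet(1)-count learner per current stimulus —
  a rationale-reproduction device for the burn-in length, not a
  hierarchical Bayesian filter; only the qualitative criterion (first
  crossing of 0.5 posterior predictive) is reproduced.
* Whether a segment's first trial conditions on the preceding segment's
  last trial is unspecified in the paradigm description; sequences continue
  across boundaries under the new regime, and the burn-in absorbs the
  switch.
* The prestimulus ramp shape, the sensor patterns and all amplitudes are in
  arbitrary units; scores are comparable within a simulation setting, not
  across settings.
* Cross-modality classifier transfer, source-space analysis and nonlinear
  decoders are out of scope.
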