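# Methods

## Estimation chain

Per subject, the pipeline transforms a parcel-level recording (trials ×
parcels × samples) as follows.

1. **Band-pass 13–30 Hz.** 4th-order Butterworth applied forward and
   backward (`sosfiltfilt`), i.e. an effective 8th-order magnitude response
   with exactly zero phase shift. Zero phase matters because any filter
   delay would masquerade as phase lag in the connectivity statistic. The
   signal is reflect-padded by three cycles of the low band edge before
   filtering; recordings shorter than that warm-up are rejected.
2. **Analytic signal.** Hilbert transform per trial and parcel over the
   *full* trial; the instantaneous phase is the complex argument. The
   analysis window is cut *after* this step — computing the analytic signal
   on a short window directly would put Gibbs ringing at its edges.
3. **Window selection.** Half-open `[start, end)` in seconds relative to
   target onset; default `[0, 1.1)` (275 samples at 250 Hz). A sample at
   time t is kept iff start ≤ t < end, implemented in index arithmetic
   with a 10⁻⁶-sample slack so float round-off of the time axis cannot
   flip the boundary sample.
4. **Phase locking.** With C the circular mean of the per-sample phase
   differences within one trial: PLV = |C|, ciPLV = |Im C| / √(1 − Re C²).
   The statistic is computed within trial and averaged arithmetically
   across trials (the common convention; it keeps estimator variance
   analyzable and makes the matrix invariant to trial duplication). All
   pairs are computed at once from unit phasors via one complex Gram
   matrix per trial; a brute-force double-loop reference implementation in
   the test suite pins the vectorized result to 1e−10.
5. **Inter-system strength.** R = M[sensorimotor rows, core columns];
   w = Σᵢⱼ Rᵢⱼ. The strength is deliberately the **sum**, not the mean, so
   it scales with the region-set sizes; group comparisons are valid only
   because one `ROISetPair` is applied to every subject (enforced by the
   model). Overlapping sets are an error, not a warning — overlap would
   place self-connectivity entries into w.
6. **Inference.** Pooled-variance (Student) independent-samples t-test on
   the per-subject w, df = n₁ + n₂ − 2; Cohen's d on the pooled SD, so
   d = t·√(1/n₁ + 1/n₂) holds identically; Shapiro–Wilk screen per group
   (restricted to 3 ≤ n ≤ 50). The default alternative is one-sided in
   the direction "first group < second group", matching the directional
   reduced-connectivity hypothesis; the tail is a configuration choice.

### Numerical conventions

* **ciPLV degenerate denominator.** |Re C| within 1e−12 of 1 means perfect
  zero-lag locking; the expression is then 0/0 and is defined as 0, which
  is also the limit along that path and the value the statistic's purpose
  dictates. The ciPLV diagonal is 0, the PLV diagonal 1, both forced by
  Δφ ≡ 0.
* **Sign.** The absolute imaginary part is used: connectivity strength is
  non-negative and w sums entries, so a sign would be meaningless.
* **One broadband estimate.** A single 13–30 Hz value per pair; no
  within-band frequency resolution.
* Constant nonzero-lag phase differences saturate ciPLV at exactly 1
  (e.g. Δφ ≡ π/4 gives Im C = Re C = √2/2 and denominator √2/2); this is a
  property of the estimator, not a defect, and is covered by closed-form
  tests.

## Synthetic generator

The generator emulates what the estimators need to be tested against, not
cortical physiology.

* **Oscillators.** Each parcel is unit-variance narrowband noise: white
  noise band-pass filtered to `center ± bandwidth/2`; default 20 ± 3 Hz,
  inside the beta band. An optional per-sample random-walk phase jitter
  (default 0) can broaden the intrinsic phase diffusion.
* **Coupling.** Target = κ·(source delayed by τ) + √(1−κ²)·(own noise).
  The √(1−κ²) weight keeps the marginal variance κ-invariant (verified to
  <10% drift across κ ∈ {0, 0.5, 1}), so coupling cannot be detected as an
  amplitude artifact. The delay is exact (frequency-domain phase ramp,
  applied in a padded segment so wrap-around never reaches the retained
  samples); τ = 0 is a literal copy. Amplitude-domain lagged mixture was
  chosen over Kuramoto-style phase dynamics: it is simpler, analytically
  tractable, and sufficient to induce controlled narrowband phase locking.
  Coupling chains (a target acting as a source) and total coupled energy
  Σκ² > 1 into one target are rejected.
* **Default lag = quarter cycle** at the oscillator center (12.5 ms at
  20 Hz). A quarter-cycle lag maximizes the imaginary part of the coupling,
  keeping the group effect well inside ciPLV's sensitive region instead of
  near its zero-lag blind spot.
* **Leakage.** Volume conduction / source leakage is an instantaneous
  linear mixing matrix applied sample-wise — an abstract operator, no
  leadfield or head geometry. The packaged leakage demonstration mixes one
  dominant latent source into two channels with weights (1.0, 0.8) plus a
  weak independent background per channel (weight 0.15). The pure
  two-copies case is exactly degenerate (PLV ≡ 1, ciPLV ≡ 0 by the
  convention above); the weak background makes the demonstration exercise
  the estimator away from the degenerate point while leaving the
  qualitative outcome unchanged: PLV ≈ 0.93, ciPLV ≈ 0.07 averaged over
  20 seeds.
* **Cohorts.** `CohortConfig` builds 2 × `n_per_group` subjects; every
  sensorimotor parcel is coupled to a core parcel (round-robin) with
  κ = `coupling_high` in the control-like group and `coupling_low` in the
  clinical-like group. Defaults: 7 per group, 50 trials (trial count is a
  free parameter of the emulation; no published value exists for it),
  250 Hz, trials spanning −0.2…1.3 s so the 0–1.1 s window fits, bilateral
  stand-in region sets (16 sensorimotor, 8 core parcels), κ = 0.8 vs 0.2.
  Seeding: subject k uses `seed + k`, so cohorts are bit-reproducible and
  within-group subjects differ only by their noise realization.

### What the generator does *not* emulate

1/f background spectra, non-stationarity, evoked transients, amplitude
correlations, realistic leakage geometry, or between-subject variability
beyond noise realization (all subjects in a group share κ). Passing tests
therefore show that the estimators and inference behave correctly under
controlled narrowband coupling and instantaneous mixing — not that the
pipeline is robust to every property of real EEG source estimates.

## Region sets

The packaged Destrieux label list (74 parcels per hemisphere, 148 total)
uses FreeSurfer `aparc.a2009s` names with `-lh`/`-rh` suffixes. The default
sensorimotor set (pre/postcentral gyri, paracentral and subcentral,
central and pre/postcentral sulci, bilaterally) and core face-system set
(fusiform, inferior/middle occipital, superior temporal sulcus,
bilaterally) are documented stand-ins covering the intended anatomical
territories; any analysis can and should override them via `ROISetPair`
when an exact list is available.

## Calibration and problem sizes

Monte-Carlo calibration of the group test uses a scaled study: 2 parcels
per system, 20 trials of 1.3 s, 7 subjects per group. Under the null
(equal κ = 0.5) the one-sided test at α = 0.05 rejects in 3–7% of 1000
cohorts; under the built-in effect (κ 0.8 vs 0.2) the empirical rejection
rate over 500 cohorts matches the noncentral-t power of the realized
effect size within 5 percentage points. Because within-group variability
is estimation noise only, the realized effect is very large and both
power figures sit at 1.0 — the calibration constrains the type-I side and
the consistency of the power computation, not a mid-range power value.

The analytic power routine uses the noncentral-t distribution with
noncentrality d·√(n/2) and is cross-checked in the tests against an
independent numeric oracle value.

## Known limitations and documented discrepancies

* With pooled-SD definitions, a reported effect size of d = −1.2 alongside
  t(12) = −1.91 for 7-vs-7 groups is internally inconsistent
  (t·√(2/7) ≈ −1.02); the variant of d behind such figures is unknowable
  from summaries alone. This package always reports pooled-SD d and makes
  the t↔d identity a tested invariant.
* A two-sided test at α = 0.05 would not reject for |t(12)| = 1.91
  (p ≈ 0.08); the directional one-sided test does (p ≈ 0.04). The default
  tail is one-sided because the substantive hypothesis is directional;
  users running non-directional questions should set `tail="two_sided"`.
* EDF support is read-only, one trial per file, channel labels taken as
  parcel labels; epoched multi-trial data should use the matrix format.
* ciPLV is blind to genuinely zero-lag physiological coupling by
  construction; that is the price of leakage robustness.
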