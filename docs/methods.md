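# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## ΔC1 pipeline

The dependent variable is the ΔC1: the LVF − UVF ERP difference averaged
over 50–100 ms after stimulus onset at O1, O2, P3, P4 and Pz. Because any
activity shared by the two visual-field conditions cancels in the
subtraction, the statistic isolates the retinotopically organized part of
the earliest visual cortical response; the audiovisual conditions inherit
this property, so an auditory-evoked potential present in both cells
cannot masquerade as a ΔC1 change.

Stage order: common-average re-reference → band-pass → ocular rejection →
motor rejection → mirror remapping → baseline → per-cell averaging →
windowed difference. Conventions that matter:

- **Window endpoints are inclusive** at sample resolution everywhere a
  millisecond window appears (baseline −100..0, ocular −25..175,
  measurement 50–100). This avoids off-by-one drift between sampling
  rates.
- **Filtering** (0.1–40 Hz, zero phase) defaults to an FFT design with
  raised-cosine transitions (up from 0.05 to 0.1 Hz, down from 40 to
  50 Hz, zero at DC). A zero-phase IIR high-pass with a 0.1 Hz corner has
  a ≈1.6 s time constant; on epochs under a second its edge transients can
  dominate the pass band, which is why the IIR (`design="butter"`) is kept
  only as an option for long continuous segments. The FFT response is
  exactly computable (`bandpass_gain`), so tests derive expected
  attenuations from the transfer function rather than from fitted
  constants.
- **Ocular rejection** compares each trial's maximum absolute amplitude
  (blink channels FP1/FP2, saccade channels F9/F10, −25..175 ms) against
  median + k × robust SD of those per-trial maxima, with k = 5 for blinks
  and 3 for saccades, computed per participant. The robust SD
  (1.4826 × MAD) keeps the threshold anchored to the clean-trial
  distribution even when a sizable fraction of trials carries artifacts —
  with a plain SD the artifacts would inflate their own threshold.
- **Motor rejection** removes trials with any response earlier than
  500 ms after onset; only standard (non-target) trials enter ERP
  averages in any case.
- **Mirror remapping** swaps left/right homologue channels
  (F7↔F8, …, O1↔O2, F9↔F10; midline Fz, FCz, Cz, Pz fixed) for trials
  with left visual-field stimulation (left sounds for auditory-only
  trials), relabels the stimulus sides, and thereby collapses left and
  right presentations into one right-side frame with twice the trials.
  The operation is an involution and preserves the per-trial multiset of
  samples; both properties are tested.
- **Re-referencing** to the common average is on by default; synthetic
  data are generated reference-free and the injected topography is
  zero-mean across the montage, so this step is exactly neutral for the
  signal and only whitens shared noise.

## Hierarchical inference

ΔC1 tables (participant × condition × electrode) are modelled as Gaussian
linear mixed models with a participant random intercept shared across
electrodes — the grouping choice documented here because the exact
hierarchical formula is a genuine design freedom; random slopes would not
be identifiable at n ≈ 14.

Priors follow a data-scaled rule: independent N(0, (2.5 × SD(y))²) on
non-intercept coefficients, N(0, (10 × SD(y))²) on intercept-like ones
(grand means, per-electrode means). Variances carry inverse-gamma priors
IG(1, var(y)/2). A degenerate all-constant response falls back to unit
scale so priors stay proper. All full conditionals are then conjugate and
the sampler is an **exact Gibbs sampler** — no step sizes, no divergences,
deterministic under a fixed seed. The production budget is 40,000 retained
draws (tests run 1,200–4,000 with correspondingly widened tolerances);
effective sample size is checked and a low-ESS fit is flagged, not
silently returned.

Three model front-ends share this machinery:

1. **Cell means** — one coefficient per group × condition × electrode;
   answers "is a ΔC1 present in this cell?" with the directional BF₊₀
   (positive direction throughout: a negative group-level ΔC1 has no
   physiological reading in this design).
2. **Contrasts** — the cell-means design is reparametrized onto the named
   contrasts plus grand mean and an orthogonal completion, per electrode
   block. Fitting in the contrast basis is essential: each contrast
   coefficient then carries its own 2.5 × SD prior, which is the density
   the Savage–Dickey ratio divides by. A "substantial difference" requires
   BF₁₀ > 3 *and* the 95% HDI fully outside the ROPE.
3. **Ordered trend** — orthogonal-polynomial coding of (V, AV_i, AV_c)
   with linear and quadratic components shared across electrodes;
   suppression growing with spatial specificity appears as a negative
   linear coefficient.

**Bayes factors** use the Savage–Dickey identity: BF₁₀ = prior density at
0 / marginal posterior density at 0, and BF₊₀ = BF₁₀ × P(θ>0 | data)/½.
The posterior density at 0 is estimated from draws by a Gaussian KDE with
a bandwidth-deconvolution correction (exact for a normal posterior) when 0
lies within 2 posterior SDs of the mean, and by a moment-matched normal
beyond that — point-KDE estimates that far out are dominated by Monte
Carlo noise, while the marginals of these conditionally conjugate models
are normal mixtures with near-normal tails. Beyond 4 SDs a warning marks
the estimate as extrapolated; decisions are unaffected because such BFs
exceed the threshold by orders of magnitude.

**Decision rule**: *present* if BF > 3 and the HDI (highest-density, not
equal-tailed) lies entirely outside [−h, +h] with h = 0.1 × SD(y);
*absent-evidence* if BF < 1/3 or the HDI lies entirely inside;
*inconclusive* otherwise. An HDI overlapping the ROPE boundary therefore
never counts as present, however large the BF. No multiplicity correction
is applied across contrasts: the priors are proper and shared shrinkage
plays that role by design. Cohen's d for a contrast is the posterior mean
difference divided by the model's residual SD — a convention, stated here
because the denominator is not fixed by the definition of the contrast.

## Behavioral arm

RT classes: A^T and V^T (unimodal targets), A^T V^0 and A^0 V^T (bimodal,
one target), A^T V^T (double target). The redundancy gain is
min(mean of the four single-target classes) − mean(A^T V^T) and may be
negative. The race-model comparison uses the bimodal classes
(F_A from A^T V^0, F_V from A^0 V^T, F_AV from A^T V^T).

- **Quantiles** use linear interpolation of order statistics (type 7) —
  the dominant convention in RMI tooling; the empirical CDFs are its exact
  inverse, and all three CDFs are evaluated at the pooled-sample quantile
  times so they are compared at identical t.
- **Violation area** integrates max(F_AV − F_A − F_V, 0) by trapezoid on
  a 1 ms grid spanning the pooled RT range; the permutation test instead
  uses only the 5th–30th-percentile grid (step 5), keeping the tested
  region inside the fast tail where race violations are diagnostic.
- **Cluster permutation test**: one-sided one-sample t per grid point,
  cluster-forming threshold at the one-sided t critical value (α = 0.05,
  n−1 df), cluster mass = sum of t, null = max cluster mass over 10,001
  random whole-profile sign flips, p = (1 + #{perm ≥ obs})/(n_perm + 1).
  Exceedance counting uses a relative tolerance so exact ties (the
  identity sign pattern) always count — p-values err conservative. Grid
  points with zero variance map to t = ±∞ so degenerate constant profiles
  stay well-defined. Participants lacking 10 correct RTs in any class are
  excluded with a logged reason.
- **Exponential-null Bayes test**: intercept model on the areas with an
  Exponential(λ) prior, λ = 1/SD(areas) so the prior variance equals the
  data variance. The intercept's full conditional is a truncated normal
  (normal likelihood × exponential prior), so the Gibbs sampler stays
  exact, and the marginal posterior density at 0 is Rao–Blackwellized
  over the conditionals; BF₁₀ = λ / that density. With a single area per
  participant the random intercept is dropped (unidentifiable); with
  replication (congruence within participant) it is kept, and a factorial
  Group × Congruence companion model reports per-factor BFs under the
  normal-prior rule. All-zero areas return BF₁₀ = 0 and an
  absent-evidence decision rather than an error.
- Misses delete the response; no imputation or kill-the-twin correction
  is applied (the task is unspeeded).

## Synthetic data generator

The EEG generator emulates exactly the features the pipeline consumes:

- a **retinotopic component** projected through a fixed zero-mean weight
  vector (maximal at O1, decaying toward parietal sites, mirrored for
  left-side stimuli), a Gaussian temporal envelope peaking at 75 ms
  (SD 12 ms), sign +1 for LVF and −1 for UVF — the calcarine polarity
  flip. Per-condition multiplicative suppression in [0, 1] emulates
  crossmodal suppression; all-ones emulates an intact control group.
  `expected_delta_c1` returns the analytic value the pipeline should
  recover, the oracle for the recovery tests.
- **1/f background noise** (default exponent 1, SD 5 µV) synthesized
  directly in the frequency domain, independent per channel plus a 25%
  shared component; variance is normalized analytically, not per trace.
- **artifacts**: 400 ms raised-cosine blinks (~250 µV, frontopolar
  maximum) and step-edge saccades (~120 µV, F9/F10 antisymmetric) at
  configurable per-trial rates, with ground-truth columns for sensitivity
  audits; unspeeded ex-Gaussian response latencies whose fast tail
  exercises the 500 ms motor rule.
- trial counts: `trials_per_cell` standards per collapsed
  condition × visual-field cell (split over left/right sides), targets
  added at 20%. Defaults — 14 participants, 200 standards/cell, 2 µV
  source, 0.4 µV between-participant amplitude SD, 500 Hz, −100..300 ms
  epochs — are the package's study conditions for recovery and
  calibration tests; per-condition counts after rejection are free
  parameters in the emulated design, so they are set once here and used
  throughout.

The RT generator draws ex-Gaussian channel finishing times (defaults
A: 350/60/120 ms, V: 400/60/120 ms, 20 ms participant jitter) and builds
the double-target RT as their minimum (`race_independent`; optionally
correlated channels via a shared Gaussian component) or as the minimum
speeded by a fixed shift (`coactivation`), floored at 100 ms. With zero
shift the coactivation path is bit-identical to the race path under the
same seed — a tested reduction. Under `race_independent` the analytic
F_min = F_A + F_V − F_A·F_V satisfies Miller's bound strictly, so the
permutation test's null calibration is measured under a composite null
where the test is expectedly conservative.

What the generator does **not** emulate: volume conduction and realistic
head geometry, oddball deviance responses beyond target labels, RT
anticipations/outliers, non-stationary noise, or drifting electrode
impedances. Passing tests therefore demonstrate the correctness and
calibration of the *statistics* under the assumed data structure, not
robustness to every pathology of clinical EEG.

## Problem sizes and reproducibility

Production settings (40,000 draws, 10,001 permutations) run in seconds to
minutes; the test suite uses reduced budgets chosen as the package's
desk-scale defaults — 4,000 draws, 1,001 permutations, 20 replicate seeds
for recovery/calibration checks, 200–500 replicates for error-rate
estimates — with tolerances widened accordingly (documented per test).
Every stochastic component takes an explicit integer seed;
`run_pipeline` derives per-stage seeds from the global one, stamps every
CSV with a provenance line (version, seed, config digest) and writes a
`provenance.json`; identical config + seed reproduces every artifact byte
for byte, which the suite asserts on the shipped demo configuration.

## Known limitations

- The ocular thresholds act on raw channel amplitudes; the original
  ICA-based isolation of ocular components is out of scope, so the
  rejection emulates the thresholding rule, not the decomposition.
- The Savage–Dickey density at 0 is an estimate; beyond ~4 posterior SDs
  its relative error is large even though the presence/absence decision
  is unaffected.
- The exponential-null reading of "further from zero than an exponential
  with the data's variance" (prior on the intercept, density ratio at 0)
  is one defensible operationalization of an ambiguous verbal
  specification; the code flags it and keeps λ explicit in diagnostics.
- BrainVision support is read-only and marker-driven; continuous
  recordings with other marker schemes need a caller-supplied trial
  table.
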