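# Methods

This note documents the models, conventions, numerical choices, and
limitations of the `formantadapt` pipeline.

## Normalisation

Formant frequencies scale inversely with vocal tract length, so raw Hz
values are not comparable across talkers. The pipeline uses the
average-formant-spacing (ΔF) normalisation:

    ΔF = (1 / (m·n)) · Σ_j Σ_i  F_ij / (i − 0.5),

with n = 2 formants (divisors 0.5 and 1.5) and m = 7 vowel-token means
(/ɛ ɪ i e æ ɑ u/, ASCII aliases eh ih iy ey ae aa uw). For an ideal
uniform tube of length L the formants are (2i−1)·c/(4L), giving
ΔF = c/(2L) exactly; the pipeline therefore reports the implied vocal
tract length L = c/(2ΔF) with c = 35 000 cm/s. ΔF is computed from
per-vowel token *means*, not raw tokens. All trial formants, inventory
means, and shift components are divided by the speaker's ΔF.

Perceptual shift magnitudes use the analytic mel scale
mel(f) = 2595·log₁₀(1 + f/700). The mel conversion is nonlinear, so the
shift magnitude in mels is anchored at the speaker's baseline /ɛ/
operating point: each component is mel(F + ΔF_comp) − mel(F) and the
magnitude is their Euclidean norm. (Historical tabulations of the mel
scale differ slightly from this analytic form; the constants are module
constants and trivially swappable.)

## Shift design

Experiment 1 shifts feedback from /ɛ/ to each of six target vowels
(per-formant difference of inventory means); experiment 2 re-uses each
direction with the Hz-space magnitude fixed at exactly 50 Hz *before*
normalisation, so its normalised magnitude is 50/ΔF — constant within a
speaker but variable across speakers. Vectors live in (F1, F2) order and
the angle is atan2(ΔF2, ΔF1) in degrees: shifts that raise F2
(front-vowel targets) get positive angles. Height
(higher: iy ih ey uw / lower: ae aa) and backness (front: iy ih ey /
back: ae uw aa) are deterministic lookups relative to /ɛ/.

## Response decomposition

For one case, the baseline centre is the mean normalised formant pair
over *good* trials among the first ten (quality control is applied to the
baseline for consistency with the rest of the pipeline). With unit shift
direction ŝ and n̂ = ŝ rotated +90° in the F1→F2 sense:

    CR = r·ŝ      OR = −(r·n̂)      TR = |r|·sign(CR)      ANG = atan2(r₂, r₁)

The OR sign convention makes responses on the quadrant-I/II side of the
shift axis negative; TR is defined as + when CR = 0; a zero response is
flagged null (ANG undefined). TR² = CR² + OR² holds identically, and the
whole frame is invariant under joint rotation of shift and response —
both are enforced by oracle tests against an explicit rotation-matrix
change of basis.

Window aggregates use good trials from the last 20 trials of the altered
block (trials 41–60): arithmetic means for CR/OR/TR, the resultant-vector
(circular) mean for ANG — computed per-trial then circularly averaged,
one of two defensible orders. NCR/NOR/NTR divide the window means by the
normalised shift magnitude. Washout trials are decomposed for export and
plotting but never enter inference.

## Circular statistics

Degrees are the external unit everywhere; radians are internal. The von
Mises concentration κ is estimated by the standard three-regime
approximation of A⁻¹(r̄) (no small-sample bias correction by default; a
flagged option applies the usual n < 16 adjustment).

**Watson U².** Because μ and κ are estimated, the U² null distribution is
obtained by a seeded parametric bootstrap (default 1000 replicates) that
refits the parameters on every replicate; the statistic uses the
probability-integral transform of the ordered angles under the fitted von
Mises. The bootstrap is fully vectorised. U² rows are *assumption
checks*: they are reported but never counted as confirmatory effects.

**Watson–Williams.** F from the between/within resultant decomposition
with the 1 + 3/(8κ̂) correction, κ̂ from the pooled within-group
resultant; df = (k−1, N−k). A warning (recorded in the result) fires when
κ̂ < 1, outside the test's validity.

**Harrison–Kanji.** Two-way decomposition of resultant-based variation in
the high-concentration χ² form:

    χ²_A  = 2κ̂ (Σ_rows R_row − R)                      df = p−1
    χ²_B  = 2κ̂ (Σ_cols R_col − R)                      df = q−1
    χ²_AB = 2κ̂ (Σ_cells R_cell − Σ_rows − Σ_cols + R)  df = (p−1)(q−1)

κ̂ uses the residual-based estimator (N − C)/(2(N − Σ R_cell)) with C
fitted cells: in the concentrated regime 2κ(N − ΣR_cell) ~ χ²_{N−C}, so
dividing by N − C (rather than inverting the pooled resultant, which
ignores the C estimated cell means) removes an upward bias that would
otherwise inflate the type-I error by several percent. A warning fires
when κ̂ ≤ 2. Calibration of both ANOVAs (type-I error within a few
tenths of a percent of nominal at κ = 2.5–8) is verified by seeded
simulation in the test suite.

Validity gating: Watson–Williams and Harrison–Kanji results whose
concentration warning fired are excluded from the confirmatory
(BH-flagged) set — mirroring the practice of checking the von Mises
assumption before relying on these tests. Under a no-adaptation null the
response angles are uniform and the circular ANOVAs are meaningless; the
gate keeps them from contaminating the false-discovery ledger.

## Mixed models

Within each experiment, TR/CR/OR over the good window trials are
modelled by REML linear mixed models with fixed effects shift angle
(continuous, degrees), shift magnitude, and gender; reduced models swap
the angle for the height or backness grouping. Cross-experiment models
use per-trial normalised responses (NCR/NOR/NTR) for the subjects who ran
both experiments, with experiment, angle, and their interaction, and a
random slope + intercept structure; the trial-level default matches the
scale of the within-experiment analyses, with a per-case option
(`cross_experiment_per_trial=False`). A likelihood-ratio comparison
(`test_slopes`, 2 df) decides between intercept-only and random-slope
structures.

**Random structure.** Beyond the subject random intercept, trial-level
models include a participant × case variance component. The 20 window
trials of one case share that case's estimated baseline (and any
case-level fluctuation of the underlying response), inducing a
within-case correlation of roughly 0.09 under the generator's own noise
model — a design effect near 2.7 for case-level covariates such as angle
and magnitude. With a subject-only random effect the post-BH false-flag
rate under null truth was measured at ~14%; with the case component it is
~2%, at or below the nominal 5%. The component can be disabled
(`case_variance=False`) to reproduce the subject-only structure.

**Type III tests.** Factors are Sum-coded; each term is tested by a Wald
F on its coefficient block. Denominator df follow the between/within
partition by default (terms constant within subjects are tested against
subject-level df; within-subject terms against observation-level df),
with a pure residual rule as the alternative — the method is declared in
the config and echoed in every result file. Responses are centred before
optimisation so that translation invariance of the F statistics is exact;
an L-BFGS fit falls back to BFGS when the profiled Hessian is singular.

Benjamini–Hochberg step-up control (α = 0.05) is applied across the
bundle's effect p-values (fixed effects + validity-passing circular
tests); the mel-scale sensitivity re-run — which replaces the magnitude
covariate with its mel-scale version — is reported separately and not
flagged.

## Synthetic-data generator

The generator emulates the study conditions: 18 speakers (ten female),
14 in both experiments and two exclusive to each (16 per experiment), six
cases per experiment, 90 trials per case in 10/50/30 blocks, randomised
case order.

- **Vowel spaces.** A packaged template of typical adult-male American
  English F1/F2 means for the ten inventory vowels (a documented
  synthetic fixture, not a measurement claim); each speaker divides it by
  a vocal-tract-length scale (female 0.82–0.95, male 1.00–1.15, i.e.
  female formants higher) and adds 1.5% multiplicative token noise.
- **Adaptation dynamics.** Truth is planted in the (CR, OR) frame of each
  speaker's own shift: the response at trial t is
  a(t)·|s|·(NCR·ŝ − NOR·n̂) with geometric approach a(t) = 1−(1−λ)^(t−10)
  during the altered block (λ = 0.25 per trial, so the last 20 trials sit
  at ≈ the asymptote) and geometric washout decay (rate 0.30). The form
  is a modelling choice; only its near-asymptotic window matters for the
  estimators.
- **Noise.** Isotropic Gaussian production noise in normalised formant
  space, SD 0.012 per formant by default (≈ 13 Hz at ΔF ≈ 1100 Hz, in
  the range implied by natural /ɛ/ production variability of ~15 mels per
  SD). Bad trials are independent Bernoulli events (p = 0.03).
- **Truth profiles.** `null`, `uniform_compensation` (NCR −0.15),
  `front_back_dichotomy` (compensate for positive angles, follow for
  negative), `experiment_dependent` (uniform in experiment 1, dichotomy
  in experiment 2 — plants an experiment × angle interaction), or any
  callable; optional per-participant (SD 0.05) and per-cell (SD 0.02)
  truth jitter.

All randomness derives from a single seed through named substreams;
outputs are bit-identical under a repeated seed.

**What the generator does not emulate:** formant-tracking error
structure, trial-to-trial motor drift, vowel-specific anisotropic
variability, perceptual category boundaries, or any within-trial
dynamics. Passing recovery tests therefore demonstrates correctness of
the pipeline's bookkeeping and estimators under the stated noise model,
not robustness to every property of real recordings.

## Estimator precision and the 50 Hz experiment

The NCR estimator error has SD ≈ √(σ²/20 + σ²/10)/|s| (window mean plus
baseline-centre error over the shift magnitude). Full-vowel shifts have
|s| ≈ 0.12–0.95 normalised, so at σ = 0.01 at least 95% of those cells
land within ±0.05 of truth. The 50 Hz shifts are only ≈ 0.04–0.05
normalised, so their *ratios* carry error SDs near 0.08 at any plausible
production-noise level: per-cell NCR/NOR values for the fixed-magnitude
experiment are intrinsically noisy by construction of that design, and
quantitative recovery guarantees are stated for the full-vowel cells
only. (Group-level inference on the 50 Hz experiment is unaffected; only
single-cell ratio precision is.)

## Problem sizes

Default analyses run the full study scale (18 speakers, 17 280 trials) in
seconds. Calibration studies in the test suite and acceptance script use
fixed seeded simulation sizes — 500–2000 replicates for test-size
estimates, 8-speaker studies for the repeated end-to-end null
calibration, reduced inferential bundles (primary models + circular
tests) for the 500-fold repetition — chosen to estimate rates to ±1–2
percentage points.

## Known limitations

- Denominator df use between/within partitioning, not Satterthwaite or
  Kenward–Roger; between-subject effects at very small cohorts are
  approximate.
- The Harrison–Kanji χ² form is only valid at high concentration; the
  package warns and gates rather than switching to a low-κ variant.
- The surrogate categorical re-analysis (target vowel instead of angle)
  is available (`angle_as_category=True`) but off by default.
- The good-trial flag in input data is authoritative; the optional
  automatic range check ([100, 4000] Hz) is off by default and is no
  substitute for inspection-based quality control.
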