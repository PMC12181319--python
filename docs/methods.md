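# Methods

This note documents the generative models, scoring conventions, statistical
procedures and numerical choices implemented in `cogbattery`, and what the
synthetic-data layer does and does not emulate.

## Scoring conventions

**MST.** Test trials present 64 targets (studied objects), 64 lures
(similar variants of studied objects) and 64 foils (new objects) in random
order after a 128-item study phase. Trial-level filter: responses faster
than 100 ms are removed as accidental key presses; nonresponses are kept
but enter no probability. Participant-level inclusion: every response key
(old/similar/new) used at least once, and at least 10 responded trials per
item category. The indices are conditional proportions over responded,
post-filter trials of the item type:
LDI = P(similar|lure) − P(similar|foil), REC = P(old|target) − P(old|foil),
PC bias = P(old|lure) − P(similar|lure). The denominator convention
(nonresponses excluded from numerator *and* denominator) is stated
explicitly because alternatives exist; it is the common practice for this
task.

**Corsi.** Five trials per sequence length 3..9 while the participant keeps
passing (≥ 3 of 5 correct); after the first failed level, later lengths
appear once (to equalize exposure) and, having fewer than five
administrations, can never satisfy the span criterion. Span = greatest
length with ≥ 3 of 5 correct. Failing already at length 3 signals a
comprehension problem and excludes the participant. A literal reading of
the rule is applied to any (design-violating) non-contiguous success
pattern: only fully administered lengths are eligible.

**Signal detection (n-back, go/no-go).** d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate)
with the standard extreme-rate correction: a rate of exactly 0 becomes
0.5/n, a rate of exactly 1 becomes (n−0.5)/n, n being the trial count of
that category; interior rates are untouched. n-back: 24 targets vs 72
non-targets; sub-100 ms responses are discarded before both the counts and
the hit-RT average (whether the RT filter feeds the d′ numerators was an
open choice; applying it to both is the consistent reading). Go/no-go: go
trials are the signal category (80) and no-go the noise category (20),
scored per phase; the headline false-alarm rate is raw (uncorrected).

**Task switching.** The first four trials of every block are warm-up
buffers and are dropped (24 + 24 + 48 valid trials). RT costs use correct
responses ≥ 100 ms; error rates count any trial without a correct response
(including nonresponses) as an error. Specific switch cost = switch −
repeat within the heterogeneous block; mixing cost = repeat − homogeneous.
Costs can be negative, so the default regression models untransformed
costs; a log-transform of the outcome is available per model
(`ModelSpec(log_outcome=True)`) and is the default only for SSRT, which is
strictly positive.

**Stop-signal.** Independent race model: a go process (ex-Gaussian
finishing time) races a stop process of constant latency SSRT starting at
the stop-signal delay (SSD). Estimation uses the integration method: all
go-trial RTs, including choice errors, with omitted go trials replaced by
the participant's maximum observed go RT, sorted ascending; the n-th value
with n = round(N_go · p(respond|stop)) — half-up rounding, 1-based rank,
clamped to [1, N_go], ties broken by stable sort — minus the mean SSD over
all stop trials (responded or not). Eligibility: p(respond|stop) within
[0.25, 0.75], go omissions ≤ 10 %, and mean unsuccessful-stop RT strictly
below mean go RT; all violated rules are reported.

**Questionnaires.** PHQ-9 and GAD-7 are item sums (0–27, 0–21) with the
published severity cut points. PSQ-20: four subscales (demands, tension,
joy, worries) of five items; subscale score = mean/3 × 100 with joy items
reverse-coded at the item level (x → 3−x) before averaging — equivalent to
subscale-level reversal under the linear transform, stated explicitly
because only "reverse coding in the total" is conventionally said. The
item-to-subscale key is configurable; the default is the instrument's
standard alternating key (worries 1,5,9,…; tension 2,6,10,…; joy 3,7,11,…;
demands 4,8,12,…). WHO-5 total = sum × 4 (0–100), totals ≤ 50 flag poor
well-being. Missing items are never imputed: an incomplete instrument
invalidates that participant's score (conservative listwise handling).

## Statistical layer

Each outcome is fit by OLS with the focal predictor (infection status,
coded never-positive = 0 / previously-positive = 1) and covariates age
(mean-centered within the analysis sample after listwise deletion), gender
(female = 0, male = 1; the handful of diverse-gender participants are not
coerced into the binary coding and drop out of regression analyses),
education (no post-secondary = 0), and the PHQ-9, GAD-7 and PSQ-20 totals.
Standardized β = b·SD(x)/SD(y) on the analysis sample; binary predictors
are standardized like continuous ones so every table cell is filled. Two
outlier rules: Tukey fences (1.5 IQR beyond the quartiles, linear-
interpolation quartiles) for the questionnaire totals, and a group-wise
two-SD rule (mean and SD computed once, no iteration) for cognitive
outcomes — for the MST a single shared exclusion on LDI *or* REC feeds all
three memory models, mirroring how such batteries report one memory
analysis sample. Order of operations per outcome: task-level exclusions →
outlier removal → listwise covariate deletion → fit.

Holm's step-down correction is applied to the four questionnaire focal p
values as one family; cognitive models are reported uncorrected (both
behaviors are switches). Auxiliary two-group comparisons use the pooled-
variance Student t test (df = n₁+n₂−2); Cohen's d uses the pooled SD.

**Bayes factors.** For t statistics, the JZS Bayes factor with a Cauchy
prior of scale √2⁄2 on the standardized effect, computed by adaptive
quadrature of the noncentral-t likelihood against the prior (the test
suite checks it against an independent mixture-of-g quadrature, which is
the other standard derivation of the same quantity). For regression terms,
the ratio of two Zellner–Siow marginal likelihoods (full vs reduced model
on identical rows), each a one-dimensional integral over g with
g ~ InverseGamma(1/2, r²n/2), evaluated in log space after locating the
integrand's mode on a coarse grid to avoid under/overflow. The same scale
r = √2⁄2 is used for consistency with the t-test prior; it is recorded in
the run manifest. Evidence bands: BF₁₀ > 10 strong H₁, 3–10 moderate, 1–3
anecdotal, 1/3–1 anecdotal H₀, 1/10–1/3 moderate H₀, < 1/10 strong H₀.

## Synthetic cohorts

The generators reproduce the battery's trial structure exactly (asserted
in tests for all eight tasks) under simple, analytically tractable
response models:

* MST responding is multinomial per item type with per-participant
  propensities drawn from Beta distributions (concentration 15) around the
  group means, so the expected scored LDI equals p_lure_similar −
  p_foil_similar by construction. The infected group's p_lure_similar is
  lowered by the configured deficit (default 0.08); age, months since the
  positive PCR test and symptom counts act as centered linear slopes on the
  same propensity. RTs are log-normal per response key; a configurable
  fraction of accidental sub-100 ms presses (default 5 %) exercises the
  trial filter without biasing the indices. Lure pair identity is carried
  as stimulus metadata but does not modulate responding — the indices never
  use pair-level similarity bins.
* The stop-signal generator implements the full 50 ms up/down staircase
  (start 250 ms, clamped to [0, 1250] ms: the SSD cannot be negative nor
  outlive the stimulus) trial by trial; a stop trial draws a response iff
  the sampled go finishing time beats SSD + SSRT.
* Go/no-go and n-back responding is Bernoulli per trial class; n-back
  letter sequences genuinely satisfy the 2-back relation at target
  positions. Task-switching RTs are base + mixing effect + switch effect +
  ex-Gaussian noise; Corsi success is logistic in (capacity − length);
  alertness is ex-Gaussian simple RT with a small miss probability.
  Speeded-task RT families are ex-Gaussian and memory/questionnaire
  latencies log-normal — standard positively skewed choices, exposed in
  the configuration, since no RT model is prescribed for such data.
* Questionnaire items are rounded, clipped latent normals sharing one
  participant trait per instrument; joy items load negatively. Group shifts
  are specified in scored points and converted to latent shifts by solving
  the closed-form expected total (so a configured +1.06 PHQ-9 point
  difference is reproduced in expectation).
* The cohort layer composes these per participant: group sizes default to
  910 previously infected / 495 never positive; ages ~ N(44, 14.5) in
  18–90; an education imbalance between groups; partial task completion by
  per-task participation probabilities calibrated to typical per-task
  sample fractions; months-since-PCR ~ N(11.15, 6.97) truncated to 0–29;
  symptom counts Poisson(2). Every (participant, task) pair gets an
  independent PCG64 stream derived from the master seed via CRC hashes, so
  regeneration is bit-identical and partial regeneration is possible.
  Any effect pushing a probability outside [0, 1] is clipped and counted;
  a clip rate above 1 % raises a warning in the simulation log.

What the generators do **not** emulate: item-level difficulty and lure
similarity structure, practice/fatigue and sequential dependencies,
device- and keyboard-timing jitter of online testing, informative
missingness (participation is independent of ability), and diffusion-style
process models of choice RT. Passing tests therefore demonstrate that the
scorers and the inference layer are correct and calibrated under the
stated models — not that real cohort effects of a given size exist.

## Validation problem sizes

The shipped suite validates at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: staircase equilibrium over 50 participants
× 48 stop trials (±0.05 on p(respond|stop)); SSRT recovery over 50
simulants at 48 and 500 stop trials (mean bias within ±25 ms at 500; the
estimator's small negative bias at the 48-trial study scale is bounded at
40 ms and tabulated by `cogbattery recovery-study`); index and OLS oracles
at 10⁻¹² / 10⁻⁸; type-I error of the focal test over 10,000 null cohorts
of n = 150 (0.05 ± 0.01); LDI-deficit recovery at 2,000 participants per
group (focal b within ±0.02 of −0.08); and a power simulation at the
memory task's group sizes (76/62) via `inference.focal_power_simulation`.

## Known limitations

* The go/no-go analysis is a participant-aggregated OLS; a trial-level
  mixed model with a participant random intercept is out of scope, and
  phase is handled by scoring d′ per phase rather than as a within-subject
  factor in one model.
* Duplicate participations are resolved by an explicit integer
  participation index; identical indices for one participant raise an
  ambiguity error rather than guessing a tie-break.
* The Tukey and two-SD rules are single-pass by design; iterating them
  would change the analysis sample.
* BF computation assumes the focal term is a single column; multi-column
  focal blocks (e.g. a factor with several levels) are not implemented.
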