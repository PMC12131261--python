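# Methods

This note documents the statistical procedures implemented in
`facebias`, the generative model behind the synthetic studies, the
numerical choices in the mixed-model engine, and the limits of what
the test suite establishes.

## Analysis pipeline

**Event ingestion.** Gaze codes are ingested as interval events
(`trial_id, coder_id, target, start_s, stop_s`); frame-by-frame
exports are expected to be collapsed to intervals upstream, since the
analysis only uses durations. A trial manifest carries the stimulus
timing — two 5-s presentation windows separated by a 0.5-s black
screen for the paired experiments (with the side the expression
occupied in window 1; sides swap between windows), and six 3-s image
windows with 0.5-s gaps for the sequence experiment — so timing is
data, not code. Events straddling a window edge are truncated at the
edge: the black-screen gap carries no stimulus, and truncation is the
conservative reading.

**Inclusion rules.** Paired trials require positive looking at both
the expression and the neutral image; sequence trials require looks at
four or more of the five initial images and at the final image.
Exclusions carry machine-readable reasons (`did_not_look_both`,
`too_few_initial_looks`, `no_final_look`).

**Attention bias.** Per includable trial,
`bias_p = look_expression / (look_expression + look_neutral)`, which
is invariant to rescaling both durations. One-sample two-sided
t-tests compare each expression's trial-level proportions with 0.5.
The expression and intensity models are linear mixed models on the
untransformed proportion (no logit transform) with random intercepts
for social group and subject; intensity is continuous on the 0.25–1.0
scale, which fixes the slope's units (recorded in the model metadata).
Pairwise expression contrasts are differences of estimated marginal
means with Tukey adjustment via the studentized range distribution at
the contrast's Satterthwaite df; for a balanced one-factor design
these equal raw mean differences.

**Violation of expectation.** Per trial an OLS line through the
(position, looking-time) pairs of the present initial images (≥ 4 of
5; missing looks are simply omitted, not imputed) is evaluated at
position 6. Predictions may be negative for steeply declining
sequences and are retained unclipped — clipping would bias the paired
t-test — with a per-trial flag. The binary composite outcome is
observed > predicted, with ties (measure zero on real durations)
scored 0.

**Composite scores.** Raw trial scores — |bias − 0.5| for
expression-vs-neutral trials (bias toward and away both indicate
discrimination), signed bias for intensity trials, the binary outcome
for sequence trials — are z-standardized within trial type using the
sample (n−1) SD pooled over all subjects' trials of that type. Trial
types: one per expression (3), one per intensity level (4), and a
single type for all sequence trials. Types with fewer than two trials
or zero variance cannot be standardized and are dropped with a logged
warning. Per subject, z-scores are averaged within trial type and the
type means averaged (an all-trials average is available as an option);
subjects with fewer than three contributing trials are omitted.
Because z-scoring is invariant to positive affine rescaling of any
type's raw scores, the choice between |p − 0.5| and 2|p − 0.5| is
immaterial — this is asserted to 1e-10 in the tests.

**Individual differences.** The maternal model regresses the
composite on grooming and cradling (percent of 30-s scan samples),
approaching and restraining (events per 10-min focal; the rate uses
the `n_focals` column of the maternal table), sex (female reference),
and an orthonormal quadratic age polynomial, with crossed random
intercepts for group and mother. The orthonormal basis is the
QR/Gram–Schmidt basis of `[1, x, x²]` with the constant column
dropped and signs fixed so each column correlates positively with its
leading power — the convention under which quadratic age coefficients
are conventionally reported. The age follow-up suite fits four models
(linear age, log age, quadratic age, and continuous age × juvenile/
adult category with juveniles under 5 years as reference, so the `age`
coefficient is the juvenile slope; the adult slope is reported as a
contrast). Significance is marked at α = 0.05 with no multiplicity
correction across coefficients.

**Inter-coder reliability.** `compute_icc` computes the two-way
random-effects, absolute-agreement, average-measures ICC (ICC2k) by
default via pingouin, with other forms selectable; the form matters
because "average ICC" is ambiguous across software conventions.
Degenerate inputs (one coder, < 5 double-coded units, constant
ratings) raise instead of returning a meaningless number.

## Mixed-model engine

All models are random-intercept LMMs. Estimation maximizes the REML
criterion with the residual variance profiled out, over the one or two
log variance ratios, using Nelder–Mead from several starts; the
covariance algebra uses the Woodbury identity on the low-rank
random-effect structure, so a fit costs O(n·q²). This engine exists
because generic gradient optimizers are unreliable on these small,
boundary-prone models (variance components frequently estimate to
exactly zero); ratios below 1e-8 are snapped to the boundary and the
fit is flagged `singular` — reported, never silently repaired.

Satterthwaite denominator df for a contrast *l* uses
df = 2·f² / (gᵀ A g) with f = lᵀ(XᵀV⁻¹X)⁻¹l, g its gradient in the
variance parameters, and A twice the pseudo-inverse of the REML
criterion's Hessian. Both derivatives are central finite differences
on the natural variance scale; the Hessian uses 1% relative steps
(second differences of an O(n)-magnitude criterion need generous steps
to beat cancellation), the gradient 0.1%. Only parameters estimated
away from the boundary are differentiated; with every component at
zero the df reduces exactly to the residual df n − p, matching the
standard implementations. The engine is validated in the test suite
against R's lme4/lmerTest: estimates and SEs agree to ~1e-7 relative,
Satterthwaite df to ~0.1%.

`fit_mixed_model(..., variance_components={...: 0})` holds components
fixed (GLS at the given values), which reduces exactly to OLS at zero
— the oracle used in the tests.

## Generative model of the synthetic study

**Cohort.** Default 83 subjects in 15 social groups (round-robin
assignment after a random shuffle), ages uniform on 1–16 years,
P(female) = 56/83. Mothers are drawn from a per-group pool of about
half the group size, so siblings are common and the mother variance
component is identifiable; maternal records are exported for a
40/83 fraction of subjects (every subject has latent maternal
behavior). Maternal protocol: nine 10-min focals with scans every
30 s (180 scans); groomed/cradled scan counts are beta-binomial with
means 10% and 35% of scans; approaches and restraints are Poisson at
0.5 and 0.15 per focal.

**Latent skill.** Skill is a centered linear predictor —
maternal-care terms at coefficients (0.044 per grooming percentage
point, 0.012 per cradling point, 1.426 per approach/focal, −0.640 per
restraint/focal), an age curve rising linearly at 0.17/year to age 5
then flat, group and mother random intercepts (SD 0.15 each) — plus
N(0, 0.20²) residual. Skill enters trial behavior through a positive
multiplicative factor m = exp(0.9·skill), normalized to cohort mean 1
so that configured effect sizes equal cohort-average effects exactly
and parameter-recovery truth is well-defined.

**Paired trials.** The per-trial looking proportion is truncated
normal on (0.02, 0.98) around
0.5 + (condition effect)·m + saturating(subject offset), with
within-subject SD 0.12. Condition effects: −0.07 (scream), +0.05
(bared-teeth), +0.01 (threat), and 0.12·(intensity − 0.625) for the
intensity experiment. The subject offset has two parts, both loaded
on skill: a stable idiosyncratic bias per subject×expression (per
subject for the intensity experiment) with SD 0.12·m — strong
discriminators react strongly in subject-specific directions, which is
exactly what the absolute-bias composite measures — and, in the
intensity experiment, a directional threat vigilance 0.12·(m − 1)
that leaves the cohort-mean bias and the slope estimand unchanged.
The offset saturates at ±0.25 (tanh) so rare extreme subjects do not
pile against the proportion bounds and attenuate the condition-effect
estimands; with this, large-sample estimands sit within ~3% of the
configured effects. Total looking time is truncated normal (mean 6 s,
SD 1.5, within 0.5–9.5 s) and split by the proportion, so looking
times are positive and bounded by the stimulus-on time. Drawing the
proportion directly (rather than two independent durations) keeps the
mean proportion — the estimand of every downstream test — exact.

**Sequence trials.** Looking times at images 1–5 are truncated
normal (floor 0.05 s, ceiling the 3-s image duration, SD 0.30 s)
around a per-trial declining line (first-image mean 2.2 s, slope
−0.15 s/image); the sixth-image mean adds 0.27·m seconds. A 10%
fraction of trials misses exactly one initial image (still
includable). The 0.30-s noise is deliberately smaller than the
dispersion the emulated study's own paired t-statistic implies
(~0.95 s): truncated-normal looks bounded by 3-s images cannot carry
that dispersion without the truncation distorting the linear-trend
estimand, so the simulated paired t runs larger than the study's at
the same mean excess.

**Dropout and trial counts.** Each trial independently fails
inclusion with probability 0.30 (one image never looked at, or a
missing final/initial-image pattern for sequences). Attempted trials
per subject (2 paired-expression, 5 intensity, 1 sequence) are chosen
so included counts land near the emulated study's; real participation
is voluntary and much more uneven across subjects, which this uniform
design does not reproduce — trial counts are config fields, not
conclusions.

**Double coding.** Nine randomly chosen includable trials are
"coded" twice: coder 2 adds N(0, 1.2²) seconds to the total duration.
The 1.2-s disagreement SD is chosen so the emulated reliability is of
the magnitude such studies report (ICC ≈ 0.9, with the wide CI that 9
videos imply).

**Calibration rationale.** The idiosyncratic-bias and vigilance
channels exist because a purely multiplicative link on the small
population effects cannot give the composite enough subject-level
signal for maternal effects to be detectable at realistic sample
sizes, whereas the emulated study's design presumes they are. Their
magnitudes (0.12) were set so that maternal-care effects on the
composite are clearly detectable at a few hundred subjects and
marginally at the study's own scale — a weaker coupling than the
emulated study reports, bounded by the trial-level noise its
population statistics imply.

## What the tests do and do not show

The acceptance suite establishes, under this generative model: exact
closed-form behavior of the sequence predictor and z-scoring; type-I
error of the three population tests within 0.05 ± 0.02 over 1000 null
replicate studies (the null configuration zeroes all effect fields
*and* the subject-level bias heterogeneity, since the trial-pooled
t-tests assume independent trials); 95% CI coverage of the scream
bias, intensity slope, and violation excess within 93–97% over 500
replicate studies of 40 subjects; positive fitted grooming and
cradling coefficients in >95% of 500-subject replicates plus
monotonicity in the grooming effect; exact agreement of mixed models
with OLS at zero variance; and exact agreement of inclusion filtering
with generated flags through the full write→read→assemble path.

Coverage is *not* asserted for the maternal coefficients themselves:
z-standardization makes the composite's scale data-dependent, so those
coefficients are identified only up to a positive data-dependent
factor and no fixed config value is their truth — sign consistency
and monotonicity are the recoverable claims. The generator draws
truncated-normal looking behavior with uniform trial counts; real
looking-time data are skewed, zero-inflated, and unevenly sampled
across subjects, so passing tests demonstrate correctness of the
*pipeline*, not robustness of the study design to those features.

## Known limitations

- Only random-intercept structures are supported (no random slopes);
  group/mother and group/subject enter as crossed variance components,
  which coincides with nesting when labels are unique within groups.
- The paired-test conservatism induced by bounded looking times
  (rejection ≈ 0.04–0.05 under the null) is a property of the
  generative model, not corrected for.
- The Exp-2 trial types enter the composite per intensity level; the
  single-type alternative for all intensity trials is not implemented.
- No GLMM (beta/binomial) alternative for the proportion response; the
  untransformed-proportion LMM mirrors the analysis being implemented.
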