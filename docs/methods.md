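# Methods

This note documents the statistical model, the generator that stands in for
real cohort data, the numerical choices, and the limits of what the test
suite shows.

## Data model and preparation

An EMA panel is long-format: one row per answered prompt, keyed by
(subject, study day 1..D, slot-of-day 1..S), with emotion ratings in
[0, 100] and NaN for unanswered items. The default protocol is D = 17,
S = 5, prompts pseudorandomised inside 30-minute windows within a
06:00–18:00 frame on workdays (08:00–20:00 on weekends), 90 minutes to
respond.

Preparation applies, in order:

1. **Exclusions.** A subject is dropped if the end-of-study burnout
   assessment is missing, or else if more than 20% of scheduled prompts are
   unanswered. The burnout rule is checked first so the two exclusion
   counts partition the sample; the 20% bound is strict (exactly 20%
   missing is retained) and its denominator is the scheduled prompt count
   (D·S), not the delivered count. An "answered" prompt is a panel row with
   at least one non-missing rating.
2. **Lag construction.** Transitions pair slot s with slot s+1 of the same
   subject and day; overnight pairs never form. For a fully compliant
   subject this yields D·(S−1) transitions — a 1/S (20%) loss.
3. **Listwise deletion.** A transition is kept only if all selected
   emotions are observed at both endpoints; an interior missing rating
   therefore removes at most two transitions.
4. **Centering.** Lagged predictors are centered at the subject's mean of
   each emotion, computed over all of that subject's observed ratings in
   the post-exclusion panel (not only ratings surviving deletion).
   Outcomes stay on the raw scale; the random intercept absorbs the
   person mean on the left-hand side.

Day boundaries come from the explicit day index; a timestamp-based fallback
(midnight boundary) exists for files without one. Within-day prompt spacing
is treated as a constant lag.

## Estimation

The mlVAR is fitted equation-by-equation with `statsmodels` MixedLM
(restricted ML by default; ML available). Random-effects structures:
`correlated` (intercept + p slopes, free covariance; the default),
`diagonal` (independent components via variance components), and
`intercept_only`. Non-convergence triggers a fallback ladder
correlated → diagonal → intercept_only, with the structure actually used
recorded per equation. `pooled` (plain OLS) is the explicit
zero-between-subject-variance limit; it is also what the single-subject
oracle `fit_var_single` computes, and the two agree to numerical precision
by construction — a property the tests assert.

Optimization tries Powell first, then L-BFGS. On these panels the slope
variance components (~10⁻²) are four orders of magnitude below the rating
variance (~10²), a scaling that defeats gradient-based optimizers from
default starts; Powell is slower but converges reliably here.

Fixed-effect p-values are two-sided normal approximations to the
coefficient/SE ratio. Degrees-of-freedom corrections (Satterthwaite,
Kenward–Roger) are deliberately out of scope; the practical consequence is
quantified below. The group-level network keeps edges with p < α (default
.05), retaining sign and weight. Person networks are Φ_i = B + b_i with
b_i the BLUPs; no uncertainty is attached to Φ_i.

**Known finite-sample bias.** Person-mean centering of a lagged predictor
induces the classic dynamic-panel (Nickell) bias of order −(1+3φ)/T on
*autoregressive* coefficients; with T ≈ 50–85 prompts this is roughly
−0.02 to −0.04, and it also inflates the null rejection rate of the
diagonal entries (≈13% at nominal 5% in short-series simulations).
Cross-lagged coefficients are essentially unaffected (their null
calibration is ~5%, verified over 200 simulated fits at 25 subjects × 50
transitions). Density estimates inherit a small upward noise floor from
|·|-averaging of shrunken coefficients. These are properties of the
two-step estimator itself, shared with the standard implementations of it.

## Density and screening

Density is Σ|Φ_i| divided by a divisor: `auto` = p² (the mean absolute
effect; 16 for four emotions) or an explicit integer. The published
analysis of this protocol divided by 20; since a 4-node temporal network
has 16 coefficients, the origin of 20 is not recoverable from the text, so
both conventions are first-class and every result records the sum and the
divisor used (`paper_mode` selects 20). Outlier screening flags values
diverging more than k = 3 *sample* (n−1) SDs from the mean, in a single
pass on the full vector (never iterated); density and burnout are screened
separately and a subject flagged on either is dropped from the correlation.

## Burnout scoring

MBI-GS: 16 items on 0–7, dimensions exhaustion (5), depersonalization (5),
professional efficacy (6, reverse-coded as 7 − item). The total is
`range_scale · (w_EE·EE + w_DP·DP + w_PE·revPE) / Σw` on dimension means,
with default weights (0.4, 0.3, 0.3) — the common convention of
up-weighting exhaustion — and range_scale 6/7 mapping the 0–7 item scale
onto the instrument's declared 0–6 total. The exact published weighting
formula is not recoverable from the available text, so the weights and
range map are explicit, configurable and echoed in every score.
Cronbach's α uses the classical variance formula with sample variances;
incomplete rows are dropped and counted.

## Inference and power

Both correlation tests are one-sided (upper tail): Pearson's p from the
t-transform, Spearman's from the t approximation on midrank correlations
(a seeded permutation p is available for small n). The one-sided 95% CI is
[tanh(atanh(r) − z₀.₉₅/√(n−3)), 1.0].

`required_sample_size` searches the smallest n reaching the target power
under one of three power functions. The noncentral-t convention
(ncp = ρ√n/√(1−ρ²), df = n−2) matches the G*Power correlation module and
gives n = 64 at ρ = .3, one-tailed, α = .05, power .80 — the planning
figure for this protocol. The exact method integrates the density of the
sample correlation under bivariate normality (via the Gauss hypergeometric
function, log-scaled for stability) above the exact critical value and is
slightly more conservative: its power at n = 64 is 0.787 (a 10⁵-replicate
Monte-Carlo oracle agrees to ±0.004) and it first reaches 0.80 at n = 67.
The Fisher-z closed form gives 68. The package reports all three rather
than pretending they coincide.

## Synthetic cohorts

The generator emulates the study protocol, with defaults chosen once to
match its published regime:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 47 | final analysed sample of the protocol |
| B_true | diag 0.30, off-diag 0.05 | autoregression-dominant network; Σ|B|/20 ≈ 0.09, the reported density regime |
| slope_sd | 0.10 | moderate between-subject heterogeneity in every coefficient |
| innovation_sd | 10 | prompt-to-prompt fluctuation on the 0–100 scale |
| person_mean, sd | 35, 12 | negative emotions sit in the lower half of the scale |
| missing_rate | 0.10 | whole-prompt nonresponse; reproduces the observed median of ~77/85 answered |
| item_missing_rate | 0.02 | sporadic single-item gaps, exercising listwise deletion |
| density_burnout_corr | 0.40 | true latent association probed by the end-to-end tests |
| mbi_alpha_target | 0.91 | reported internal consistency |

Each subject's Φ_i is B_true plus independent normal deviations, rescaled
to spectral radius 0.95 if needed (stationarity). The latent series starts
from its stationary distribution (discrete Lyapunov solution) and is
iterated through every prompt *including overnight steps* — the truth
deliberately contains the overnight dependency that preparation must
discard. Ratings are the latent values clipped to [0, 100] (< 5% clipped
under defaults, asserted); they are continuous by default with an optional
integer-rounding flag. Prompt times are uniform in the first 30 minutes of
equal segments of the day-type frame. Burnout is a linear-plus-noise
function of standardized true density with the requested population
correlation, mapped to mean 2.2, SD 0.65 and clipped to [0, 6]; MBI items
are a one-factor model of standardized burnout with loadings solved from
the standardized-α identity λ² = α/(k−(k−1)α), discretized to 0–7, efficacy
items stored reverse-keyed. All randomness flows from one seeded generator
with per-subject stream splitting; identical configs give bit-identical
cohorts.

What the generator does **not** emulate: informative (mood-dependent)
missingness, circadian or day-of-week trends, response latency,
cross-valence coupling, non-stationary dynamics, and integer-valued
visual-analogue artefacts. Passing tests therefore show that the pipeline
recovers the truth of a well-specified stationary VAR world, not that the
model is correct for any real cohort.

## Problem sizes used by the checks

Simulation-based checks are run at sizes chosen to keep the full suite in
the minutes range while preserving the asymptotic regime each property
needs: null calibration uses 200 fits of 25 subjects × 50 transitions
(2400 cross-lag edges; binomial 95% band 0.041–0.059); parameter recovery
averages three replications at 20/50/100 subjects × 68 transitions;
end-to-end detection uses five replications at 200 subjects. The density
recovery criterion (correlation of true and estimated density > 0.5 at 50
subjects) sits near the statistical ceiling of the two-step estimator at
T = 68 — single replications scatter roughly 0.45–0.65 — which is why it
is evaluated as a three-replication average.

## Limitations

* Exact numerical agreement with any specific published mlVAR fit is not
  attainable: the random-effects structure, estimator and convergence
  handling of the original are unspecified, and REML/Powell choices here
  are documented defaults rather than a reconstruction.
* p-values are asymptotic; with few subjects the autoregressive edges of
  the group network are anti-conservative (see the bias note above).
* The weighted MBI total and the density divisor each have one
  configurable convention chosen to be explicit rather than guessed.
* The permutation Spearman p is O(n_perm) per call and intended for small
  samples only.
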