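# Methods

## The model

Responses are ordered categories `x = 0..m_i` to items indexed `i`,
answered by persons `v`. The partial credit (polytomous Rasch) model gives

    Pr{x_vi = x} ∝ exp( −τ_1i − … − τ_xi + x·(β_v − δ_i) )

normalised over `x = 0..m_i`, with person location `β_v`, item location
`δ_i` and thresholds `τ_xi` on a common logit scale (the threshold sum is
empty at `x = 0`). A threshold `δ_i + τ_xi` is the point on the latent
continuum where categories `x−1` and `x` are equally probable; thresholds
are centred per item (`Σ_x τ_xi = 0`) and item locations centred to mean
zero over the common (non-resolved) items, which anchors the scale across
resolution steps. Internally a higher score always means more frequent
problems; reports flip the sign so higher = better health, stated in the
report header.

The model's sufficiency property — the total score carries all the
information about `β_v` — drives both the estimation and the fit
machinery below.

## Estimation

**Items** are estimated by conditional maximum likelihood (CML). Persons
are grouped by observation pattern; within a pattern, the likelihood of
the responses conditional on their total is free of `β`. The
score-generating (elementary symmetric) coefficients of each pattern are
built by convolving per-item category weights `λ_i(x) = exp(−Σ_{l≤x}
(δ_i + τ_li))`, rescaled exactly in log-space so no overflow occurs. The
single unidentified direction (a common shift of every threshold) is
pinned by a quadratic penalty and removed exactly by centring afterwards.
Optimisation is quasi-Newton (L-BFGS-B) with the analytic gradient
`S_jl − Σ n_r · Pr(X_j ≥ l | r)`; convergence tolerance 1e-8 on the
gradient, at most 500 iterations, non-convergence is warned about, never
silent. The estimator handles incidental missingness (each person
conditions on their own observed-item total) and the structural
missingness created by item resolution (each group simply becomes its own
pattern) identically. Extreme totals drop out of the conditional
likelihood, as they carry no information about item parameters.

**Persons** are maximum-likelihood: `β` solves
`total = Σ_i E_i(β)` over the person's observed items (strictly monotone,
solved by Brent's method to 1e-10), with `se = 1/sqrt(Σ_i V_i(β))` from
the observed information. Zero and perfect scores have no finite ML
estimate; for reporting they are extrapolated by moving the raw score 0.3
score-points inward, and they are flagged `extreme` and excluded from
reliability, class intervals and residual analyses. Item standard errors
come from the numerically differenced Hessian of the conditional
likelihood (no sandwich correction — treat as approximate).

**Reliability** is the person separation index,
`PSI = (var(β̂) − mean(se²)) / var(β̂)` over non-extreme persons
(population variance).

## Class intervals

Persons are binned at empirical quantiles of the non-extreme `β̂`
(default 10 intervals); intervals under 30 persons merge with their
smaller neighbour, and fully tied estimates collapse to a single interval
with a warning. Because `β̂` is a function of the total score, its values
form group-specific lattices; where a quantile bin misses a group
entirely, the DIF ANOVA merges adjacent intervals per item until every
group × interval cell holds at least 10 persons.

## DIF detection and resolution

Standardized residuals are `z_vi = (x_vi − E_i(β̂_v)) / sqrt(V_i(β̂_v))`.
Because `β̂_v` is estimated from the same responses, their variance is
`≈ 1 − V_i/I_v` (about 0.87 with eight items), not 1; this does not
affect the ANOVA, whose residual mean square estimates the actual
variance.

Per item, a two-way fixed-effects ANOVA of the residuals on group, class
interval and their interaction uses Type II sums of squares (cells stay
unbalanced; computed by closed-form cell-mean decomposition, verified
against statsmodels to 1e-10). The group main effect tests uniform DIF, a
constant group offset along the trait; the interaction tests non-uniform
DIF. Effect sums of squares are multiplied by `adjusted_n / n` before
F-ratios and p-values (default notional size 1500), so significance is
judged as if the sample had that size — the residual mean square, being a
variance estimate, is not rescaled. Under the null the unadjusted group
test rejects at 4.6–5.3% for a nominal 5% (Monte Carlo).

Significance policy: an item is flagged when
`min(p_group, p_interaction) < α / (2k)` with `α = 0.05` and `k` tested
items — Bonferroni over all 2k tests in the pass, because the minimum of
two p-values is itself a double test. Flagged items are ranked by
`max(F_group, F_interaction)`, so strong non-uniform DIF can outrank weak
uniform DIF; exact ties keep item order with a logged note.

The sequential procedure fits, tests, resolves the top-ranked item into
group-specific copies (all other groups' responses become structurally
missing on each copy), refits — person estimates are refreshed every step
— and repeats until nothing is significant or `max_steps` is reached.
Resolved copies are excluded from subsequent DIF testing (their data come
from a single group). Resolving a *real* DIF item moves the group person-
mean difference; resolving an item whose DIF was an artefact of the
residual constraints does not — that contrast, plus the disappearance of
compensating opposite-signed residuals in the other items, is how real
and artificial DIF are separated.

For a resolved item the DIF magnitude is quantified as the difference of
group-specific `δ`; the "slope" summary is the derivative of the expected
value curve at the group's item location divided by `m` (for this model
the EVC derivative equals the response variance). This is an
interpretation supplied by the package — the model itself has no
discrimination parameter — and is flagged as such.

## Item fit

The fit chi-square compares observed cell totals with their *conditional*
expectations given each person's total score, computed exactly from the
elementary symmetric functions. Unlike expectations at estimated person
locations, these are bias-free under the model, so the statistic stays
calibrated in very large samples (Monte Carlo: chisq/df = 1.00, rejection
5.0% at nominal 5%). Cells are class intervals crossed with groups when
groups are supplied (as the pipeline does): the group split is what makes
DIF-type misfit visible, since pooling groups within an interval lets
their opposite-signed biases cancel. Degrees of freedom are
`n_cells − 1`; sparse cells merge by interval; the same
`adjusted_n / n` rescaling applies. The overall fit probability combines
per-item p-values by Fisher's method (recorded in the report metadata).
On DIF-injected data the overall probability rises monotonically across
resolution steps while PSI changes by < 0.005 per step.

## Synthetic data

The generator draws group-specific normal latent values and samples
responses from the model. Uniform DIF: the designated group answers an
item at `δ + shift`. Non-uniform DIF: the group's exponent on `β − δ` is
multiplied by a discrimination factor; the *fitted* model remains strictly
Rasch, so this appears as interaction-type misfit, matching how
non-uniform DIF presents in real data. Incidental missingness is applied
completely at random. One seed drives independent substreams for latent
draws, responses and missingness.

The survey-scale preset has eight 3-category items with locations spread
over ±1.5 logits (thresholds ±0.7), three groups of 3500 (boys, girls
before menarche, girls after; latent means −0.45, −0.30, +0.50, sd 1.0 —
the gap emulates large true group differences that persist after DIF is
taken into account), and uniform DIF of −0.8 and −0.5 logits injected
into `felt_low` and `stomach_ache` for the post-menarche group, in that
magnitude order. The five-category preset uses near-tied within-pair
thresholds (swapped outright, i.e. disordered, on two items) to emulate
response categories that do not work as intended: collapsing 5→3 then
barely moves the PSI. What the generator does *not* emulate: grade/age
structure, survey-year effects, local dependence between items, and any
non-normal latent shape — passing tests therefore show that the procedure
behaves correctly for data meeting the model's assumptions, not that any
particular real dataset does.

## Numerical and degenerate-input choices

Category probabilities use log-sum-exp; person solving brackets
adaptively; tied thresholds count as disordered (equality already means a
category is nowhere modal); a category never observed raises an error
advising collapse; a disconnected item design raises; zero-variance
residual cells become missing with a log entry; identical data and
settings give byte-identical estimates.

## Problem sizes used in the shipped checks

Calibration suites use 500 replicates at 3×1000 persons (DIF test
type-I), 60 replicates at 3×300 (item-fit calibration), 100 replicates at
2×2000 (artificial-DIF mechanism), 30 replicates at 2×1000 (ranking
power), 25 replicates at 2×600 (misfit detection); recovery checks run at
the full 3×3500 preset. The acceptance script uses 150 and 60 replicates
for its two calibration blocks.

## Known limitations

Item SEs ignore the penalty/centring covariance and any
misspecification (no sandwich); the 0.3-point extreme-score adjustment is
a reporting convention, not an estimate; the notional-sample-size
rescaling is a blunt instrument (it scales evidence, not information);
only one grouping factor is tested per pass; Mantel–Haenszel, logistic
regression and likelihood-ratio DIF methods are out of scope.
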