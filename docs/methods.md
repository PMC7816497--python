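# Methods

## Endpoints and estimators

Overall survival (OS) is time from resection to death from any cause;
cancer-specific survival (CSS) is time to death attributed to the index
tumor, with other-cause deaths censored at their death time (the registry
cause-specific convention). CSS is deliberately *not* a cumulative-incidence
(Fine–Gray) quantity: the conditional-survival ratio CS(y|x) = S(x+y)/S(x)
is defined on a survival function, and the cause-specific Kaplan–Meier
estimate is the S the analysis conditions on.

Both endpoints are estimated by the product-limit method with Greenwood's
variance, delegated to `lifelines.KaplanMeierFitter`; the per-event-time
at-risk/event/censored bookkeeping is exposed on the curve object. Group
comparisons use the k-group log-rank test (`lifelines.statistics`).

Conventions, chosen once and applied everywhere:

- **Right-continuity.** S(t) at an event time is the post-drop value; the
  "yearly grid" of all conditional quantities means exact multiples of 12
  months looked up on this step function.
- **t = 0.** Registry survival times are floored to whole months, so a
  recorded time of 0 means death *within* the first month; S(0) = 1 by
  definition. This also makes the baseline conditional value CS(y|0) equal
  the actual y-year rate exactly, and keeps the telescoping identity
  CS(y1+y2|x) = CS(y1|x)·CS(y2|x+y1) exact at machine precision.
- **Ties.** Deaths precede censorings within a month (product-limit), and
  Cox fits use Efron's tie correction — month-granularity data are heavily
  tied, and Efron's approximation is much less biased than Breslow's there.
- **No extrapolation.** Looking up S beyond the last observed time is an
  error; conditional series are truncated (with a warning) rather than
  extended.

The smoothed hazard curve is an Epanechnikov kernel smoother over the
Nelson–Aalen increments d_i/n_i, with the kernel mass renormalized over the
observed window so estimates near t = 0 and the end of follow-up are not
biased toward zero. Default bandwidth is 12 months on a monthly grid —
wide enough to suppress month-to-month registry noise, narrow enough to
show the early hazard peak and late plateau; it is a parameter everywhere
it appears. Hazard shape near the very end of follow-up is
bandwidth-sensitive and should be read qualitatively.

Median follow-up is computed by the reverse Kaplan–Meier method (median of
the censoring distribution) and reported as a diagnostic only.

## Cox modelling

Categorical covariates are dummy-coded against explicit reference levels
(age < 65, male, white, married, grade I, size < 5 cm, unifocal, solitary
fibrous tumor, untreated); reference levels carry implicit HR 1 and no
term. Fitting is by `lifelines.CoxPHFitter` (damped Newton on the partial
likelihood, Efron ties), with Wald 95% intervals and p-values — the layout
of the standard registry HR table. The univariable screen flags covariates
with any level at p < 0.05, the usual carry-forward rule into the
multivariable model. Separation (a level with no events) is surfaced as a
convergence warning on the fit object, not an error. The default
multivariable covariate sets are age, sex, grade, size, multifocality,
histology and chemotherapy for both endpoints, plus marital status for OS
only; both sets are configuration inputs.

## Conditional survival and standardized differences

CS(y|x) is computed on unrounded survival values; percent rounding (one
decimal) and d rounding (two decimals) happen only at presentation. The
conditional matrix fills CS(total−x | x) for every x < total on the yearly
grid with an exact 100 diagonal; each row is non-decreasing in x because
S(x) decreases while the numerator S(total) is fixed.

For the standardized difference d = (P2 − P1)/√[P(1−P)], P is the *pooled
whole-cohort* conditional rate at the same time point. This convention was
fixed by independent arithmetic against the published subgroup tables: with
pooled P it reproduces the printed 0.82/0.27 (grade I vs III COS3 at
baseline/5 y) and 0.58/0.26 (chemotherapy CCSS3) to two decimals. The sign
convention is "A vs B" = (P_A − P_B), positive when the first-listed group
fares better. Bands: |d| < 0.1 none, 0.1–0.3 small, 0.3–0.5 moderate,
≥ 0.5 significant.

When ratios of printed one-decimal percentages disagree with a published
conditional cell in the last decimal, the discrepancy is attributable to
computation on unrounded curves upstream of printing; the package therefore
asserts exactness only for the worked examples that survive independent
arithmetic on printed inputs, and covers everything else by the
telescoping and survivor-subset identities.

## The synthetic cohort generator

The generator is the package's stand-in for a registry extract that cannot
be redistributed. It emulates:

- **Covariate mix.** Independent categorical draws reproducing the
  published marginals (60.8% aged < 65, 54.3% female, 79.5% white, 61.4%
  married, 19.6% grade III, 56.5% ≥ 15 cm, 86.1% unifocal, 24.0% LMS,
  52.7% complete resection; chemotherapy 13.4%, radiotherapy 24.7%,
  chemoradiotherapy 4.6% drawn jointly so chemoradiotherapy implies both
  components). Splits not published — the race minority levels, the
  unmarried/unknown marital split, grades I/II/unknown, the sub-15 cm size
  classes, the non-LMS histologies — were fixed once at plausible
  registry-like values and are ordinary configuration fields.
- **Effect structure.** Two independent latent piecewise-exponential
  clocks (cancer-specific and other-cause death), each scaled by
  exp(Σ log-HR) over the subject's covariate levels. The cancer clock's
  default log-HRs are the logs of the cohort's multivariable CSS hazard
  ratios; no other-cause model is published, so the all-cause (OS) ratios
  stand in on the other clock, which keeps the OS-side effect structure
  realistic. The latent-clock construction matches the cause-specific
  (not subdistribution) reading of CSS.
- **Censoring.** Uniform accrual over a 156-month window with
  administrative cutoff at the window's end — which reproduces the
  cohort's observed 0–155-month follow-up range exactly under month
  flooring — plus a small exponential loss-to-follow-up rate
  (0.0008/month).
- **Granularity.** Observed times are floored to whole months, making ties
  common on purpose; this stresses the tie conventions downstream.

Baseline hazards (per month, pieces at 0/12/36/60 months: cancer 0.00128,
0.00166, 0.00139, 0.00125; other 0.000295, 0.000375, 0.000317, 0.000500)
were calibrated by a coarse iterative simulation search so that pooled OS
tracks 89.8/71.8/60.8/48.2% at 1/3/5/8 years, pooled CSS the corresponding
91.9/77.1/67.8/58.2%, and the cancer-specific share of deaths sits near
75.5%. The calibration is a convenience default defining realistic study
conditions, not a claim of cohort-level reproduction.

What the generator does **not** model — and hence what green tests do not
establish about real registry data: covariate dependence beyond the
chemoradiotherapy constraint (real grade, size and histology are strongly
associated), calendar-period trends, age as a continuous confounder,
non-proportional hazards, informative censoring, and cause-of-death
misclassification. Parameter-recovery tests show the estimators are
correct under the generative model, not that the model is the registry.

## Problem sizes in the test suite

Deterministic identities run at hand-checkable sizes (≤ 12 records) against
brute-force oracles. Stochastic checks use sizes chosen for stable
Monte-Carlo behaviour: marginal frequencies at n = 10,000 (3 binomial SEs),
closed-form exponential and memorylessness checks at n = 20,000–40,000,
Cox parameter recovery at n = 5,000 over 100 seeded replicates (bias
< 0.05 on the log scale, ~95% Wald coverage), generator calibration at
n = 20,000 (3 Monte-Carlo SEs around 75.5%), and the end-to-end
determinism check at the cohort's published size n = 1,594.

## Known limitations

- No confidence intervals on conditional survival (none are published for
  the analysis the package reproduces; bootstrap CIs would be the natural
  extension).
- No landmark regression, cure-fraction or relative-survival modelling.
- The univariable screen's p < 0.05 carry-forward is the only model
  selection offered.
- The published multifocality hazard ratios (0.588 OS, 0.111 CSS,
  protective) run opposite to most of the surgical literature; the
  generator defaults to the published values and takes whatever the
  configuration says — the conflict is representable, not resolved.
- Schoenfeld-style proportional-hazards diagnostics are not bundled;
  `lifelines.CoxPHFitter.check_assumptions` can be applied to the same
  design matrix if needed.
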