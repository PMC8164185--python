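# Methods

This note documents the statistical models the package implements, the
defaults it ships, the choices made where a convention had to be picked, and
what the synthetic-data validation does and does not demonstrate.

## The measurement problem

Domestic violence is stigmatized, so self-reports in surveys are suppressed
by social desirability. The analysis this package implements therefore runs
two elicitation channels side by side:

* **direct questions** for less severe outcomes (verbal and physical
  conflict, emotional abuse, child corporal punishment), analyzed as
  binomial proportions and as binary outcomes in logistic risk models;
* **double list experiments** for severe/stigmatized outcomes (physical
  violence, non-consensual sex, violence against children), where the
  respondent never answers the sensitive question itself.

## Estimators

### Binomial prevalence

`estimate_prevalence` returns `100·x/n` with the Wald interval
`p ± 1.959964·sqrt(p(1-p)/n)`. The Wald form is the default because it is
the convention of descriptive survey tables and is exactly recomputable from
printed `(count, denominator)` pairs; Wilson and Clopper–Pearson are exposed
behind `method=` for sensitivity analysis but never used by the pipeline.
Percent formatting is half-up to two decimals. Intervals are not clipped at
0/100 unless `clip=True`; the clipping is flagged on the estimate.

### Double list experiment

Respondents are randomized 1:1 into arm A (sensitive item appended to list
1) or arm B (appended to list 2) and report only the count of applicable
statements per list. With `D_i` = sensitive-bearing count − control count,

```
tau_hat = (mean(D | A) + mean(D | B)) / 2
var     = (var(D|A)/n_A + var(D|B)/n_B) / 4
```

using n−1 sample variances and treating arms as independent. This is the
natural variance for the described design; the within-respondent difference
removes innocuous-item variation shared across lists. The CI may cross zero
and is reported as such — truncation would misstate the design's precision.
Respondents missing the arm or either count are dropped listwise per outcome
with a logged count. A diagnostic warns when more than 5% of respondents sit
at a list's floor or ceiling (piled-up counts break the protection and can
bias the difference in means); under the default innocuous-item mix the
expected floor/ceiling share is ≈3.8%, so occasional warnings in simulation
tails are expected and harmless.

`power_simulation` compares the double design with a same-`n` single-list
design by Monte Carlo; the double design's empirical SE is smaller (≈2.1 vs
≈2.9 points at n = 3818, truth 3.57%) and test size under a zero truth is
nominal.

### Scale scores

Items are z-scored (complete-case moments) and projected on the leading
eigenvector of their correlation matrix. Correlation rather than covariance
is used because Likert items have no shared natural unit. The loading sign
is fixed so the loading sum is positive, i.e. higher item responses score
higher; items must therefore be coded symptom/worry-positive before scoring
(reverse-coded items mirror the score exactly). Respondents missing some but
not all items receive a score from the available items rescaled by the
inverse available squared-loading mass and are flagged `partial`; fully
missing batteries yield NaN. Cronbach's alpha is complete-case with n−1
variances. Top-quintile flags cut at the empirical 80th percentile with ties
included above the cut; all-equal scores are an error because quintiles are
then undefined.

### Disclosure gradient

Reported prevalence of a direct outcome is tabulated by quintile of the
social-desirability score, with a Cochran–Armitage-style least-squares slope
of the individual binary report on the quintile index as the trend
statistic. The gradient characterizes misreporting qualitatively; it is not
used to correct estimates.

### Risk models

Each directly elicited outcome is modelled by maximum-likelihood logistic
regression. The default ("full") predictor set mirrors conventional
risk-factor tables: the pandemic block (home quarantine, top-quintile
financial worries, own/partner reduced work, top-quintile own/partner
mental-health scores, daily childcare hours, children under 10, children 10
or older) plus age per year, education (reference: middle school or less),
household income (reference: under €2000), own and partner employment, key
worker, household size and cohabitation. The child corporal-punishment model
runs inside the children subsample with "children ≥ 10 only" as the implicit
reference, rendered as OR 1.0 with no interval, as are all reference
categories. Separation is flagged per term (huge pooled SE ⇒ CI reported as
unbounded) rather than penalized, keeping the estimator a plain ML fit.

Partner mental health — observable only through the respondent's assessment
— is the imputation target. `chained_imputation` cycles Bayesian
normal-linear conditional draws (coefficients and error variance drawn from
their approximate posterior, then posterior-predictive imputations) for 10
cycles over m = 10 chains, each seeded from its own substream; with no
missing data it returns unmodified copies. Pooling follows Rubin's rules at
the coefficient level, including the full covariance matrix so that profile
predictions propagate imputation uncertainty. With m = 1 and no missingness
the pooled result equals a single complete-case fit exactly. Top-quintile
flags derived from an imputed score are recomputed within each completed
dataset.

Predicted probabilities for named profiles set the profiled design columns
and hold all others at analytic-sample means (averaged over imputations);
the interval is the delta method on the linear predictor mapped through the
inverse logit, hence asymmetric on the probability scale and always inside
(0, 100).

## The synthetic-data generator

The generator's defaults emulate the study conditions end to end:

* **n = 3818** partnered women; covariate marginals follow the published
  sample characteristics (quarantine 17.21%, cohabiting 90.99%, children
  <10 25.46%, education 33.24/28.13/38.63%, income 19.80/42.82/24.23/13.15%,
  etc.). The published combined "reduced work or furlough (woman or
  partner)" share of 28.58% is split into two independent Bernoulli(0.1552)
  flags. Age and childcare hours are uniform over 18–65 years and 0–12
  hours (distributions not published); household size is categorical with
  P(≥4) = 24.23%. Children flags are independent draws, giving a child
  subsample of ≈39% vs the study's 38.6%.
* **Scales**: one-factor Likert batteries, 5-point items cut at
  equal-probability normal thresholds. The factor loading is solved from the
  target alpha via the parallel-items identity α = kr/(1+(k−1)r), with the
  latent correlation inflated by the closed-form attenuation factor λ² of
  5-category discretization (λ = Σφ(tⱼ)/√((c²−1)/12) ≈ 0.942) so realized
  alphas land within ~0.02 of their targets (0.81, 0.83, 0.84, 0.69).
  Item counts (4/4/5/6) follow the typical lengths of the instruments the
  scales emulate; the published source states alphas but not k.
* **Latent outcomes**: logit p = b₀ + Σ log(OR)·x with the published
  risk-factor odds ratios per outcome; b₀ is calibrated by root-finding on
  the realized covariate draw so the marginal latent prevalence equals the
  configured target (the published point estimates). "Baseline prevalence"
  in the configuration therefore means the marginal, not the reference-cell,
  prevalence. List outcomes are i.i.d. Bernoulli at their targets, with no
  covariate structure, because indirect outcomes are excluded from
  regression modelling.
* **Disclosure**: p(disclose) = min(1, 2·expit(slope·z)) with z the
  standardized social-desirability score. This is a logistic curve rescaled
  so that a respondent at or below average sensitivity always discloses:
  slope = 0 is exactly the no-suppression identity, and negative slopes
  produce the observed negative prevalence gradient across
  social-desirability quintiles. The default slope −1.0 yields strong
  suppression in the top quintile (disclosure ≈0.4) and an average
  disclosure of ≈0.8, matching the qualitative published gradient; no
  numeric slope is published. Misreporting only suppresses — a direct
  report of 1 implies the latent indicator is 1.
* **Lists**: four innocuous items per list with endorsement probabilities
  {0.2, 0.4, 0.6, 0.8} — heterogeneous to avoid floor/ceiling pile-up (the
  real items' rates are unpublished). Counts are bounded by 4 on a pure
  control list and 5 on the sensitive-bearing list.
* **Missingness**: MCAR, applied last; defaults are 5% on the whole partner
  mental-health battery (the imputation target) and 4.71% on childcare
  hours, which reproduces the analytic-sample attrition 3818 → ≈3638 through
  listwise deletion. The published source does not characterize its
  missingness mechanism; MCAR is the neutral choice.

What the generator does **not** emulate: quota sampling and panel weighting,
item-level (as opposed to battery-level) nonresponse patterns, correlation
between the children-age flags, informative (MAR/MNAR) missingness,
respondent heterogeneity in innocuous-item endorsement, and any causal
structure among covariates. Passing recovery tests therefore demonstrates
that the estimators are correct under the stated design, not that the
original survey's estimates are right — in particular, MCAR missingness
makes imputation easier than a real not-able-to-assess mechanism would be.

## Validation design and problem sizes

* Double-list recovery: 1000 simulated surveys at n = 3818 with latent truth
  3.57%; the Monte-Carlo mean must sit within 3 MC standard errors of the
  truth and the mean CI width near the ~7.8-point span such a design
  produces. This is also what `scripts/acceptance.py` recomputes.
* Odds-ratio recovery: 300 simulated surveys at n = 3818 (analytic ≈3638
  after attrition), m = 10 imputations, fitting exactly the generating model
  — the pandemic block plus age. The generating model is fitted rather than
  a superset or subset because logistic odds ratios are non-collapsible;
  omitting generating covariates would bias estimates toward the null for
  reasons unrelated to implementation. Disclosure suppression is switched
  off in this study: non-differential under-reporting attenuates odds
  ratios, so coverage of the generating values is only a meaningful check
  without it. Pooled 95% intervals must cover their truths (2.38, 3.41,
  1.60, 1.07/hour; 5.31 for young children on corporal punishment) at
  95% ± 3 points.
* Disclosure gradient: 200 surveys at study scale; the fitted trend must be
  negative in ≥95% of them. Smaller samples were not used here because the
  trend test's power, not the gradient's existence, is what limits the rate.
* Published predicted probabilities (e.g. 25.17% for a high-risk physical
  conflict profile) are not recomputable without the original microdata; the
  profile machinery is instead validated by plug-in arithmetic, an
  intercept-only identity, and monotonicity checks.

## Numerical choices and edge cases

* z = 1.959964 (the two-sided 97.5% normal quantile) everywhere a 95%
  interval is formed; scipy's `norm.ppf` supplies other levels.
* Intercept calibration uses Brent root-finding on [−40, 40] with xtol
  1e−12; a zero-prevalence outcome short-circuits to an all-zero latent
  vector.
* Eigen-decomposition of symmetric correlation matrices uses `numpy.eigh`;
  a single-item scale degenerates to the z-scored item.
* Imputation regressions use `lstsq`/pseudo-inverse, so collinear predictor
  sets degrade gracefully; the error-variance draw is scaled inverse-χ².
* Logistic fits try Newton first and fall back to BFGS under perfect
  separation; terms with pooled SE ≥ 100 on the log-odds scale (or |coef| >
  30) are flagged and their CIs suppressed.
* Ties at quintile cuts always go to the upper quintile, both for flags and
  for quintile indexing, so the two views never disagree.
* All randomness flows from one integer seed through named `SeedSequence`
  substreams (covariates, scales, outcomes, disclosure, lists, missingness;
  one per imputation chain); configuration maps are iterated in sorted key
  order so logically equal configurations — including YAML round trips —
  generate byte-identical datasets.

## Known limitations

* The list-experiment estimator is design-based difference-in-means only; no
  maximum-likelihood or covariate-adjusted item-count estimators, matching
  the analysis it implements.
* MCAR-only missingness generation; the imputer assumes a normal-linear
  conditional model and imputes continuous targets only (flags derived from
  imputed scores are recomputed per completed dataset).
* No survey weights, no causal identification, no interaction terms beyond
  subgroup refits the caller can express by filtering rows.
* Wald intervals degenerate at p ∈ {0, 1}; the alternative interval methods
  exist for exactly that situation.
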