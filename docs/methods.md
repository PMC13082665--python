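# Methods notes

## Model and estimands

The screen treats each two-arm trial comparison as yielding one draw of the
log coefficient-of-variation ratio (lnCVR), treatment over control. The
estimand is the trial-specific *true* lnCVR; across a body of comparable
trials the true values are modeled as $N(M^*, \tau^2)$. The decision rule
flags a comparison when its observed lnCVR is both statistically significant
and outside a k-sigma prediction interval for a new trial's true effect.

The bias-corrected lnCVR point estimate and its delta-method variance
(per-arm contribution $CV^2/n + CV^4/(2n^2) + 1/(2(n-1))$, summed over
arms) assume approximately normal outcomes within arms and moderate CVs;
the variance form was validated against a simulation oracle (empirical SD
over $10^5$ normal trials within 1% of the formula at n = 50, CV = 0.2).
Significance uses $t = \widehat{\mathrm{lnCVR}}/\mathrm{SE}$ against a t
reference with Welch–Satterthwaite df formed from the two per-arm variance
contributions, $df = (v_T+v_C)^2 / (v_T^2/(n_T-1) + v_C^2/(n_C-1))$. How
the df should be formed for a log-ratio statistic is a genuine design
choice; the per-arm Satterthwaite form was adopted because it collapses to
$2(n-1)$ for symmetric arms and converges to the normal reference (checked
to $10^{-3}$ in p at $n = 10^4$), and the realized type-I error under
gamma nulls at n = 50 sits within Monte-Carlo error of the nominal 0.05.

lnVR ($\ln(s_T/s_C)$ with the analogous $1/(2(n-1))$ corrections) and
$\ln F = 2\,\mathrm{lnVR}$ use the standard bias-corrected forms. An exact
F-test p-value is available for lnF; its rejection decisions agree with the
t approximation in ≥99% of null trials at n ≥ 50.

## Tolerance bands

The reference distribution is fit by inverse-variance random effects.
$\tau^2$ defaults to REML (1-D profile optimization of the restricted
likelihood, bounded at 0), with DerSimonian–Laird as an option; the two
differ negligibly on well-behaved reference sets, and DL is cross-checked
against an independent implementation in the tests. For independent
estimates the prediction interval uses $df = k - 2$ and the model-based
$V_{M^*} = 1/\sum w_i$.

When a trial contributes several estimates (multi-arm trials sharing a
control, multiple post-intervention time points) the estimates are
correlated and the trial becomes the cluster. $V_{M^*}$ then uses a CR2
small-sample cluster-robust sandwich. For the intercept-only weighted model
the CR2 adjustment matrix $(I - H_{jj})^{-1/2}$ has a rank-one structure
and acts on the cluster weight vector as the exact scalar
$(1 - h_j)^{-1/2}$, where $h_j$ is the cluster's leverage
$\sum_{i \in j} w_i / \sum w$; the implementation uses this closed form.
The Satterthwaite df uses the Bell–McCaffrey trace formula
$(\mathrm{tr}\,\Omega)^2/\mathrm{tr}(\Omega^2)$ with $\Omega$ assembled in
observation space.

Tukey fences use Tukey hinges (median-of-halves, halves sharing the middle
observation at odd n) as the declared quartile convention — conventions
differ across software and the fence positions depend on it, so it is fixed
and unit-tested. The bootstrap resamples whole trials with replacement,
relabeling each drawn trial as a new pseudo-cluster so the refitted k is
preserved, and reports 95% percentile intervals of each band bound.

Reference-set eligibility mirrors the screening workflow: comparisons whose
dispersion was derived under homogeneity-of-variance assumptions are
excluded from band fitting, as are trials whose baseline-plausibility
screen is < 0.025, > 0.975, or missing.

Coverage note: the k-sigma prediction interval targets the *true* effect of
a new trial. The *observed* lnCVR of a new small trial carries additional
sampling noise not included in $\sqrt{T^2 + V_{M^*}}$, which is precisely
why the observed-effect flagging rule also requires statistical
significance before calling a value an outlier.

## Simulator

The generator emulates a diabetes-trial setting: strictly positive,
right-skew post-intervention HbA1c modeled as gamma with mean 8.0% and SD
1.5% (typical diabetic values; configurable). Each simulated trial draws a
true lnCVR $\theta \sim N(M^*, \tau^2)$ and gives the treatment arm
$CV_T = CV_C e^{\theta}$ at the same mean. Defaults $M^* = -0.035$,
$\tau = 0.166$ are back-derived from the reference 3-sigma band
(−0.54, 0.47) as its midpoint and half-width/3.01, treating $V_{M^*}$ as
negligible; the band itself is the default for flagging, and a k-sigma
variant keeps the midpoint and scales the half-width by k/3.

Mechanisms act on individual draws before summarization. Heterogeneous
treatment effects: a uniformly random responder subset of the treatment arm
receives an additive shift (values pushed ≤ 0 are floored at $10^{-6}$,
logged; untruncated shifts never occur at the default parameters).
MNAR dropout: the highest-valued fraction of the *control* arm is deleted
and n shrinks — an intentionally extreme informative-dropout stress test.
Fraud duplication: the highest-valued fraction of the *treatment* arm is
replaced by copies of that arm's single lowest value, n preserved.
"Worst" = highest HbA1c, "best" = lowest. Replacement counts are
`round(fraction * n)`; RNG consumption order is fixed so degenerate
mechanism parameters reproduce the no-mechanism stream bit-for-bit.

What the generator does **not** emulate: ceiling/floor effects,
non-gamma outcome families, compliance dynamics, correlated multi-time-point
reporting within a trial, and rounding of published summaries. Passing
operating-characteristic tests therefore demonstrate behavior under the
stated stochastic model, not under every real-world reporting pathology.

## Problem sizes and numerical choices

Scenario cells run 1,000 iterations (Monte-Carlo SE ≤ ~0.016 for a
proportion), matching the scale at which the reference operating
characteristics are quoted; property tests use $10^3$–$10^5$ replicates as
appropriate for the tolerance being checked, and the prediction-interval
coverage check uses 30 reference sets of k = 175 trials. REML optimization
is bounded at $\tau^2 \in [0, \max(10\,\mathrm{var}(y), 10\max v_i)]$ with
`xatol=1e-10`, falling back to 0 when the boundary is preferred. Ties in
highest/lowest values are broken by stable sort order. Flag boundary
handling is conservative: a value exactly on a band bound is inside. A
trial arm that shrinks below 2 observations or loses all spread after a
mechanism raises a degenerate-trial error; scenario runs skip and count
such trials (none occur at the default grids).

The fraud-sensitivity figures are the quantities most sensitive to the
outcome-distribution defaults, since they hinge on the spread of the lowest
order statistics of a gamma sample; with the defaults above they reproduce
reported values to within a few percentage points, and the package treats
±3 percentage points as the parameter-default tolerance when comparing.

## Known limitations

- lnCVR requires strictly positive means and reported SDs; comparisons with
  SE/SD ambiguity are handled only through explicit column typing
  (`dispersion_type`), with SE converted as $sd = se\sqrt{n}$ and logged.
- Small reference sets (k near 3–10) give unstable $\tau^2$ and wide,
  noisy bands; the CLI surfaces k so users can judge.
- The baseline-plausibility screen implements the continuous
  summary-statistic t-test + Stouffer path only; categorical baseline
  variables and Monte-Carlo variants of such screens are out of scope.
- Specificity/sensitivity statements transfer to outcomes other than HbA1c
  only after re-deriving the five generator parameters (outcome mean and SD,
  $M^*$, $\tau^2$, $V_{M^*}$) for that outcome.
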