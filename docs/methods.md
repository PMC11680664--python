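# Methods

## The model

The package analyses *retention datasets*: series of (delay `t` in seconds,
proportion remembered `M`) pairs with at least three delays, the minimum
needed to compare two-parameter curves. Five classical families are
considered, each with a scale parameter `a` and a rate parameter `b`:

| family             | equation            | notes |
|--------------------|---------------------|-------|
| logarithmic        | `M = a − b·ln t`    | constant proportional loss per log-time unit |
| power              | `M = a·t^b`         | `b < 0` for loss; undefined at `t = 0` |
| exponential-power  | `M = a·e^(−b·√t)`   | Weibull with shape ½ |
| hyperbolic-power   | `M = 1/(a + b·√t)`  | `a` lives on the reciprocal scale |
| linear             | `M = b·t + a`       | constant absolute loss per second |

The logarithmic and linear families can leave [0, 1]; a boundary constraint
(clamping into the unit interval) is applied uniformly at prediction and
plotting time. Clamping is deliberately kept **out** of the least-squares
residuals: the boundary is a conceptual constraint on what a proportion can
be, not part of the fitting criterion, and clamped residuals would flatten
the loss surface exactly where the fit is worst.

## Fitting

Logarithmic and linear fits are ordinary least squares in closed form
(`M` on `ln t` and on `t`). The three remaining families are fitted by
nonlinear least squares (`scipy.optimize.curve_fit`) minimising
`Σ (M − f(t))²` in untransformed proportion space, so that r² — computed as
`1 − SSE/SST` on the same scale — is comparable across families. The family
with the highest r² is the best fit; ties within 1e−10 break by the fixed
reporting order (logarithmic, power, exponential-power, hyperbolic-power,
linear) and are flagged.

Nonlinear fits are started from each family's linearising transform
(log–log regression for power, `ln M` on `√t` for exponential-power, `1/M`
on `√t` for hyperbolic-power; proportions floored at 1e−6 inside the
transform only), surrounded by a 3×3 ±50 % multi-start grid. Two further
start families guard against datasets whose proportions hit 0, where the
global transform is dominated by the floor: starts solved exactly through
the (floored at .02/.08) first and last observations, and a 1-D profile
scan over the rate parameter with the scale solved in closed form at each
candidate rate. Every start's own SSE participates in the comparison, so a
diverging polish step can never lose a good start. In testing this fitter
matches or beats a dense (a, b) lattice search on random 3–6-point series.

Degenerate datasets (zero variance in `M`) are never fitted — r² is
undefined there — and are routed to net-change classification directly.

## Classification

Each dataset receives exactly one label:

1. **no net change** if the proportion at the longest delay minus the
   proportion at the shortest delay lies in the closed band [−.01, +.01]
   (no fit is consulted);
2. **increasing** if the net change exceeds +.01 (a linear fit is attached
   for typical-curve rendering);
3. otherwise the best-fitting family, provided its r² ≥ .5;
4. **removed** if the best fit of a loss dataset falls below r² = .5 —
   a threshold about two standard deviations below the corpus-typical mean
   best fit — meaning none of the candidate shapes describes it.

Flat and increasing datasets are never removed, whatever their fit quality.
Net change is evaluated on the observed proportions (the sum of successive
changes telescopes to the same value); a per-interval mean-change variant is
reported in the trim report. Trimming partitions the corpus and summarises
both groups (count, mean best r², amount-of-data and retention-interval
statistics) so removed datasets can be compared with retained ones.

## Prevalence and typical curves

The headline summary weights each retained dataset by its total amount of
data (participants × observations per participant) so small studies do not
skew the picture; unweighted summaries are available, and the weighting
choice only matters when weights differ across categories. A category's
typical curve evaluates its family at the element-wise median of the
members' fitted (a, b) — not the member curve closest to the median — with
no-net-change drawn flat at the median initial level and increasing drawn
from the median linear fit. The default plotting grid is log-spaced from
1 second to 68 years, the span of the survey corpus.

## Study-characteristic analyses

Thirteen numeric covariates (publication year, material complexity 1–7,
multiple-study flag, degree of learning 1–4, distractor flag, design,
amount of data, number of retention intervals, shortest/longest/average
interval, interval range, initial memory) are screened for collinearity at
|r| ≥ .70. The documented reduction drops interval range (r ≈ .99 with the
longest interval), the shortest and average intervals, and degree of
learning (r ≈ .77 with complexity), leaving nine predictors; a generic
greedy mode is available for other corpora. Delay-scale predictors are
log10-transformed by default — delays span ten orders of magnitude, and raw
seconds would let a handful of decade-scale studies dominate any linear
analysis.

Each retained factor is tested by one-way ANOVA across the seven patterns
(partial η² = SSB/(SSB+SSW)), with Tukey HSD pairwise comparisons: the t
statistic uses the pooled within-group mean square, the adjusted p comes
from the studentized-range distribution, and Cohen's d uses the pooled SD
of the two groups compared. p < .05 is reported as significant and
p < .10 as marginal. One-vs-rest logistic regressions predict membership
in each pattern from the z-scored retained predictors (z-scoring makes the
reported z statistics scale-free; the intercept-only base rate is absorbed
by the constant). Perfect separation falls back to a ridge-penalized fit,
flagged as such with no Wald statistics. Because the seven regressions are
fitted independently, predicted probabilities across categories need not
sum to one.

A small C4.5-family decision tree (binary threshold splits chosen by
information gain ratio, configurable depth and minimum leaf size) is
provided as a guide for predicting the likely pattern from study
characteristics. It is written in-package because no installed library
implements gain-ratio trees (CART implementations use Gini/entropy without
the split-information normalisation). It is a guide, not a verdict: it is
trained on noisy, possibly biased corpora, and unseen or missing predictor
values route to the majority child with a warning.

## The synthetic-data generator

The generator emulates the structure of the survey corpus so every pipeline
stage is testable without downloads. Each dataset draws a pattern from a
mixture (defaults: curvilinear loss families most common, a sizable
minority flat or increasing), 3–10 log-spaced delays whose span covers
2–4.5 decades below a category-typical longest interval, and proportions
from the generating curve plus additive Gaussian noise (default sd .01 in
proportion units) clamped to [0, 1]. A binomial observation model
(`Binomial(n, M)/n`) is available as the more literal account of how
proportions arise. Curves are parameterised by their initial level
(category means ≈ .57–.81, grand mean near the corpus-typical .73) and the
fraction retained at the longest delay (25–60 % for loss categories), so
every trajectory starts in a realistic range and shows substantial,
clearly shaped loss.

Covariates are drawn with category-conditional shifts mirroring the
empirical per-pattern profiles: flat/increasing/linear datasets get longer
longest intervals, power datasets simpler single-exposure materials,
exponential-power datasets higher initial memory and more distractor
tasks, increasing datasets lower initial memory, and so on. This is what
makes association-recovery tests meaningful: the logistic regressions and
the guide tree are asked to find directions that are genuinely planted.

What the generator does **not** emulate: the empirical joint distribution
of the deposited survey corpus (only its marginal structure and association
directions), reporting artifacts (rounded proportions, heaped delays),
within-paper clustering of conditions, and measurement error that varies
with sample size. Passing recovery tests therefore show that the pipeline
is correct and well calibrated under a realistic data-generating process —
not that any particular empirical corpus obeys one of these five families.

### A calibration limit worth knowing

With elementwise noise of sd σ, the observed net change of a truly flat
dataset is distributed N(0, 2σ²). At σ = .01 only ≈ 52 % of flat datasets
land inside the ±.01 stability band (≈ 57 % after clamping), so flat-pattern
recovery is intrinsically capped far below the ≥ 90 % achieved by the other
patterns at that noise level; recovering flat patterns at 90 % would require
σ ≲ .004 or a wider band. The recovery suite reports this rate alongside
the others rather than hiding it.

## Numerical choices

* Time is always seconds internally; a leading 0-second delay is replaced
  by .01 s (nominally immediate tests) or an instruction-time estimate
  (default 30 s) before fitting, since several families are undefined at 0.
* The natural logarithm is used for the logarithmic family.
* The stability band is closed at both ends; boundary behaviour is tested
  on float-exact constructions.
* The trim threshold (.5), stability band (±.01), weighting scheme,
  reduction mode and tree hyperparameters are configuration defaults, not
  hard-coded constants.
* `converged=False` on a fit means every optimizer start failed; the best
  evaluated candidate is still reported so r² is always defined for
  non-degenerate data.

## Problem sizes

The bundled studies use a 500-dataset recovery corpus (noise sd .01, five
intervals per dataset), a 400-dataset corpus for covariate analyses,
200 replicates per family for rate-parameter bias, and 1,000 label shuffles
for ANOVA calibration — sizes at which the stochastic checks are stable to
a few percent while the whole study runs in well under a minute.

## Known limitations

* The three-parameter exponential-power generalisation `M = a·e^(−b·t^c)`
  is noted but not fitted; only two-parameter families are compared.
* Model comparison is by raw r² (as in the survey tradition this follows),
  not AIC/BIC; with all families at two parameters the rankings coincide,
  but r² differences carry no calibrated evidential weight.
* Logarithmic and power fits are near-collinear on realistic designs
  (fit-quality correlation ≈ .99 in the bundled studies), as are
  exponential-power and hyperbolic-power; confusions within those pairs are
  expected and, for log/power, reported separately.
* The guide tree makes no claim of matching any particular external C4.5
  implementation split-for-split.
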