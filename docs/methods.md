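# Methods

This note documents the models, the synthetic-cohort generator, the
numerical conventions and the deliberately open design choices in
`graftree`. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survival tree

**Model.** A node containing subjects with 0/1 failure indicators `c_i` and
observation times `t_i` (months) is summarised by the observed event rate
`lambda = sum(c)/sum(t)` and the per-subject Poisson deviance
`D = (1/N) sum_i [c_i log(c_i/(lambda t_i)) − (c_i − lambda t_i)]`, with
`0·log 0 = 0` (required for event-free nodes; the limit is exact). This is
the deviance of a constant-rate (exponential) survival model: each subject
contributes an exposure `t_i` and a count `c_i`, and the node's fit is the
maximum-likelihood rate.

**Split search.** The split criterion is the deviance improvement
`D_parent − (D_left + D_right)`. The `1/N` normalisation makes the printed
statistic ambiguous under differing child sizes, so the search and the
pruning threshold use the unnormalised sums (Σ-form), for which the
improvement equals the Poisson log-likelihood-ratio statistic and is
provably nonnegative; the per-subject `D` is retained on every node for
reporting. Within a node the linear term of the Σ-form vanishes and
`sum(c log t)` is partition-invariant, so the improvement reduces to
`f(E_l,T_l) + f(E_r,T_r) − f(E_p,T_p)` with `f(E,T) = E log(E/T)` on the
children's event/time sums — one cumulative-sum pass per sorted covariate.

Candidate cuts for ordered covariates are midpoints between consecutive
distinct observed values. Categorical covariates are ordered by per-level
event rate and scanned as if ordered; for a one-parameter exponential-family
criterion with exposure weights the optimal subset is a prefix of this
ordering, so the scan is exact without 2^k enumeration (verified against
exhaustive subset enumeration in the tests). Ties in gain break toward the
lowest covariate index, then the lowest threshold, for cross-platform
determinism. Gains below `1e-10` times the statistic's scale are treated as
zero so pure nodes are not split on float noise.

**Stopping and pruning.** Growth stops at `maxdepth` (`maxdepth = 1` is a
root-only tree), below `minsplit` subjects, or when no positive-improvement
split exists. Pruning removes any split whose Σ-form improvement is below
`cp` times the root's Σ-form deviance (`N·D`, rpart-style relative scale),
discarding its subtree; negative `cp` disables pruning entirely — the
protocol tables' `cp = −1` rows are interpreted this way, since rpart
forbids negative values and the only coherent reading is "no complexity
constraint".

**Prediction.** A leaf predicts the hazard ratio `leaf rate / root rate`
(root HR exactly 1). Rows with a missing value at a split covariate are
routed in the majority direction recorded at fit time and the fallback is
logged: fitting requires fully observed covariates (impute or use
complete cases first), so the fallback should only fire on degraded inputs
at prediction time. Each node also carries a shrunken ratio
`((E + 1/2)/(T + (1/2)/rate_root))/rate_root`, strictly positive even for
event-free leaves; it exists only so ensembles can average on the log scale
without `log 0`, and all reporting uses the exact HR.

## Horizon classification and censoring handling

`GiniTreeClassifier` is a weighted binary CART (unnormalised weighted Gini
decrease, same split machinery). `minsplit`/`minbucket` bound total instance
*weight* rather than row counts, so a censored subject split into a weighted
positive/negative pair still counts as one subject.

Labelling at horizon `h` years: an observed failure by `h` is positive;
follow-up beyond `h` without an earlier event is negative; censoring short
of `h` is indeterminate. *Use One* TRUE admits short-follow-up failures as
positives; FALSE excludes them. *Zupan weighting* replaces exclusion of the
indeterminate subjects with two weighted copies, negative with weight
`S(h)/S(t_c)` and positive with `1 − S(h)/S(t_c)`, i.e. the Kaplan–Meier
conditional probability of surviving to the horizon given survival to the
censoring time. The source protocol names the weighting scheme without
restating it; the KM conditional-probability form is the published scheme
matching its description, and it reduces exactly to complete-case labelling
when nothing is censored (tested). The KM curve is always estimated on the
training partition only, never on test data.

The first-year acute-rejection coding conditions are implemented as a
configurable map. The published conditions assign an early (<1 year)
rejection code 0 on the adequate-follow-up path but code 1 on the
short-follow-up-failure path — a contradiction we surface rather than
resolve: the default `"verbatim"` map reproduces the printed text, and an
alternate `"within1yr-positive"` map codes any rejection within 12 months
as 1, which is how the fitted trees treat first-year rejection. Code 2
("not treated") marks rows the rules leave undetermined; callers drop them
from training.

## Ensembles

Bagging draws bootstrap resamples; the random forest additionally samples
`mtry` covariates at *every node* (not per tree). Per-tree randomness comes
from spawned substreams of one seed sequence, so growing B+1 trees leaves
the first B unchanged, and `mtry = p` reproduces bagging exactly. Survival
ensembles aggregate the per-tree log hazard ratio (reported as the
geometric-mean HR, preserving the ratio-to-root semantics); event-free
leaves substitute their shrunken HR as described above. Classification
ensembles average leaf fractions, with plurality vote behind a flag.
Out-of-bag indices are recorded per tree; `oob_concordance()` scores
OOB-averaged risks. Covariate importance is the total Σ-form improvement
per covariate across trees, normalised to sum to one.

## Chained-equation imputation

`MiceCartImputer` initialises missing cells by marginal draws from the
observed values, then sweeps columns in descending missing-rate order
(stabilises the chains; configurable), refitting a CART on the currently
completed other columns and redrawing the column's missing entries from the
terminal node's donor pool — continuous targets use variance-reduction
splits, categorical targets multiclass Gini, and in both cases an imputed
value is always an observed value. Defaults `m = 5` chains, `n_iter = 10`
sweeps (the conventional chained-equation settings; the source protocol
states neither). `conditional_model="random-sample"` degrades to marginal
draws, used as the comparison arm in tests. Observed cells are never
altered. Downstream, the pipeline fits a model on each completed dataset
and averages *predictions* on the model's natural scale (log-HR or
fraction), not coefficients; the training and test partitions are imputed
separately so test rows never enter a training donor pool.

## Evaluation

Harrell's concordance: comparable pairs are those where the strictly
smaller time carries an event; concordant when that subject has the larger
risk; tied risks count 1/2; time ties (including double events) are not
comparable; zero comparable pairs raises an undefined-result error rather
than returning a number. The weighted AUC is the weighted Mann–Whitney
statistic with the same tie convention. Kaplan–Meier estimation delegates
to lifelines and is wrapped as a right-continuous step function with
`S(0) = 1`.

Partitioning stratifies every split and fold on the event indicator, drawing
`round(fraction · n)` per class (half away from zero). The protocol tables
use test ratio 0.3 with 5-fold inner cross-validation or a 0.285
one-validation split; the methods text describes 80/20 with 10-fold
cross-validation. Both are expressible in `SplitPlan`; the defaults follow
the tables because they parameterize the reproduced protocol rows. The
0.285 validation ratio is taken as a fraction of the non-test data.

## Baselines

Cox proportional hazards maximises the Breslow partial likelihood by
Newton–Raphson with step halving (convergence at max |score| < 1e-8 or 50
iterations), on internally standardized covariates with coefficients
reported on the original scale; tied event times share the full risk set
(Breslow — the simplest consistent tie handling, matching common defaults).
Logistic regression is weighted IRLS with the same conventions. In both
models a standardized coefficient exceeding 10 in absolute value (an odds
or hazard ratio of e^10 per standard deviation) is taken as evidence of a
monotone likelihood and flagged as non-converged separation. Penalised
(ridge/lasso) variants are deliberately out of scope: they are named in the
source abstract but given no settings or results to reproduce.

## Synthetic cohort generator

The generator emulates the structure of a three-center transplant registry
(n = 3,117, 9.8% graft failure, 85-month mean follow-up) whose records are
not public. The packaged roster mirrors the published baseline tables: 35
mixed continuous/binary/categorical covariates with the printed marginal
means, frequencies and per-column missing rates (donor-specific antibody at
81%).

**Outcome model.** Event times are exponential given covariates — the
constant-rate assumption implicit in the tree's deviance statistic — with
log-hazard effects for first-year rejection (log 4.27), a 3-month
creatinine threshold at 1.65 mg/dl (log 3.01) and a recipient-age threshold
at 59.5 years (log 2.39). A piecewise-constant extension concentrates these
effects in a 36-month acute phase, after which they are attenuated to 25%;
this is switched on in the packaged default because a purely constant
hazard makes discrimination essentially flat across prediction horizons
(the true-risk AUC does not decay), whereas the study's horizon profile
falls steeply from 1 to 10 years — early graft loss driven by identifiable
acute factors, late loss closer to random attrition. The
maintenance-regimen covariate (cyclosporine vs tacrolimus) keeps a chronic
(non-attenuated) hazard effect and is tied to the transplant era: its
prevalence tracks the administrative follow-up window, reproducing the
era–treatment–censoring confounding of an 18-year retrospective registry.
The baseline rate (0.000545/month) was set by bisection so a pilot cohort
hits the 9.8% event fraction; the helper `calibrate_baseline_rate` exposes
this calibration.

**Censoring.** The censoring time is the minimum of a uniform
administrative window (28–219 months, the potential follow-up implied by a
1997–2012 transplant era observed until early 2015) and exponential dropout
(0.0045/month, set so the mean observation time lands near 85 months).
Censoring is independent of the outcome given covariates.

**Missingness.** Injected after generation (the complete table remains
available as ground truth), per-column MCAR at the printed rates by
default, with a MAR mechanism conditioned on a named column for tests. Time
and event are never masked.

**What the generator does not emulate.** Correlations among covariates
(beyond the era–regimen link), competing risks (death with a functioning
graft — the event is a single absorbing state, and whether the published
outcome was death-censored is unstated), informative censoring given
covariates, time-varying covariates, and structured (era-blocked)
missingness: the real registry's missingness is concentrated in covariates
introduced mid-study, so its complete-case subset is much larger than
independent per-column masking would produce. Passing tests on this
generator therefore demonstrate correctness of the algorithms and
qualitative reproduction of the study's phenomena, not clinical performance
on real registry data.

## Problem sizes and determinism

Unit and property tests run on cohorts of a few hundred to a few thousand
rows; oracle-equivalence properties use exhaustive enumeration on nodes of
up to 30 subjects and 3 covariates (200+ random instances). The pipeline
ordering check compares the model families twenty times; each comparison
averages the best-cell test-concordance gap over five replicate n = 3,117
cohorts, each evaluated with five inner partition seeds, using symmetric
(cp, maxdepth) grids assembled from the published protocol rows. The
replication is needed because the survival tree's systematic advantage
(~0.01 concordance) is comparable to single-cohort sampling noise. The horizon-AUC profile is averaged over three cohorts and
five partition seeds before computing its rank correlation with horizon.
All randomness flows through explicit integer seeds or spawned
`SeedSequence` substreams; identical seeds give byte-identical cohorts,
partitions, trees and ensembles.

## Known limitations

- The Σ-form/`1/N` reconciliation means the node-displayed deviance is the
  per-subject statistic while split decisions use sums; both are exposed.
- Hazard-ratio leaves are maximum-likelihood rates without shrinkage;
  small leaves can print extreme HRs (the ensembles, not single trees, are
  the variance-controlled estimator).
- The Cox implementation targets the cohort sizes here (10^3–10^4 rows,
  tens of covariates); it makes no attempt at the sparse or stratified
  cases a production survival library handles.
- `UndefinedMetricError` (no comparable pairs / single-class input) is a
  deliberate hard signal; pipeline tables record such cells as NaN.
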