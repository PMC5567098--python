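# graftree

Survival decision trees and censoring-aware learners for predicting kidney
allograft failure.

## The problem

After a kidney transplant, roughly one recipient in ten loses the graft over
the following decade, and the follow-up of everyone else ends early — by the
administrative close of the records or by dropout. Predicting graft failure
from registry-style tables (recipient demographics and comorbidities, donor
factors, immunological markers, 3-month post-transplant labs, first-year
rejection/infection episodes) therefore means learning from *censored*
outcomes: for most patients we only know the graft survived *at least* t
months. Conventional classification trees either discard these subjects or
mislabel them, and both choices bias the model when the event rate is low.

`graftree` implements an analysis stack built around a decision tree whose
split rule is a survival statistic rather than a class-purity index, plus the
censoring-aware machinery needed to compare it fairly against conventional
learners on this kind of cohort.

## The core model

Each tree node summarises its subjects by the observed event rate

    lambda_hat = sum_i c_i / sum_i t_i

(`c_i` the 0/1 graft-failure indicator, `t_i` the observation time in
months) and by the within-node Poisson deviance

    D = (1/N) * sum_i [ c_i log(c_i / (lambda_hat t_i)) - (c_i - lambda_hat t_i) ]

with `0·log 0 = 0`. Recursive partitioning chooses, at every node, the
covariate and cut that maximise the deviance improvement
`D_parent − (D_left + D_right)` (computed on the unnormalised sums, where it
is the Poisson likelihood-ratio statistic and provably nonnegative). Leaves
predict a **hazard ratio**: the leaf's event rate divided by the cohort-wide
(root) rate. Cost-complexity pruning removes splits whose improvement falls
below `cp` times the root deviance; `cp = -1` disables pruning.

Around the core tree the package provides, all as scikit-learn-style
estimators with `fit`/`predict`/`get_params`:

- `SurvivalTree` — the Poisson-deviance tree above;
- `GiniTreeClassifier` — a weighted-Gini CART for "failure by N years"
  classification, with the published censoring rules: *Use One* TRUE/FALSE
  (whether short-follow-up failures enter training) and *Zupan weighting*
  (a subject censored at `t_c` before horizon `h` enters as a negative with
  weight `S(h)/S(t_c)` and a positive with the complementary weight, `S`
  the training Kaplan–Meier curve);
- `SurvivalEnsemble` / `ClassificationEnsemble` — bagging and random
  forests (node-level covariate subsampling) over either tree;
- `MiceCartImputer` — chained-equation multiple imputation with CART
  conditional models and donor-pool draws;
- `CoxPH`, `WeightedLogisticRegression` — directly implemented baselines
  (Newton–Raphson on the Breslow partial likelihood; weighted IRLS);
- `metrics` — Harrell's concordance index, weighted AUC, Kaplan–Meier,
  event-stratified train/test/fold partitioning;
- `pipeline` — a settings-grid runner (attribute subsets × imputation ×
  censoring handling × tree hyperparameters, averaged over seeds) and a
  1–10-year horizon-AUC table;
- `cohortgen` (module `graftree.cohort`) — a synthetic transplant-cohort
  generator whose packaged defaults mirror the published cohort structure:
  n = 3,117, ~9.8% graft failure, ~85-month mean follow-up, 35 mixed-type
  covariates with per-column missingness up to 81% (donor-specific
  antibody), era-dependent administrative censoring, and the headline
  effects (first-year rejection HR 4.27, 3-month creatinine cut-off
  1.65 mg/dl, recipient-age threshold).

## Worked example

```python
import numpy as np
from graftree import (default_covariates, default_hazard, generate_cohort,
                      SurvivalTree, concordance_index, make_partitions, SplitPlan)
from graftree.tree import render_text
import dataclasses

covs = [dataclasses.replace(c, missing_rate=0.0) for c in default_covariates()]
cohort = generate_cohort(3117, covs, default_hazard(), seed=7)
parts = make_partitions(cohort, SplitPlan(test_ratio=0.3, seed=7))

tree = SurvivalTree(cp=0.01, maxdepth=4).fit(
    cohort.data.iloc[parts.train],
    time=cohort.time[parts.train], event=cohort.event[parts.train])
print(render_text(tree))
risk = tree.predict(cohort.data.iloc[parts.test])
print("test C =", round(concordance_index(
    cohort.time[parts.test], cohort.event[parts.test], risk), 3))
```

prints the fitted rule list and its test concordance:

```
rejection_1yr <= 0.5?
Y:
  HR = 0.79 (n = 1870)
N:
  creatinine_3mo <= 1.67811?
  Y:
    anion_gap_3mo <= 14.0678?
    Y:
      HR = 1.19 (n = 226)
    N:
      HR = 19.69 (n = 8)
  N:
    HR = 6.22 (n = 78)
test C = 0.629
```

Reading the tree: subjects with no first-year rejection episode carry a
hazard 0.79 times the cohort average, while rejection followed by a 3-month
creatinine above ~1.68 mg/dl multiplies the hazard by ~6 (the `Y` branch
answers the node's question affirmatively; the recovered creatinine cut is
close to the 1.65 mg/dl used to simulate the cohort). The concordance index
is the fraction of comparable patient pairs whose predicted risks order the
same way as their observed failure times (0.5 = chance).

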