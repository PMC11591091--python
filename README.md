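# diabkit

Computational core of a mobile diabetes-management workflow: estimate food
weight from a single tilted-phone photograph, convert diet records into
nutrient intake through a food-composition database, classify the
direction of a patient's HbA1c change from personal, lifestyle, nutrient
and baseline medical features with a SMOTE + stacked ensemble, and rank
the risk factors behind the prediction with Shapley-style attribution.
Synthetic scene and cohort simulators with known ground truth make every
stage testable end to end without any external data.

## Who it is for

Researchers building or auditing diet-tracking / diabetes-progression
pipelines who need the quantitative pieces — perspective geometry, intake
accounting, imbalanced three-class modelling, attribution — as tested
library code with explicit protocols (oversampling strictly inside
training folds, out-of-fold stacking, leakage audits).

## The models

**Photo geometry.** A phone of camera length p leans on the table at tilt
α; the camera sits at A = (p cos α, p sin α) and the near field-of-view
boundary ray crosses the table at l_OB = p sin β / sin(α + β), with β a
phone-model constant. A food at image-height fraction k = a/b is seen
along the pinhole ray n + (2k − 1) cot β · u (optical axis n ⊥ phone body
u), whose table intersection is the shooting distance l_OC. The projected
area is S = (mask pixels) × pitch². The implementation is validated
against an independent numerical ray caster to 1e−6 relative error; a
published closed form with a dimensionally inconsistent final step is
kept behind `mode="literal"` for audit only.

**Weight.** LASSO regression of weight on (type indicators, α, l_OC, S,
S×type), standardised features, unpenalised intercept, λ by internal
5-fold CV; predictions clamped at 0 g.

**HbA1c change.** y ∈ {0 no change, 1 increased, 2 decreased} from
HbA1c(exam 2) − HbA1c(exam 1); 111 predictors (second-exam block dropped).
Classifier: XGBoost + calibrated RBF-SVC + extra trees, each behind
fold-internal ANOVA-F screening, stacked into a distance-weighted KNN on
out-of-fold class probabilities; SMOTE balances training folds only.
Metrics: accuracy = Σᵢ TPᵢ / Σᵢ (TPᵢ + FNᵢ) and macro precision / recall /
F1, macro one-vs-rest ROC with trapezoid AUC, per-fold mean ± SD.

**Attribution.** Permutation-sampling Shapley values on class
probabilities; exact additivity per sample and class by construction;
global and per-class mean-|contribution| rankings.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate a study-style cohort (88 participants, 21:15:52 class mix, the
default paper-direction planted effects at 1.5 SD), cross-validate the
stack, and rank risk factors:

```python
import numpy as np
from diabkit import (CohortSpec, StackConfig, StackedHbA1cModel,
                     assemble_predictors, attribute, simulate_cohort)
from diabkit.cohort import default_planted_effects

cohort = simulate_cohort(CohortSpec(
    planted_effects=default_planted_effects(1.5), seed=0))
X, y = assemble_predictors(cohort)

model = StackedHbA1cModel(X, y, config=StackConfig(seed=0))
report = model.cross_validate()
print(report.summary())

results = model.fit()
rng = np.random.default_rng(0)
rows = X.to_numpy()
att = attribute(results, rows[:32], rows[rng.choice(88, 50, replace=False)],
                n_permutations=8, seed=0, feature_names=list(X.columns))
print(att.global_importance().head(5))
```

Output:

```
Cross-validated HbA1c-change classification
====================================================
folds: 5    samples: 88    macro AUC: 0.927

metric            pooled    fold mean +/- sd (%)
accuracy           86.36     86.27 +/-  3.58
macro-precision    85.79     88.00 +/-  6.54
macro-recall       83.14     83.17 +/-  2.19
macro-F1           84.45     85.36 +/-  2.37

confusion matrix (rows = true class):
  class 0: [18, 0, 3]
  class 1: [0, 11, 4]
  class 2: [3, 2, 47]

WHR_exam1      0.143426
TG_exam1       0.102334
HDL_exam1      0.064125
HbA1c_exam1    0.058460
Se             0.051027
dtype: float64
```

Read: pooled 5-fold accuracy 86 % with macro AUC 0.93 on this seed, the
confusion concentrated on the diagonal, and the attribution top-5 made of
planted features (WHR, TG, HDL, baseline HbA1c, Se — all shifted at
1.5 SD by the default plant list). Fold-to-fold SDs of a few points are
what n = 88 supports.

The same pipeline is scriptable from the shell:

```bash
diabkit simulate cohort --seed 0 --out run/cohort
diabkit train --cohort run/cohort/cohort.csv --schema run/cohort/schema.yaml \
              --seed 0 --report run/report
diabkit explain --cohort run/cohort/cohort.csv --schema run/cohort/schema.yaml \
                --max-samples 32 --permutations 8 --out run/explain
```

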