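# adherefit

Predicting fourth-month training adherence of fitness-app users from their
first 90 days of workout sessions.

Fitness apps lose most of their users within months. If attrition can be
anticipated from early training behaviour, an app can intervene before a
user quits. `adherefit` implements a cluster-conditioned ensemble
framework for exactly that: users are grouped by the shape of their first
three months of activity, a one-step-ahead forecaster is trained per user,
and a new user's fourth month is predicted by the *ensemble* of
forecasters belonging to their behavioural cluster. The predicted month is
then binarised into **adherent** (any meaningful training activity) versus
**non-adherent** (an essentially inactive month).

The package is aimed at digital-health / mHealth researchers who have
per-session workout logs (user id, timestamp, duration, finished flag) and
want a reproducible adherence-prediction pipeline, plus a calibrated
synthetic-cohort generator for method development without real user data.

## The method

The base signal is one number per user per day: the accumulated workout
time in seconds. Each user contributes a 120-day series, split 90 days of
history / 30 days held out (the fourth month).

1. **Features.** From days 1–90: monthly mean daily seconds
   (`mean_first_month` …), monthly counts of missed (zero-activity) days
   (`missed_first_month` …), and twelve weekly means — 18 features, with
   named subsets (`missed_months`, `month_means`, `weeks`, `combined`).
2. **Clustering.** K-means (SSE
   `Σᵢ Σ_{x∈Cᵢ} ‖x − mᵢ‖²` minimised by Lloyd iterations with k-means++
   seeding), BIRCH (additive cluster-feature triples
   `(n, Σx, Σ‖x‖²)` in a radius-thresholded CF tree, agglomerated
   globally), and affinity propagation (damped responsibility/availability
   message passing on similarities `s(i,k) = −‖xᵢ − x_k‖²`, exemplars from
   the criterion matrix `C = R + A`) — all with a uniform fit/assign
   contract.
3. **Per-user forecasters.** The 90-day window is converted to supervised
   pairs (7 consecutive days in → day 8 out). Each user gets the best of a
   hyperparameter grid by training MAE: either an LSTM
   (units ∈ {50,75,100,125,150} × dropout {0.2,0.4,0.6} × batch {1,2,4},
   50 epochs, early stopping) or an ε-tube SVR
   (poly/RBF/sigmoid kernels, C ∈ (0, 500], ε = 10 s).
4. **Ensemble prediction.** A new user is assigned to a cluster; every
   member forecaster of that cluster rolls out 30 recursive one-step
   predictions from the user's history; the prediction is the elementwise
   mean, Ē. The user is labelled adherent iff `sum(Ē) ≥ τ`
   (default τ = 600 s/month).
5. **Evaluation.** Leave-one-user-out: each user is scored by their
   cluster's ensemble with their own member removed, against the ground
   truth of their held-out fourth month; accuracy, precision, recall,
   specificity and F1 from the confusion matrix (adherent = positive).

A seedable synthetic-cohort generator provides four behavioural archetypes
(steady / declining / ramping / inactive) with log-normal session
durations, calibrated so cohort daily means sit in the 300–400 s band and
the adherent fraction is 112/246.

## Worked example

```python
from adherefit import AdherenceFramework, CohortConfig, simulate_cohort

cohort_full = simulate_cohort(CohortConfig(n_users=200, seed=1))
cohort = [series for series, _, _ in cohort_full]

results = AdherenceFramework(
    cohort, clustering="kmeans", regressor="svr", preset="missed_months",
).fit(seed=1)
print(results.summary())

report = results.leave_one_out()
print(report.confusion.pretty())
print(report.metrics.as_dict())
```

Output (a few minutes on one CPU):

```
Adherence ensemble framework
==========================================
cohort size           200
clustering            KMeansConfig
feature preset        missed_months
regressor             svr (grid of 18)
adherence tau         600 s/month
clusters / ensembles  4
  cluster   0:   60 members, median train MAE    249.1 s
  cluster   1:   40 members, median train MAE     48.0 s
  cluster   2:   60 members, median train MAE    136.2 s
  cluster   3:   40 members, median train MAE    181.9 s

Confusion Matrix  Predicted: No  Predicted: Yes
Actual: No        TN: 88         FP: 21
Actual: Yes       FN: 6          TP: 85

accuracy     0.8650
recall       0.9341
precision    0.8019
specificity  0.8073
f1           0.8629
```

K-means on the missed-days features recovers the four planted archetypes
(one ensemble per cluster of 40–60 members; the low-MAE cluster is the
near-inactive group, whose series are easiest to forecast).
Leave-one-user-out classification reaches 0.865 accuracy against a 0.545
majority-class baseline: early training frequency carries most of the
signal about fourth-month adherence.

The same pipeline is available from the shell:

```bash
adherefit simulate --n-users 200 --seed 1 --out data/
adherefit train    --sessions data/sessions.csv --clustering kmeans \
                   --regressor svr --out model/
adherefit predict  --model model/ --sessions data/sessions.csv
adherefit evaluate --model model/ --sessions data/sessions.csv --loo
```

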