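# Methods

This note documents the models, parameters and design choices behind
`adherefit`, in the spirit of a statistical package's model documentation.
It states no empirical numbers beyond those the test suite and
`scripts/acceptance.py` themselves compute.

## Signal definition and windowing

The pipeline's base signal is daily accumulated workout seconds: the sum
of a user's completed-session durations per calendar day (the date
component of the logged timestamp; no timezone conversion). Day indices
are 1-based, anchored at the user's first retained session. Each user
contributes a 120-day series; days 1–90 (months 1–3, fixed 30-day blocks)
are the model's input and days 91–120 the held-out fourth month. By
default only sessions flagged *finished* accumulate time
(`finished_only=True`); the flag is configurable because logs also record
aborted sessions with durations.

Cleaning removes exact duplicates (identical user/timestamp/duration
triples), records with negative or missing durations, and unparseable
timestamps, and reports counts per rule. Cleaning filters — it never
raises.

## Features

Eighteen per-user features from days 1–90: three monthly means (seconds
per day), three monthly missed-day counts, and twelve weekly means.
"Missed" is operationalised as a zero-activity day inside the 30-day
block — the app prescribes no schedule, so inactivity is the only
observable skip. Weeks are fixed 7-day blocks over days 1–84; days 85–90
contribute to month 3 only. Features are used raw (seconds) by default;
cohort-level z-scoring is available but off, because the BIRCH radius
threshold is most interpretable in raw seconds.

Feature subsets ("presets"): `month_means` (3), `missed_months` (3),
`weeks` (12), and `combined` (missed months + month means + weeks 8–11,
10 features).

## Clustering

All three algorithms are implemented in the package (K-means, BIRCH,
affinity propagation) with a uniform assign-new-point contract
(nearest centroid / global label of nearest leaf centroid / cluster of
nearest exemplar; squared Euclidean distance, lowest index on ties).

* **K-means**: Lloyd iterations with k-means++ seeding from an explicit
  RNG, best of `n_restarts` (default 10) by SSE, `max_iter` 300. An empty
  cluster is re-seeded at the point farthest from its assigned centroid.
  The SSE elbow utility reports best-of-restarts SSE per k.
* **BIRCH**: cluster features are additive triples (count, linear sum,
  squared coordinate sum); a point is absorbed into its nearest leaf
  subcluster iff the merged RMS radius stays within the threshold,
  otherwise it opens a new subcluster; nodes split around their two
  farthest centroids when the branching factor (default 50) is exceeded.
  The global phase merges leaf centroids into `n_global_clusters` by
  average-linkage agglomeration (scipy).
* **Affinity propagation**: similarities are negated squared Euclidean
  distances with the preference on the diagonal (default: median
  off-diagonal similarity). Responsibility and availability sweeps are
  mixed with damping λ ∈ [0.5, 1) (`new = λ·old + (1−λ)·computed`,
  default 0.7); exemplars are points with positive criterion diagonal
  (C = R + A); convergence requires a stable exemplar set for 15
  consecutive sweeps within 200. A non-convergent fit labels every point
  −1, and assignment returns the −1 sentinel. A fully symmetric input
  (all off-diagonal similarities equal) can never break the tie by
  message passing; it is resolved directly by the preference — below the
  shared similarity: a single cluster with label 0; at or above it: every
  point its own exemplar.

## Per-user forecasters

Series are converted to supervised pairs by a sliding window: seven
consecutive days in, the eighth day out (L − 7 pairs from a length-L
series). Multi-step forecasts are recursive one-step-ahead roll-outs:
each prediction is appended to the history and re-enters the input
window. Forecasts are clipped to [0, 86400] s/day — seconds cannot be
negative, a day has 86400 of them, and the clip also prevents
ill-conditioned kernel models from diverging over a 30-step roll-out.

* **LSTM** (NumPy implementation in `adherefit._lstm`): one recurrent
  layer of U units with peephole connections (gates see the cell state),
  logistic gates, configurable cell activation (ReLU by default, tanh
  available), followed by dense layers of widths U/2 (ReLU), U/4 (ReLU)
  and 1 (linear) with inverted dropout after the first two. Trained on
  min–max-scaled series ([0, 1] per user) with MSE loss, Adam
  (lr 10⁻³), up to 50 epochs, early stopping on the training loss with
  patience 15. The grid: units {50, 75, 100, 125, 150} × dropout
  {0.2, 0.4, 0.6} × batch size {1, 2, 4} (45 combinations; the same
  dropout rate is used at both sites). Gradients are exact BPTT,
  validated against numerical gradients in the test suite. Dense widths
  U/2 and U/4 are the package's choice (layer counts are fixed; widths
  were open). The forget-gate bias is initialised to 1.
* **SVR** (scikit-learn): ε-tube regression with kernels poly (degree 3) /
  RBF / sigmoid, γ data-scaled, ε = 10 and C searched over
  {1, 10, 50, 100, 200, 500} within (0, 500]. Because ε is specified in
  seconds, the SVR trains on the raw-seconds axis (identity transform);
  min–max scaling to [0, 1] would put every residual inside a 10-unit
  tube and flatten the model. The solver is capped at 10⁵ iterations: the
  degree-3 polynomial kernel on raw-second features can cycle
  indefinitely, and a capped fit simply scores a worse MAE and loses the
  grid search.

Grid search trains every combination on the user's 90-day window and
keeps the model with the lowest training MAE (in original seconds; ties
go to the first combination in documented grid order). There is no
validation split — early stopping monitors the training loss — so the MAE
is a training-fit criterion, consistent with selecting a per-user
representation rather than estimating generalisation.

## Ensembles and prediction

Each trained user contributes exactly one member (their best forecaster)
to the ensemble of their cluster. A new user's fourth month is the
elementwise mean of the 30-day forecasts of their cluster's members, each
member applying its own scaling transform to the new user's history. An
empty cluster — or the −1 sentinel of an unconverged affinity-propagation
fit — falls back to the global ensemble of all members, which is also
exposed directly as the `"none"` clustering mode (single-ensemble
baseline). Leave-one-user-out evaluation excludes only the held-out
user's own member; the clustering fit is shared across folds.

## Adherence rule and τ

Ground truth: a user is non-adherent iff every day of their fourth month
is zero. A continuous 30-day forecast is binarised by its total:
adherent iff `sum ≥ τ`.

τ cannot be arbitrarily small. A forecaster fitted with an ε-insensitive
tube tolerates a per-day bias up to ε even on an all-zero month, so
ensemble totals for truly inactive users carry a bias floor on the order
of 30·ε = 300 s (at ε = 10 s/day); LSTM members inherit an analogous
floor through inverse scaling. The default τ = 600 s/month is twice that
floor and still roughly twenty-fold below typical adherent monthly
activity (cohort daily means of 300–400 s ≈ 10⁴ s/month). τ is a
configuration parameter and is reported in every model summary.

## Synthetic cohorts

The generator emulates the statistical structure of real fitness-app
cohorts so the whole pipeline is testable without user data. Four
archetypes, with daily activity probabilities per month (months 1–3) and
a month-4 continuation probability for adherent users:

| archetype | p₁ | p₂ | p₃ | p₄ (adherent) | adherence propensity |
|-----------|----|----|----|---------------|----------------------|
| steady    | .50| .50| .50| .45           | .95 |
| declining | .60| .25| .10| .10           | .08 |
| ramping   | .10| .35| .60| .55           | .92 |
| inactive  | .05| .05| .05| .10           | .02 |

Active-day seconds are log-normal (median 800 s, σ = 0.5) — positive and
right-skewed, matching logs whose daily standard deviation far exceeds
the mean. Mixture weights default to .30/.30/.20/.20. With these
defaults the cohort's daily means land in the few-hundred-seconds band
and month-1 per-user means mass in the (0, 300] and (300, 1800] s bins.

Cohort composition is a study condition and is realised exactly:
archetype counts by largest-remainder apportionment of the mixture
weights (randomly ordered), and the adherent count as
`round(adherent_fraction · n)` (default fraction 112/246). The adherent
set is drawn by systematic probability-proportional-to-size sampling
with per-archetype propensities (table above), so realised inclusion
probabilities are `min(1, c·propensity)` with c solving the count
constraint. Sequential weighted draws without replacement were rejected:
with a draw of nearly half the cohort they exhaust the high-propensity
pool and flatten the designed rates. Because the pinned adherent
fraction (0.455) is slightly below the propensities' expected fraction,
realised rates are diluted by c ≈ 0.92, giving archetype-conditional
adherence of roughly .87/.07/.84/.02 — an archetype-level Bayes ceiling
of about 0.90 for any classifier that only sees behavioural group, in
line with the predictability level reported for real cohorts.

Adherent users get at least one active fourth-month day enforced, so
generated labels are exactly recoverable by the adherence rule;
non-adherent users' fourth months are identically zero.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: weekday/weekend seasonality,
within-archetype heterogeneity of activity level, gradual within-month
trends (activity probabilities are piecewise-constant per month), any
dependence of adherence on a user's *individual* realised history beyond
their archetype, demographics, and measurement artefacts beyond the
cleaning rules exercised. In particular, on synthetic cohorts the
classification signal is carried almost entirely between clusters, not
within them.

## Numerical choices and problem sizes

Min–max scaling of a constant (or all-zero) series maps to zeros with an
offset-only inverse, so constant series round-trip exactly. Standardised
features with zero cohort variance map to 0. Nearest-centroid and
nearest-exemplar ties break to the lowest index. Metric denominators of
zero yield NaN with a defined-flag, never an exception; metrics are
reported to 4 decimals (round-half-even).

The test suite and the acceptance script run the end-to-end evaluation
at n = 200 users with the SVR regressor (and a single-combination,
few-epoch LSTM grid in smoke tests); these sizes exercise every stage
while keeping a full run in the minutes range on one CPU. All randomness
flows through explicit seeds: cohort generation, k-means++ restarts and
LSTM initialisation/dropout are reproducible bit-for-bit, and SVR and
the message-passing/CF-tree fits are deterministic by construction.

## Known limitations

* Recursive roll-outs converge toward each member model's fixed point,
  so 30-day ensemble totals are dominated by the cluster's members
  rather than fine detail of the new user's last week; discrimination is
  mostly between clusters.
* Whole-cluster misclassification is possible when a cluster's ensemble
  total lands near τ (observed for taper-style groups at small cohort
  sizes); larger cohorts stabilise the ensemble mean.
* Training-MAE model selection can prefer overfitted members; the
  ensemble mean damps, but does not eliminate, their influence.
* The full 45-combination LSTM grid at 50 epochs is computationally
  heavy at cohort scale; the SVR pipeline or a reduced LSTM grid are the
  practical defaults on a single CPU.
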