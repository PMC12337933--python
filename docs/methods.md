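# Methods

`rxadherence` reimplements, end to end, a pharmacoepidemiological analysis
chain over longitudinal pharmacy dispensing records: new-user cohort
construction for antihypertensive monotherapy, proportion-of-days-covered
(PDC) adherence, drug-utilization pattern classification, risk-factor
clustering, penalized-regression prediction models, and an inverse-
probability-weighted survival analysis of the time to reach high adherence.
Because dispensing databases of this kind are proprietary, the package ships
a synthetic-data generator with planted ground truth; every statistical
component is validated against that truth or against independent brute-force
oracles.

## Data model and cohort design

The atomic input is a dispensing record: patient, date, ATC code, days of
supply. Day 0 is the index date (first dispensing of one of the five
exposure classes: thiazides C03AA, calcium-channel blockers C08C/C08D/C08E,
ACE inhibitors C09A, angiotensin-receptor blockers C09C, beta-blockers
C07A); supply intervals are half-open `[day, day + supply)`.

A patient enters the cohort when their first exposure dispensing has no
exposure dispensing in the preceding 730 days (new-user washout), is the
only exposure class dispensed that day (monotherapy; two classes on the
index day exclude the patient), and the patient is 18 or older in completed
years. Patients with a dispensing of an exclusion drug group (cardiac
therapy C01, migraine N02C, systemic corticosteroids H02A, thyroid H03,
parathyroid H05 — an editable prefix table, since the underlying conditions
are named but not coded anywhere authoritative) in `[index − 730, index +
90]` days are excluded.

Follow-up ends at the earliest of: the study end (default 2020-12-31,
counted inclusively), 3780 days (ten years), the first acute-cardiovascular
drug dispensing, the end of supply of the last index-class dispensing, or
the first dispensing of another exposure class or fixed-dose combination
(FDC). Ties resolve in that order. We deliberately censor at the *end of
supply* of the last dispensing rather than its date, so a patient is never
censored mid-supply; the raw-date variant is available via
`exposure_end_rule`.

Covariates are all categorical: sex; age band (18–39 / 40–69 / ≥70 completed
years at index); nine comorbidity-drug flags, true when at least one
dispensing of the group (diabetes A10, rheumatoid arthritis M01C+L04A,
asthma/COPD R03, antiepileptics N03, antiparkinson N04, psycholeptics N05,
psychoanaleptics N06, addictive-disorder drugs N07B, antineoplastics L01)
falls within 180 days after index (inclusive); and the calendar period of
the index date, binned half-open as [1996, 2000), [2000, 2010),
[2010, 2021) because the conventional printed bins share endpoints.

## Adherence (PDC)

Coverage timelines support two overlap policies. Under `carryover` (the
default, and the common PDC convention) an early refill is banked: its start
shifts to the end of the supply already held. Under `truncate` overlapping
supply is discarded (plain interval union). Annual PDC for treatment year k
is the covered days in `[360(k−1), 360k)` divided by a fixed 360-day
denominator; a year window not fully inside follow-up is *not evaluable*
(returned as missing) rather than being diluted toward zero, which restricts
each year-k estimate to patients persisting beyond 360·k days. Overall PDC
divides covered days in `[0, followup_end)` by the follow-up length. Both
are capped at 1 (no credit for oversupply) and binarized as high adherence
at PDC ≥ 0.8, threshold inclusive.

## Pattern classification

Four non-exclusive patterns are scanned inside an observation window:

* **Discontinuation** — the first end-of-supply day `e` with no same-class
  dispensing in `(e, e + 180]`; a gap of exactly 180 days does not count.
  The event is dated at supply exhaustion, not at the last dispensing.
* **Switch** — the first dispensing of a different exposure class or FDC in
  `(disc, disc + 180]`.
* **Add-on** — the first other-class/FDC dispensing on a day strictly inside
  initial-class coverage and before any discontinuation. Intervals are
  half-open, so a dispensing on the exact end-of-supply day is outside
  coverage and falls on the switch side.
* **Continuation** — none of the above before the end of observation.

Switch and add-on can both occur for one patient; continuation excludes
everything. The observation window for patterns is `min(study_end − index +
1, 3780)` days, *not* the supply-censored follow-up end: under the censoring
rule that ends follow-up at the last supply end, a post-supply gap could
never lie inside follow-up and nobody could ever discontinue. This is the
one place where two parts of the design genuinely conflict, and the pattern
module resolves it in favour of observable events.

## Risk clustering

All risk factors are unordered categoricals, so the Gower dissimilarity
reduces to the fraction of variables on which two patients differ; it is a
metric in [0, 1], with binary variables treated symmetrically. Clustering is
partition around medoids (PAM). Because the greedy BUILD + best-improvement
SWAP procedure can stall in a swap-optimal but globally suboptimal medoid
set even at n ≤ 10, `pam()` enumerates all medoid sets exactly whenever
C(n, k) ≤ 5000 and falls back to BUILD+SWAP above that; ties break on the
lowest patient index, so results are deterministic. For n > 10,000 a
CLARA-style strategy (PAM on five random subsamples of 2000, keeping the
medoid set with the lowest full-data cost; this is the only use of the
seed) bounds the O(n²) cost. K is selected over 2–10 by maximizing the
average silhouette width `s(i) = (b − a)/max(a, b)`, with `s(i) = 0` for
singleton clusters and ties resolved toward the smaller K.

## Prediction models

Categorical variables are dummy-encoded against a most-frequent reference
level. Pairwise association is screened with Cramér's V (no bias
correction) and multicollinearity with VIFs computed by regressing each
dummy column on all others (exact collinearity reported as infinite).

Penalized logistic models (ridge, LASSO, elastic net with mixing 0.5) are
parameterized glmnet-style — objective `(1/n)·deviance/2 + λ[(1−α)/2‖β‖² +
α‖β‖₁]` on internally standardized columns, solved through scikit-learn with
`C = 1/(nλ)` and a one-dimensional Newton polish of the unpenalized
intercept — and reported on the original indicator scale. The λ grid has 30
log-spaced values from λ_max down to 10⁻⁴λ_max (for ridge, λ_max uses the
standard α = 0.001 surrogate). Model selection uses a stratified 7:3
train/test split and 10-fold cross-validated binomial deviance on the
training part; one seed controls the split and fold assignment and is
recorded in the fit object.

Each cross-validation pass yields two solutions, used for different
purposes exactly as in common glmnet practice: **λ_min** (minimum CV
deviance) is the prediction-optimal fit used for the ridge/LASSO/elastic-net
comparison (lowest RMSE *and* highest R² on the probability scale wins;
discordant winners are reported without a flag; exact ties break on AUC)
and for the reported AUC / sensitivity / specificity on the 30% holdout;
**λ_1SE** (largest λ within one standard error of the minimum) drives
variable selection, where the minimum-deviance solution is known to drag
several null variables along. A source variable survives when at least one
of its dummies has a nonzero LASSO coefficient at λ_1SE; surviving variables
are refit in an unpenalized logistic model (statsmodels Newton, BFGS
fallback on singular Hessians) reported with odds ratios, 95% Wald CIs,
holdout AUC/sensitivity/specificity (0.5 probability threshold), a 10-group
Hosmer–Lemeshow test (deciles of predicted risk, tied risks kept together,
degenerate groups merged, χ² with groups − 2 df) and Nagelkerke's R²
(Cox–Snell rescaled by its maximum). A sensitivity mode refits the plain
logistic model on all variables, dropping columns that are constant on the
training split. Per-cluster refits run the same chain inside each PAM
cluster.

## Survival analysis

The event is the transition to high adherence: follow-up is cut into
consecutive 180-day windows; the event is placed at the end of the first
window with window PDC ≥ 0.8, and patients never qualifying are censored at
`min(followup_end, 1080)` days. The window length, threshold and horizon
are configurable, since any such event construction involves choices the
field does not standardize. Kaplan–Meier curves (lifelines) describe the
probability of remaining in low adherence, by exposure class.

Exposure classes are compared by Cox regression against beta-blockers,
crude and weighted. Stabilized inverse-probability-of-treatment weights come
from an unpenalized multinomial-logistic propensity model of exposure given
all covariates; the weight is the marginal class probability over the
fitted conditional probability, truncated at its 1st/99th percentiles, with
near-zero propensities flagged as positivity failures. Balance is
diagnosed by the maximum pairwise standardized mean difference per design
column, before and after weighting. Ties use Efron's method; weighted
proportional-hazards fits use a robust sandwich variance. Time-dependent
exposure effects use counting-process episodes split at 180 and 540 days
(configurable) with interval-specific exposure coefficients; the underlying
time-varying fitter offers no sandwich variance, so those intervals carry
model-based CIs, which we note rather than hide. Degenerate designs
(intervals with no informative events, separation) are flagged by a warning
and refit with a small L2 penalizer (0.05) instead of failing.

Model performance: cumulative/dynamic AUC at 1080 days with inverse-
probability-of-censoring weights (ties between events and censoring resolve
censoring-last so the censoring survival function stays positive at the
horizon); sensitivity and specificity at the Youden-optimal threshold among
subjects whose 1080-day status is known; Nagelkerke's R² from the partial
likelihood (n = subjects); Harrell's C over usable pairs (0.5 reported for
a constant score). For time-dependent fits the prognostic score is the
episode-length-weighted mean linear predictor.

## Synthetic-data generator

The generator emulates the study population, not any real database:

1. **Covariates first.** Age band (25/55/20% young/middle/older), sex
   (50/50), comorbidity flags at realistic chronic-therapy prevalences
   (2–12%), and an index date uniform over the study window but leaving at
   least `min_observation_days` (default 1800) of observable time, so
   planted events are classifiable.
2. **Adherence.** A binary high-adherence label is drawn from a logistic
   link on the covariates (defaults: intercept 1.0; middle/older age +0.4/
   +0.5; male −0.1; diabetes +0.5; asthma/COPD +0.3; psycholeptics −0.5;
   post-2000/post-2010 periods +0.3/+0.4 — signs chosen to mirror the
   qualitative epidemiology of adherence). The label maps to a refill
   propensity band (high: 0.92–1.0; low: 0.55–0.70) and the inter-dispensing
   delay factor is `1/propensity + U(−0.1, 0.1)`, so year-1 PDC lands on the
   intended side of 0.8 with margin and the planted label is exactly
   recoverable through the PDC engine.
3. **Archetypes.** Continuers refill until banked supply reaches the
   horizon (with trailing refills placed exactly at exhaustion so coverage
   is guaranteed); discontinuers and switchers stop after a
   Geometric(0.3) number of dispensings capped at 8, so events stay inside
   the observation window; switchers start a different class (or an FDC
   with probability 0.1) U(1, 180) days after supply ends; adders start a
   second class on a day strictly inside ongoing coverage. Default days of
   supply is 90 per class, typical for chronic therapy.
4. **Late improvement.** An initially low-adherent persister jumps to the
   high-propensity band with probability 0.15 per 180-day window from day
   360. This yields the declining probability of remaining in low adherence
   that a time-to-high-adherence analysis needs (without it, essentially
   all events occur in the first window and late hazard intervals carry no
   information), while leaving year-1 labels untouched.
5. Comorbidity-drug dispensings (one or two per flagged group) are placed
   uniformly in the first 180 days.

Optional logit shifts let exposure class or archetype depend on covariates,
which is how confounding is planted for the weighting experiments. With a
fixed seed all three output tables are byte-identical across runs.

What the generator does *not* emulate: dose titration, stockpiling
behaviour beyond the carryover mechanics, seasonal refill patterns,
pharmacy-level effects, database entry/exit (every simulated patient has a
clean washout), or correlated comorbidity onset after baseline. Passing
tests therefore demonstrate the correctness of the analytic machinery under
a controlled generative model — not that a real database would produce any
particular rate.

Auxiliary simulators used by validation studies: random messy dispensing
histories (for coverage/pattern oracles), categorical archetype tables with
rejection-sampled well-separated profiles (for planted-K recovery),
exponential two-group survival with a binary confounder raising both
exposure odds and hazard (true conditional HR 2.0, confounder HR 2.5), and
piecewise-exponential survival with a sign-flipping group effect (+0.7 /
0 / −0.7 log-HR over 0–180 / 180–540 / 540–1080 days).

## Validation studies and problem sizes

The test suite cross-checks interval arithmetic and pattern flags against
day-by-day boolean oracles on 1000 random histories each; PAM against
exhaustive enumeration on 50 small matrices; silhouette-based K selection
against planted K ∈ {2..5} at n = 400 over 10 seeds per K; LASSO
group-selection against 3 planted effects (|log-odds| 0.7) and 6 nulls at
n = 5000 over 20 seeds; stabilized-weight properties and crude-vs-weighted
hazard-ratio bias at n = 2000–5000 over up to 50 seeds; and the
time-dependent sign-flip recovery at n = 1500 over 20 seeds. The
`scripts/acceptance.py` entry point re-runs the full pipeline at n = 2000
patients plus these studies (some at reduced replicate counts) and writes
every headline number it computes as JSON; the replicate counts and sample
sizes above are the package's chosen study sizes and are stated in the
script.

## Known limitations

* The pattern observation window and the follow-up censoring rule embody
  different readings of "end of follow-up" (see above); both are explicit
  and configurable, but results depend on the choice.
* PAM above the exact-search bound is a heuristic; its cost is only
  guaranteed swap-optimal.
* The time-varying Cox variance is model-based even under weighting.
* Hosmer–Lemeshow group merging makes the χ² reference distribution
  approximate when many predicted risks tie.
* The generator's refill-delay model produces PDC values clustered by
  propensity band rather than a smooth continuum; prediction-model AUCs on
  default synthetic cohorts are therefore modest (≈0.55–0.65) and vary
  across seeds at n ≈ 1300.
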