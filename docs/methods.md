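# Methods

`habitcoach` implements an automated-feedback loop for weight management:
raw mobile-sensor and food-log streams are condensed into a life log,
repeated behaviors are clustered, and each day the engine emits
personalized exploit–explore suggestions. A companion statistics module
implements the trend-based analysis used to evaluate behavior change in
a small two-arm trial. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Activity recognition

Windows of tri-axial accelerometer samples are summarized by twelve
statistical features — mean (g), population variance (g²) and
zero-crossing rate (crossings/s of the mean-removed signal) for each of
the three axes and the magnitude. Classification uses one Gaussian
mixture per class (walking, running, stationary, driving) with diagonal
covariances, k = 2 components, EM with k-means initialization and a
fixed seed; a window is assigned to the class maximizing log prior +
mixture log-likelihood, with ties broken by a fixed class order
(stationary < walking < running < driving). With k = 1 the decision rule
reduces to a diagonal quadratic discriminant, which the tests exploit as
a closed-form oracle.

Feature extraction is sampling-rate-generic. The interchange sensor
format is a 1 Hz CSV, so the pipeline classifies non-overlapping
60-sample (one-minute) windows and broadcasts each window label to its
seconds; a per-second prediction cadence is thereby preserved into the
aggregation stage. Zero samples are treated as positive in the crossing
count so a signal touching zero is not double-counted. A finite window
of a sinusoid of frequency f yields 2f·T − O(1) sign changes, not
exactly 2f·T; tests assert against an explicit counting oracle rather
than the asymptotic constant.

Manually logged exercises bypass the classifier entirely and enter the
life log with their MET-table label.

## Energy

Gross expenditure follows the standard MET convention, kcal = MET ×
body mass (kg) × duration (h); resting expenditure is not subtracted.
The MET table is a small synthetic excerpt (stationary 1.3, walking 3.5,
running 8.0, driving 1.3, plus a dozen manual exercise types). Food
energy is kcal-per-unit × quantity from a 30-item synthetic food table
with ingredient token sets; a direct calorie override models label-entry
of packaged foods. Mixed events use the duration-weighted sum of their
constituents' MET rates.

## Life-log construction

Stage 1 takes the majority per-second label of each minute; a tie takes
the previous minute's label (a temporal-continuity prior) and otherwise
the fixed class order. Stage 2 merges maximal runs of identical minute
labels into single events; both stages conserve labeled time exactly.
Maximal chains of ≥ 2 consecutive activity events with ≥ 2 distinct
labels, every constituent shorter than 15 minutes and inter-event gaps
under 15 minutes, are replaced by one `mixed` event (the canonical
commute: walk / wait / ride / walk); events of 15 minutes or longer are
never absorbed. Food events are instantaneous entries given a nominal
1-minute extent; a manual exercise entry overlapping an automatic event
wins, and the automatic event is truncated (split if necessary) with
calories pro-rated.

End-to-end recovery is scored as: a ground-truth event is recovered when
it overlaps a life-log event of the same label *or* a mixed event that
carries the label among its constituents. The second clause matters
because a single misclassified boundary minute adjacent to a short walk
legitimately folds that walk into a mixed event; the behavior is still
present in the log.

## Behavior clustering

* **Stationary places** — single linkage over the great-circle distance
  of episode locations (median of the GPS trace) with a 150 m threshold,
  the stated working accuracy of indoor localization; any two episodes
  within 150 m share a cluster. Events without location go to one
  "unlocated" cluster that suggestions skip.
* **Trajectories** — each walk/run trace is resampled to 32 points
  uniform in arc length (endpoints preserved; length preserved to within
  the corner-cutting of the grid, < 1% for traces whose vertices are
  denser than the grid). Distance between two canonical trajectories is
  the mean point-wise great-circle distance with start-to-start
  alignment, making the measure direction-sensitive (A→B ≠ B→A). Leader
  clustering processes events chronologically: join the nearest
  representative within 150 m (ties to the lowest cluster id) or found a
  new cluster; the representative is the point-wise mean of members,
  re-resampled. The 150 m threshold reuses the localization accuracy
  scale; with 20 m GPS noise the expected distance between two repeats
  of the same path is ≈ 35 m, an order of magnitude under the threshold,
  while distinct routes are kilometers apart.
* **Foods** — events are first typed meal vs snack (inside a canonical
  meal window 07–09 / 12–14 / 18–21 local, or ≥ 250 kcal → meal), then
  leader-clustered within type by Jaccard similarity ≥ 0.5 of the
  ingredient token sets; the representative is the modal food item.
* Cluster frequency is the member count in a trailing 14-day window;
  weekly frequency is that count × 7/14.

Leader clustering is order-dependent by construction; chronological
processing with deterministic tie-breaks mirrors online accumulation on
a phone and makes runs reproducible.

## Suggestion engine

Each behavior cluster is an arm of a multi-armed bandit whose payoff is
energy balance. Daily batches contain 10 activity and 10 food
suggestions at a fixed 9 + 1 exploit/explore split (⌊10 × 0.9⌋ = 9),
realized deterministically per batch rather than per-slot Bernoulli so
the long-run explore share is exactly 10%.

* **Exploit** — frequent clusters (≥ 3 occurrences per 14 days), ranked
  by aggregate impact: weekly frequency × kcal per instance for
  activities (descending burn); ascending per-instance kcal for frequent
  meals and snacks ("keep choosing your low-calorie regulars").
* **Small change** — each frequent stationary cluster becomes a
  prescription of a 3-minute walk per stationary hour; its projected
  weekly burn (weekly stationary hours × walking kcal of a 3-minute
  bout) competes in the same exploit ranking, which is how a 25-h/week
  office cluster (25 × 12.25 = 306.25 kcal/week at 70 kg) outranks a
  once-a-week 245-kcal gym visit.
* **Explore** — one uniform draw from infrequent-but-demonstrated
  clusters in the healthy calorie direction: per-instance burn at or
  above the category median for activities, per-instance intake at or
  below it for foods. The median is taken over all clusters of the
  category and the comparison is inclusive so a lone candidate stays
  eligible. Never-done behaviors are never suggested (if the user has
  done it, even rarely, the skills are assumed present).
* **Backfill** — an empty explore pool backfills the slot from the
  exploit ranking; conversely, when fewer than 9 frequent clusters
  exist, remaining slots are filled from the rest of the infrequent pool
  so a user with ten total candidates still receives a full batch; with
  fewer than 10 candidates overall, as many as exist are emitted.
* Frequent high-calorie meal clusters above a goal-dependent cutoff
  (lose 500 / maintain 700 kcal) render as avoid/reduce text alongside
  the batch but never occupy its ten scored slots.
* Score ties go to the earlier-created cluster. The engine learns from
  passive frequency change only: a behavior crossing the frequency
  threshold migrates from explore to exploit on the next recomputation.
* The control arm draws uniformly without replacement from a 42-entry
  generic-suggestion pool (synthetic placeholder texts; only the pool
  size and sampling mechanics are meaningful).

## Trial statistics

Per user and metric (walking length in minutes; kcal per meal item),
weekly medians over the three study weeks classify the trend: positive
means the week-3 median moved in the healthy direction relative to
week 1 (longer walks, or fewer meal calories); a week with no events
flags insufficient data, and such users are counted non-positive in the
2×2 arm × outcome table — a choice that reproduces the published diet
p of .15 exactly (excluding them gives ≈ .30). Medians are the standard
sample median (mean of the middle two for even n); a log display scale
does not change order statistics, so medians are computed on the raw
scale.

The Fisher exact p is the full hypergeometric enumeration: the sum of
probabilities of all tables with the observed margins whose point
probability is at most the observed table's (with a 1e-9 relative
tolerance so equal-probability tables are included), the two-sided
convention of mainstream statistical software. Mann–Whitney U is exact
by enumeration of rank splits for pooled n ≤ 12, and a tie-corrected,
continuity-corrected normal approximation above; the effect size is the
rank-biserial correlation 2U/(n_a n_b) − 1. The two-sample t is the
pooled-variance form with df = n_a + n_b − 2 (the published t₁₅ with
arms 9 + 8 identifies the pooled, not Welch, statistic) and Cohen's d =
mean difference / pooled SD; a zero-variance pair with equal means
returns t = d = 0, with unequal means it is an error.

The published walking-trend p of ".05" is not reproducible as stated:
two-sided enumeration of the printed table [[7,2],[2,6]] gives 0.0567
and one-sided gives 0.0444, so the sidedness/rounding is ambiguous. The
package computes and reports the two-sided value and asserts nothing
about the printed one.

## Synthetic data generator

The generator defines the test conditions. The day template is:
stationary at home overnight, a commute walk home→office along a fixed
per-user jittered polyline (each leg with probability rate/14 per day,
default 10 legs/week, ~30 ± 5 min lognormal), stationary at the office,
a short (< 15 min) office-loop walk on some working days, an occasional
long evening loop from home, an evening exercise session (3/week across
five types with one per-user favorite, logged manually), and three meals
in the canonical windows (≈ 600 ± 150 kcal lognormal, realized through
the food-log quantity field) plus Poisson snacks (1.5/day, 180 ± 60
kcal). GPS noise is isotropic Gaussian in the local tangent plane,
default 20 m per axis. Every second of every day carries exactly one
ground-truth activity label. Each user's randomness derives from
(seed, sha256(user_id)), so adding users never perturbs existing ones
and identical inputs are byte-identical on disk.

An `intervention_effect` e multiplies walk durations by (1+e) and meal
kcal by (1−e) from day 7 onward — a planted, recoverable behavior
change. `simulate_trial` gives the effect to the experimental arm only.

The accelerometer channels are class-separable surrogates (alternating
gait component plus white or AR(1) noise around gravity), deliberately
not realistic waveforms: passing recognition tests demonstrates the
feature/classifier machinery, not field-grade recognition of real human
motion. Similarly the generator omits weekends, multi-modal commutes,
location drift, missing data and logging noncompliance, so recovery
rates near 100% on synthetic data are an upper bound on real-world
behavior, not an estimate of it.

## Problem sizes and power

Simulation-based checks use: 21-day users (the 3-week study duration);
40 users × 2 metrics for trend recovery; 400 replicates of a 9 vs 8
null trial for the size of the Fisher analysis; 150–200 replicates at
effect +0.3 for power. Fisher's exact test is conservative at 9 vs 8 —
summing Bin(9,½) × Bin(8,½) over the rejection region gives an attained
size near 2–4%, below the nominal 5% — so the size check asserts
control (≤ 5% plus Monte-Carlo error), not equality with nominal. A
design-stage power calculation shows that with a null control arm
(P(positive) = ½ by symmetry) the rejection probability at arms 9 vs 8
is capped at 63.7% even if all nine experimental users trend positive;
the power simulation therefore uses 20 vs 20, where the same
calculation gives ≈ 94% at a 0.97 per-user positive rate. Measured
values land near 99%.

## Known limitations

The trajectory matcher is a deliberately simple arc-length-resampling /
mean point-wise distance construction; it has a clean testable contract
but no elastic matching, so strongly time-warped repeats of a route
(e.g. a long detour on one day) can split clusters. Leader clustering
depends on arrival order. The meal/snack rule is a heuristic on time
and size. The engine has no notion of suggestion acceptance — it
recomputes from observed behavior only — and no day-over-day
deduplication of batches.
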