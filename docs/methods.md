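# Methods

This note documents the models and procedures `bseqlab` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical corner cases.

## Data model

The primary datum is a **behavior sequence**: ordered, non-overlapping
intervals `(start_s, end_s, label)` over a fixed 45-label vocabulary, one
sequence per animal per ~23-h recording. Because the proprietary binary
format written by commercial acquisition software is undocumented, the
canonical raw input is a plain TSV with those three columns; minute- and
hour-binned CSV summary exports (seconds per label per bin) are accepted
as fallbacks. Hour bins are expanded to minutes by dividing each hourly
value by 60 — the coarser the input, the blunter the downstream windows,
but the pipeline is otherwise identical.

**Minute binning.** Each event's duration is apportioned exactly to the
minutes it spans. The trailing incomplete minute is dropped rather than
rescaled, so every row has a uniform 60-s denominator. Minute tables
store *seconds* (0–60); proportions are computed downstream. Summary
files with behavior values slightly above 60 s/min (export rounding) are
clamped with a warning; values far above are rejected.

**Synchronization.** The anchor is the first lights-off at or after
`recording_start`. `bintodark` is the signed offset in minutes of each
minute's start from that anchor; the phase is NIGHT exactly when
`bintodark mod 1440` falls inside the lab schedule's night length.
Recordings must span exactly one lights-off event. Synchronization only
annotates; it never alters behavior values.

## Categories

The 45 raw labels first reduce to 38 base behaviors: the horizontal
distance channel (`Travel.m.`) is not a behavior and is held separately;
the `No.Data` and `Arousal` markers are discarded; the three drink zones
and three eat zones collapse to `Drink` and `Eat`. Two pooling schemes
then apply: **Berlin** (18 categories counting `Distance_traveled`),
which merges rarely observed behaviors, and **Jhuang** (10 categories),
the coarser set detectable by an open-source classifier and therefore
useful for cross-software comparison. The mapping ships as a CSV data
file rather than code so it can be audited or replaced; its SHA-256 is
pinned in the tests. Pooling is a column-sum (linear), conserves time up
to the discarded markers, and is idempotent under an identity mapping.

## Time windows

Nine windows in lights-off-relative minutes, resolved against the
concrete recording span and night length *L*:

| id | interval | meaning |
|----|----------|---------|
| W1 | `[start, start+120)` | first 2 h of recording |
| W2 | `[-120, 0)` | last 2 h of day |
| W3 | `[0, 180)` | first 3 h of night |
| W4 | `[L-180, L)` | last 3 h of night |
| W5 | `[L, L+180)` | first 3 h of the second day |
| W6 | `[-120, end)` | 2 h before dark → end |
| W7 | `[start, 0)` | whole day phase before dark |
| W8 | `[0, L)` | whole night phase |
| W9 | `[start, end)` | entire recording |

The composition of the overlapping trio W7–W9 is a design choice (the
smallest natural set overlapping the first six while keeping 18 × 9 =
162 variables); it is overridable via `define_windows(...,
overlap_trio=...)`. A window enters the analysis only if **every**
non-excluded animal's minutes fully cover it — this keeps all samples at
equal valence and is the main defense against truncated recordings
silently biasing one group.

## Features

Per animal, window and pooled category: the square root of the
proportion of window time in the category. The denominator is the total
behavior time actually recorded in the window, not the window's nominal
length, so dropped partial minutes cannot distort proportions and the
squared behavior features sum to exactly 1 per (animal, window). The
square root (not arcsine-square-root, not log) stabilizes variance while
tolerating zero counts, which rare behaviors produce routinely. Features
are invariant to any uniform rescaling of the input time unit.

The distance channel, when the source provides one, becomes one extra
feature per window on the same denominator. Its scale is arbitrary
(tracker units vs. seconds), which distorts distance-inclusive analyses;
`drop_distance=True` (CLI `--drop-distance`) removes it and is
recommended whenever distance is not specifically of interest.

Exclusions (an `exclude` column in the experiment metadata; any
non-empty value other than `0`/`false`/`no` excludes the test) are
applied to the finished matrix and commute with building it.

## Group analysis

**Explorative branch.** Pass 1 fits a 500-tree random-forest classifier
on all variables and keeps the top 20 by mean decrease in Gini impurity;
pass 2 refits on those 20 and keeps every variable whose importance
exceeds 0.95 of the pass-2 maximum, or the top 8, whichever set is
larger — hence always 8–20 variables. The 0.95 threshold is interpreted
on importances normalized to the pass-2 maximum, giving a scale-free
criterion; importance ties break deterministically by variable name.
A 3-component FastICA embeds the animals for visual inspection (falling
back to the available rank, with a warning, for degenerate data). This
branch is selection-biased by construction — with 162 variables it will
find apparent structure even in shuffled data — and is therefore never
used for inference; the test suite demonstrates the point by showing
the confirmatory test stays null on shuffled labels.

**Confirmatory branch.** One PCA on the column-centered (not rescaled —
all features already share the sqrt-proportion scale) feature matrix,
and one pre-registered test on PC1: for two groups a two-sided rank-sum
with tie-corrected normal approximation, reported as Z, p and effect
size r = |Z|/√n; for three groups Kruskal–Wallis (no r). More than three
groups are rejected; multi-group designs are analyzed pairwise.

**SVM validation.** C = 1, `gamma="scale"` (radial) — deliberate
ecosystem defaults, recorded in the report; no tuning, since the point
is honest validation, not leaderboard accuracy. With ≤15 animals per
group (15 itself resolves to the conservative small-sample path) a
non-exhaustive **two-out** scheme is used: per repeat one random animal
per group is held out, the model is trained on the rest (features
standardized on the training fold only) and predicts the pair;
predictions are pooled over `repeats` (default 100, capped at the number
of distinct cross-group pairs). Larger cohorts use a single stratified
holdout of 1/3. Accuracy and Cohen's κ are computed on the pooled
predictions.

**Permutation inference.** The observed accuracy is computed once; each
of `n_perm` permutations randomizes group membership over the whole
dataset and repeats the entire validation. The default permutes *all*
labels before splitting rather than only the training folds: each
permuted run then carries the same per-animal label structure as the
observed run, which is what makes the null calibrated (re-shuffling
training labels inside every repeat averages away the per-labeling
variance and was measured to be anticonservative on synthetic nulls);
training-fold permutation remains available as `permute="train"`. With
exceedance count k = #{permuted ≥ observed}, the point p-value is
(k+1)/(n_perm+1) and the **p-range** is the 95% Clopper–Pearson interval
for k/n_perm — an honest statement of what a finite permutation count
can support. n_perm is always reported; below ~73 permutations the upper
bound cannot fall below 0.05 even at k = 0.

## Consistency checking and transitions

Vendor minute exports are replayed against the raw sequence: any
(minute, label) differing by more than `tol_s` (default 1 s) is flagged,
and the verdict is *consistent* only if nothing is. The distance column
is excluded (it cannot be derived from events).

Transition context: consecutive identical labels are merged into runs,
then for every occurrence of the focal behavior the immediately
preceding and following distinct labels are tallied, each occurrence
weighted equally regardless of duration. Occurrences at a sequence
boundary contribute only their defined side. Per-animal percentage
distributions are summarized across animals by mean and median, top-k by
median.

## Synthetic generator

`SimConfig` defaults define the reference study conditions: 2 groups ×
11 animals, one 1380-min (23-h) recording each starting 2 h before a
19:00 lights-off with a 12-h night. Behavior is a semi-Markov chain over
the 44 non-distance labels: states drawn independently with per-label
propensities, held for exponential dwell times (per-label means), with
consecutive duplicates merged. Activity-type labels are up-weighted
3-fold at night and rest-type labels by day (mice are nocturnal);
per-animal lognormal propensity noise (σ = 0.15) provides between-animal
heterogeneity. Expected time share per label is propensity × mean dwell,
which is the ground truth the convergence tests check. Group effects are
multiplicative propensity shifts on chosen labels in a chosen phase,
applied to every non-reference group; `STRONG_NIGHT_WALK_EFFECT`
(walking ×2.5, rearing ×2, sleep ×0.5 at night) is the planted effect
used in the power tests. Distance is simulated as a clipped noisy linear
function of walking seconds so the 162-column path is exercised.

What the generator does **not** emulate: realistic ethograms or dwell
distributions (real bouts are heavy-tailed and history-dependent),
ultradian rhythms, habituation drift within a session, or label noise of
a video classifier. Tests passing on this generator demonstrate the
pipeline's arithmetic, calibration and power under its stated
assumptions — not classifier robustness on real video output.

## Numerical and scale choices

- All randomness flows through explicit integer seeds; identical seeds
  give byte-identical simulated projects and bit-identical analysis
  results.
- Event boundaries are rounded to 1 ms when written to TSV; the ≤1 ms
  coverage slack is absorbed by the minute binner.
- Degenerate inputs: constant feature matrices yield Z = 0 / p = 1 and a
  rank-0 ICA fallback rather than NaNs; single-class training folds
  (possible under permutation) predict the single class.
- Test-suite problem sizes: calibration uses 100–200 null replicates and
  power uses 100 seeded cohorts at the default study size; forest-heavy
  property tests use 60–150 trees (the analysis default is 500), and
  permutation checks use 99 permutations with 8–20 validation repeats.
  These sizes give the assertions comfortable statistical margins while
  keeping the suite around eight minutes on one CPU.
- Age for the meta-analysis table is days between birth date and
  recording start divided by 30.44 (mean Gregorian month).

## Known limitations

- Only one lights-off event per recording is supported; multi-day
  recordings must be split upstream.
- The minute-summary path cannot carry sub-minute temporal structure;
  the hour-summary path additionally blurs the lights-off alignment to
  hour resolution.
- Distance traveled is passed through, never computed from events.
- Three experimental groups at most; pairwise analyses beyond that are
  the user's responsibility to correct for multiplicity.
- The SVM branch validates honestly but — as the permutation machinery
  readily shows — small-cohort home-cage data rarely supports confident
  classifier claims; the PCA branch is the primary inference path.
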