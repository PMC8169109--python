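# Methods

This note documents the models, conventions and numerical choices behind
`dmsephys`, in the spirit of a methods section: what is computed, under
what assumptions, and where the genuinely open choices were made.

## Task model and time conventions

All event times are seconds relative to the onset of the sample tone —
the stimulus carrying the decision-relevant frequency — in every task
variant. Default trial timing: 0.2 s sample, 1.5 s delay, 0.2 s test
tone (or response cue), 1 s response window, 10 s inter-trial interval.
The response window opens at test-tone offset for DMS, at response-cue
offset for delayed go/no-go, and at sample-tone offset for plain
go/no-go; the last two anchors are a documented convention, since only
the task structure, not the anchor arithmetic, is fixed by the designs
these variants emulate.

Every interval in the package — response windows, epoch windows, PSTH
bins — is half-open, `[start, end)`, so consecutive bins partition time
exactly and no event is counted twice. Windows quoted relative to the
delay (e.g. "300–500 ms of the delay") are represented with an explicit
`delay_onset` reference and converted by adding the sample duration.

## Trial classification and session metrics

A trial counts as a lick response iff at least one lick falls in the
response window; delay-period licks are recorded but ignored (they are
not penalized in the task and carry no outcome information here).
Match-trial responses are hits, non-responses misses; nonmatch responses
are false alarms, non-responses correct rejections. The metrics

* performance = (H + CR) / (H + CR + FA + M)
* hit rate = H / (H + M), FA rate = FA / (FA + CR)

make hit + miss = 1 and CR + FA = 1 identities, which the tests assert
exactly. A rate with an empty denominator raises by default and becomes
NaN in permissive mode.

Per-subject metrics pool all of a subject's trials (across sessions)
before the metric is computed, rather than averaging session-level
values; with roughly equal session sizes the two coincide, and pooling
is the better-conditioned default at small trial counts.

Condition contrasts (laser ON vs OFF) compute the metric per subject and
condition, then test across subjects. The test is chosen by a
Shapiro–Wilk normality screen of the paired differences at α = 0.05:
normal-looking differences get the paired *t*-test, otherwise the
Wilcoxon rank-sum on the two per-subject samples — the nonparametric
fallback conventional in this literature (rather than the signed-rank
test, matching the practice the pipeline emulates). Multiple metrics are
tested uncorrected, one test per metric.

## Spike-train analyses

**Inclusion.** Units must exceed a whole-session mean rate of 2 Hz
(strict inequality). An optional quality flag drops units with more than
1% of inter-spike intervals below 2 ms, a refractory-violation signature
of cluster contamination; it is off by default because the synthetic
generator produces Poisson trains, which legitimately contain short
intervals.

**PSTH.** Spikes are binned at 10 ms; the unsmoothed per-bin rate is
count/(n_trials·binwidth), so rate × binwidth × n_trials sums exactly to
the spike count (asserted, along with linearity over trial subsets).
Smoothing convolves with a unit-sum Gaussian kernel, σ = 100 ms,
truncated at ±4σ. Near the edges the kernel mass falling outside the
span is renormalized away (dividing by the convolution of the kernel
with a constant), so a constant-rate input stays constant up to the
edges. Population PSTHs are unweighted means of unit PSTHs.

**Baseline.** The 0.5 s immediately before sample onset. Per-trial
baseline rates pair with per-trial epoch rates in the responsiveness
screen: a paired *t*-test per configured epoch (default: the sample
epoch plus successive 100 ms delay bins), a unit being task-related if
any epoch reaches p < 0.05, uncorrected. The tested epoch set is
configurable because which epochs enter such screens is rarely pinned
down; the default mirrors the displayed timecourse analyses.

**Bin significance timecourse.** For each 100 ms bin: (i) a
population-level Wilcoxon rank-sum of per-unit mean bin rates against
per-unit mean baseline rates; (ii) the fraction of units individually
significant, each unit tested by rank-sum of its per-trial bin rates
against baseline rates. The per-unit baseline sample is drawn from
sub-bins of the same 100 ms width tiling the baseline period — not from
the single pooled 0.5 s estimate — because rate estimates from windows
of different lengths differ in dispersion even at equal mean, which
would inflate the rank-sum false-positive rate on Poisson data. With
matched widths the null is exchangeable, and the per-bin significant
fraction calibrates to α (asserted on 150 flat units).

## ROC selectivity

The preferred stimulus is assigned once per unit — the identity with the
higher mean rate in the sample epoch, ties broken deterministically
toward the lower frequency — and reused for every epoch, so the
timecourse traces coherent preferred/nonpreferred responses. Because
preference is estimated from the data, the population-mean AUC under the
null sits slightly above 0.5 during the window used for assignment;
null expectations in tests are therefore established by simulation, not
assumed to be 0.5. (The standalone statistic on a-priori-labeled groups
does average 0.5, which is what the calibration targets check.)

For each 100 ms epoch the statistic places 12 evenly spaced thresholds
spanning the pooled [min, max] of the per-trial rates (both endpoints
included; the levels need only cover the range). Per threshold, the
fraction of preferred and nonpreferred trials with activity strictly
greater than the threshold gives one (FPR, TPR) point; the curve is
closed with (0, 0) and (1, 1) and integrated by trapezoid. Strict
exceedance means ties at a threshold count as non-exceeding. Both TPR
and FPR are nonincreasing in the threshold, so the points are already
monotone in FPR and the trapezoid is well defined. A degenerate pooled
range (all rates equal) returns 0.5. Consequences of these conventions,
asserted as properties:

* complete separation gives exactly 1 or 0;
* swapping the groups reflects the AUC about 0.5 up to the
  strict-inequality asymmetry, bounded by the threshold spacing (1/12);
* as the threshold count grows the statistic converges to the
  Mann–Whitney pair-count AUC with tie half-credit. At 200 thresholds
  the residual error on count-valued rates with ≥ 10 trials per group is
  below 0.02; the worst case in general is ~1/(2·n₁·n₂), reached when
  two near-coincident values from opposite groups fall inside one
  threshold gap and the trapezoid cuts the corner.

**Permutation test.** Trials are redistributed into two groups of the
original sizes (preserving sizes keeps the statistic exchangeable under
the null), 5000 times by default. The thresholds are computed once from
the pooled sample — it is invariant under regrouping — which makes the
null distribution fully vectorizable. When the number of distinct splits
is at most the requested permutation count the null is enumerated
exhaustively and p is exact; otherwise p carries add-one smoothing,
p = 2·min(tails)·(r+1)/(N+1)-style, capped at 1. "Extreme in either
tail at total level 5%" is read as a two-sided test at α = 0.05, i.e.
2.5% per tail, since that is the convention that makes the criterion
equivalent to p < 0.05; a 5%-per-tail variant is available via
`tail_convention="per_tail"`. Note that small groups bound the
attainable p from below: with 3+3 trials the 20 possible splits make the
smallest two-sided p exactly 0.1, so no 3+3 epoch can be significant at
0.05 — the exhaustive mode reports this honestly rather than
undershooting via sampling noise.

Per-epoch permutation seeds are derived deterministically from the
configured seed, the unit id and the epoch index, so every result is
bit-reproducible and independent across epochs.

## Synthetic data generator

The generator produces data with the statistical structure the analyses
assume — it is a calibration instrument, not a biophysical model.

**Behavior.** Outcomes are Bernoulli draws: lick with probability
`p_hit` on match trials and `p_fa` on nonmatch trials (defaults 0.88 and
0.32, typical of well-trained animals at criterion). Match/nonmatch and
laser ON/OFF trials are randomly interleaved. A laser window shifts the
probabilities additively (clamped to [0, 1]) only when at least half of
the laser window overlaps the "effective" window — stimulus plus early
delay, 0.2–1.0 s from sample onset by default. This single mechanism
reproduces the early-vs-late-delay dissociation the pipeline is designed
to detect: an early-delay laser moves the FA rate, a late-delay laser
changes nothing. Lick times on response trials are drawn uniformly
inside the response window, since only window membership matters
downstream.

**Spikes.** The intensity is piecewise: baseline `r0`; `r0 + a_s` during
the stimulus, with amplitude `a_pref` or `a_nonpref` by sample identity;
`r0 + a_s·exp(−(t−offset)/τ)` after offset; and exactly `r0` beyond a
hard truncation `t_end_from_onset` after stimulus **onset** (1.0 s for
the working-memory condition). Tying the truncation to onset rather than
offset encodes the observation that delay activity spans a fixed
interval from stimulus onset regardless of stimulus duration. τ defaults
to 0.5 s, which keeps the evoked trace well above baseline through the
early delay and makes the truncation visible as a sharp drop. The
passive-listening preset truncates at 0.5 s — the passive trace is known
only to be "much shorter", so this is a free modeling parameter, not a
measured constant. Sampling is per-bin thinning at 1 ms (rate treated as
constant within a bin, spike placed uniformly inside it), exact enough
for statistics aggregated over 100 ms epochs; the expected count matches
the analytic rate integral within Monte-Carlo error (asserted).

What the generator does **not** emulate: across-unit noise correlations,
non-Poisson spiking statistics (bursting, refractoriness), licking
kinematics, slow drift, behavioral learning, or any coupling between
neural activity and trial outcome. Passing tests therefore demonstrate
that the analysis chain is correct and calibrated on data satisfying its
own assumptions — not that real recordings satisfy those assumptions.

## File formats and reproducibility

Trial tables and spike tables are flat UTF-8 CSVs (schemas in
`pipeline.py`): one row per trial with semicolon-packed lick lists, one
spike per row at microsecond precision. Schema violations raise errors
naming the offending row and column. A unit that fired no spikes at all
has no representation in the spike format and is skipped on write with a
warning.

All randomness flows from explicit seeds through `numpy` seed
sequences: a master seed spawns per-subject, per-unit and per-epoch
streams, so the full pipeline is byte-reproducible (asserted) and units
are independent. The full-run driver writes a provenance sidecar with
the config hash, master seed and package version next to every output
set.

## Problem sizes in tests

The test and calibration suites use desk-scale problem sizes chosen so
that Monte-Carlo error bands stay decisive: 500–1000 simulated units for
null calibrations (permutation count reduced to 1000 from the 5000
default), 40-unit populations with 60 trials per stimulus for the
timecourse-recovery checks, and 50 replicate 8-subject experiments for
the behavioral power checks. Headline counts from large chronic-recording
datasets (hundreds of units over many sessions) are not reproducible at
these scales and are not targeted; the suite instead pins the identities,
calibrations and recovery properties that any faithful implementation
must satisfy.

## Known limitations

* The ROC statistic's strict-inequality convention makes it mildly
  asymmetric under group swap at few thresholds; use more thresholds if
  exact antisymmetry matters.
* The rank-sum population test in the bin timecourse compares per-unit
  means estimated from windows of different widths (bin vs full
  baseline); its null calibration is empirical, dominated by across-unit
  variability.
* Multi-tone (four-stimulus) sessions classify correctly, but ROC
  selectivity is defined for two-stimulus contrasts only; no pairwise
  extension is provided.
* No reaction-time, d′/criterion, decoding or correlation analyses.
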