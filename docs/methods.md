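# Methods

This note documents the statistical procedures, the synthetic-data model, the
numerical conventions, and the design choices made where the published
procedure left the details open.

## Design construction

The experiment is a 2 (occupation stereotype: female/male, intrinsic to each
display) × 3 (action stereotype: female/male/neutral) repeated-measures
design. Because a display's occupation cannot change across lists, the Latin
square rotates the six *within-item* variants — 3 action sentences × 2 agent
genders — across six lists: item *i* on list *l* receives variant
(*i* + *l*) mod 6. Occupation stereotype alternates along the item order, so
each occupation × action analysis cell contains exactly *n*/6 items per list
(7 for the 42-item set), and female/male agents are exactly balanced (21/21)
within every list. Across the six lists every item passes through all six
variants once.

Pseudo-randomization must start with a filler and never present more than two
experimental trials consecutively. Naive rejection sampling of full
permutations is infeasible (the acceptance probability at 42 experimental +
28 filler trials is ~10⁻¹⁰), so orders are sampled *exactly uniformly* over
the valid set: the number of ways to distribute the experimental trials into
per-filler gaps of size ≤ 2 is counted by dynamic programming, gap sizes are
drawn sequentially in proportion to the remaining counts, and filler and
experimental identities are shuffled independently. Feasibility requires
n_fillers ≥ ⌈n_experimental / 2⌉.

## Gaze model (synthetic data)

Gaze is a renewal process at fixation-report granularity: dwell times are
gamma(k = 4, mean 250 ms), fixations abut, and at each fixation onset an AOI
is drawn from a five-category multinomial (female character, male character,
two objects, elsewhere) whose probabilities are frozen at the onset time.
Baseline probabilities are (0.25, 0.25, 0.20, 0.20, 0.10).

Condition effects act on the log-odds of the target character. A cell with
anticipation onset *t₀* (ms relative to the critical noun) multiplies the
target's baseline weight by exp(Δ · r(t − t₀)), where Δ = logit(asymptote) −
logit(baseline) and r(u) = 2/(1 + e^(−0.01u)) − 1 for u > 0 (0 otherwise), a
logistic-shaped ramp that is exactly 0 before onset and saturates within a
few hundred ms. With only this adjustment active the target probability
approaches the asymptote exactly. A referential ramp toward the *named* agent
starts 200 ms after noun onset (oculomotor delay) with asymptote 0.75.
Participant and item random effects (SD 0.3 / 0.2 on the log-odds scale)
scale with the anticipation ramp, so flat ("null") profiles generate
genuinely exchangeable data.

Default anticipation profiles encode the qualitative pattern the analysis is
designed to detect: female-action trials ramp toward the female character
from −1200 ms (female-stereotypical occupations) or −800 ms (male-
stereotypical occupations) with asymptote 0.65; male-action trials ramp
toward the male character from −500 ms only in female-occupation contexts;
neutral and male/male cells show no anticipation. The asymptote and slope are
the generator's own calibration — no quantitative preference strength is
published — chosen as plausible visual-world magnitudes.

Trial timing: 3000 ms display preview, 500 ms audio lead, then a verb–noun
interval drawn from a normal(1719.26, 228.75) truncated at 0, and 1500 ms
after the noun. Filler engagement responses are Bernoulli(0.91).

Sampling uses a canonical category order with the target character first, so
relabelling genders everywhere (occupations, actions, agents, baseline) under
the same seed reproduces the identical dataset with female/male labels
swapped; downstream log-ratios are negated bit-for-bit. This mirror symmetry
is asserted exactly in the tests.

### Likert generator

Items load equally on one latent trait: xᵢⱼ = λFᵢ + √(1−λ²)εᵢⱼ, discretized
at equal-probability normal thresholds into the scale's integer range. The
loading solves α = kr/(1 + (k−1)r) for the target α, with r pre-compensated
for discretization by the analytically computed correlation between a normal
score and its m-category discretization. Recovered α for the NGRO target of
0.89 is within ±0.01 at n = 500.

### What the generator does not emulate

Saccade kinematics, smooth pursuit, blinks as distinct events (inter-fixation
gaps simply count as "elsewhere"), track loss, audio-envelope coupling, item-
specific semantics, and any dependence of gaze on attitude scores. Passing
tests therefore demonstrate the *procedures* are correct and calibrated, not
that real data would show these effects.

## Binning

A 1-ms sample at integer time w (relative to noun onset) belongs to a
fixation iff start ≤ w < end; samples covered by no fixation are "elsewhere".
Bins are half-open [t, t+100) tiling [−2000, +1000), 30 bins. The
implementation counts integers in [max(start, bin_lo), min(end, bin_hi)) in
closed form (⌈hi⌉ − ⌈lo⌉) and equals the literal indicator expansion exactly,
including fractional fixation times; this equivalence is a test invariant.
Trials with no fixations in the window yield zero proportions with
n_valid = 0, flagged rather than raised.

## Preference score and time courses

The log-ratio uses additive smoothing 0.5 on both counts (the empirical-logit
convention), computed per participant × trial × bin and averaged upward. It
is computed as log(f + 0.5) − log(m + 0.5) — a difference of logs, not the
log of a quotient — so antisymmetry under swapping the characters is exact in
floating point.

Within-subject CIs: Cousineau normalization (subtract each participant's mean
across the C condition cells, add the grand mean), per-condition SEM of the
normalized scores inflated by Morey's √(C/(C−1)), times the t quantile with
n−1 df. For C = 2 this equals the paired-difference CI half-width divided by
√2 — the identity frozen in the oracle test. C is whatever condition set the
summary is computed over (6 for the full design, 2 for occupation-only
log-ratio panels), matching the figure being drawn.

## Cluster-based permutation inference

**Stage 1 (per bin).** The default statistic collapses trials to participant
means and uses a paired t (occupation contrast within an action condition) or
one-sample t against zero (within one occupation × action cell), with the t
distribution on n−1 df for the cluster-forming threshold at α = 0.05.
A mixed-model statistic (`stat="mixed"`) fitting random intercepts for
participants and items (crossed, via variance components) is available and
agrees with the paired t on balanced data; it is impractical at thousands of
permutation iterations, and because the *same* statistic scores observed and
permuted data in either case, the permutation p-values are exact regardless
of which is chosen. Non-convergent mixed fits fall back to the paired t,
flagged.

**Cluster formation.** Maximal runs of consecutive significant bins with the
same t sign (a sign change splits a run — two-tailed summed-t mass is
otherwise ill-defined); the cluster statistic is the summed t.

**Stage 2 (null distributions).** Three schemes, 2000 iterations by default:
condition-swap permutes each participant's occupation labels across that
participant's trial series (whole series move together, preserving
within-trial autocorrelation); the two vs-zero schemes swap real/zero labels
per trial series, equivalent to sign-flipping the series. Each iteration
reruns the per-bin tests, forms clusters, and records the largest |summed t|
(0 when no cluster forms — conservative). The cluster p-value uses the
add-one estimator p = (1 + #{null ≥ |Σt|})/(1 + N); significance is strict
p < 0.025 (two-tailed 2.5% criterion). The permutation engine is fully
vectorized (einsum over iterations × participants × series × bins), making
hundreds of iterations per analysis essentially free.

The condition contrast defaults to occupation (female vs. male) within each
action condition — the orientation under which the reported anticipation
clusters are contrasts between occupation contexts — with the transposed
orientation (action contrast within occupation) available via
`contrast_factor="action"`.

## Attitude scales and regression

Scales are mean-scored (reverse-keyed items flipped as min + max − x; none
are flagged by default since the published instruments' keying is external to
this pipeline, but the definition object accepts them), with an 80% item-
coverage requirement per participant. Cronbach's α uses the standard
k/(k−1)·(1 − Σσᵢ²/σ_total²) with n−1 variances. Scores are z-standardized
across participants.

Pre-noun significant vs-zero clusters become clusters of interest; each
participant's log-ratio is averaged over the cluster's bins and its own
condition cell's trials. Negative-preference clusters (male-character
anticipation) are multiplied by −1 so all clusters share a preference scale.
The OLS regresses these aggregates on the three z-scored scales, a treatment-
coded three-level cluster factor, and all scale × cluster interactions;
refitting with each cluster as reference rotates the coefficients while
leaving fitted values identical (asserted to 10⁻¹⁰). Because the predictors
are centered, each model's intercept is exactly its reference cluster's mean
aggregate. Inference uses classical OLS standard errors. Participants missing
one cluster contribute their remaining rows (per-row, not listwise, deletion),
logged.

## Problem sizes and tolerances

Calibration checks run at reduced but statistically meaningful scale, chosen
as the package's own verification budget: type-I error on 100 null
experiments (24 participants, flat profiles, 200 permutation iterations;
acceptance band [0, 0.11], the binomial 95% band around 5% at n = 100),
onset recovery on 50 experiments (≥ 80% of earliest detected clusters within
±200 ms of the injected −1200 ms), α recovery over 20 replicates (±0.05),
and regression calibration over 200 simulations (null |t| ≥ 1.96 rate in
[0.01, 0.10]; injected slope recovered within 2 Monte-Carlo SE). Binning is
checked for *exact* equality against the indicator oracle on 1000 random
trials; mirror symmetry and reference-rotation invariance are exact
assertions.

## Known limitations

- The paired-t default treats participants as the sole random factor at the
  permutation stage; items enter only through averaging. The mixed statistic
  addresses this at small iteration counts.
- The generator's effect sizes are calibrated to the qualitative published
  pattern, not to quantitative fixation proportions; absolute summed-t values
  are therefore not comparable to any real dataset.
- AOI assignment supports rectangles only; real displays with irregular
  regions need pre-assigned AOI labels in the fixation report.
- No divergence-point analysis, GAMMs, or threshold-free cluster enhancement.
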