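# Methods

This note records the models, conventions and design choices behind
`ideaelicit`, in the order the pipeline applies them.

## Elicitation data model

A study consists of questions, participants and judgements. A question
carries hard domain bounds (`domain_min`, `domain_max`, in question
units; unbounded sides are ±∞, written as empty CSV cells), a positive
`grain_size` in question units, and an optional `realised_value`.
Questions without a realised value are legal — outcomes sometimes
cannot be validated — and are excluded from every score and every
accuracy-change computation, not just some of them.

A judgement is a four-step answer: ℓ′ ≤ b′ ≤ u′ within the question
domain, plus a stated confidence m′ as a **percent in (0, 100]**.
Confidence supplied as a proportion (≤ 1) in input files is rejected
with a validation error rather than rescaled: silent unit guessing is a
classic source of double-scaling bugs. Validation is total — every
malformed row is reported with its row number; nothing is dropped
silently. Participants may skip individual questions; all per-entity
scores use the entity's own question count Nʳ.

## Interval standardisation

Intervals are rescaled to a common target confidence j (default 80%,
config key `target_confidence_pct`) by linear extrapolation, scaling
each half-interval by the ratio j/m′ and leaving the best estimate
unchanged. The ratio convention means m′ = 100 shrinks an interval
(factor 0.8 at the default target) and m′ = 50 widens it (factor 1.6).
No parametric distribution (beta, betaPERT, log-normal) is fitted; the
linear form is deliberately simple, serves primarily to make intervals
comparable in feedback and discussion, and alternative distribution
fits are an extension point, not implemented.

Extrapolated bounds that leave the feasible domain (e.g. a negative
lower bound for a density) are truncated to the domain edge exactly,
and `truncated_low` / `truncated_high` flags are preserved so feedback
documents can show participants what standardisation did — they are
expected to revise in Round 2 if the extrapolation or truncation
misrepresents their belief. Stated confidences below the target are
allowed without a floor; extreme widening is handled by truncation, not
by capping m′.

## Group aggregation and withdrawal

Group judgements use quantile aggregation with the arithmetic mean:
component-wise means of members' best estimates and standardised
bounds. Means preserve order, so group intervals always satisfy
lower ≤ best ≤ upper. Members who did not answer a question are simply
absent from that question's mean (per-question `n_members` may vary);
no imputation is performed. Random allocation shuffles participants
with a seeded generator and deals them into groups whose sizes differ
by at most one, remainder to the first groups in shuffled order.

Withdrawal after Round 1 is handled by policy. `exclude` (default)
removes a withdrawn participant's judgements from the analysis set
before anything else happens — their values therefore cannot influence
aggregates, range contexts or any score in either round. `carry_forward_round1`
duplicates their Round-1 judgements as Round-2 judgements. The super
group aggregates every participant admitted by the policy; its Round-2
values are built from post-discussion judgements of members who only
interacted within their own sub-groups, so it is not equivalent to one
large interacting panel.

## Scoring

Range contexts (per-question pool extrema of best estimates, and the
background range spanned by the extreme standardised bounds) are
computed over **all individual judgements in the analysis set, both
rounds**; group aggregates and the realised truth never enter them.
Including both rounds keeps Round-1 and Round-2 scores on the same
scale. The truth is range-coded with the same pool extrema and may fall
outside [0, 1]; a coded value ≤ −1 is a domain error (the log-ratio
term is undefined there). A degenerate pool (all best estimates
identical) is refused with a typed error rather than returning 0/0; the
pipeline caller may drop the question.

Calibration is stored on the **proportion scale** ([0, 1]) everywhere;
percent appears only in rendered reports. Interval containment is
closed at both endpoints. Informativeness excludes questions with zero
background width (with a warning). Scores are kept at full float
precision; report tables round to 3 decimals. Group score cards are
direct evaluations of the same formulas on the aggregated judgements —
scoring is fully decoupled from aggregation, which the tests exploit by
cross-checking against brute-force loops.

## Update analysis

`delta_accuracy = |b₁ − x| − |b₂ − x|` (question units; positive =
improved). Direction is `unchanged` when the best estimate did not
change **or** the two distances tie exactly, keeping improved/worsened
a partition of the strict changes. Change detection uses exact
equality, no epsilon: elicited values are human-entered decimals, and a
simulated "no update" copies values bit-for-bit. A change is
`meaningful` when |delta_accuracy| ≥ the question's grain size.
Cross-entity medians of update counts get percentile-bootstrap 95%
intervals (10,000 seeded resamples); notched boxplots are only a visual
approximation of the same comparison.

## Synthetic study generator

The generator emulates the *measurable signatures* of a two-round
remote elicitation. Defaults describe a study of 76 experts in 8
groups answering 14 questions, one of which cannot be validated.

| parameter | default | meaning / rationale |
|---|---|---|
| `truth_log10_range` | (−1, 4) | question truths drawn log-uniformly across five decades, emulating heterogeneous scales (densities to discharge volumes) |
| `bias_mean`, `bias_sd` | 0, 0.3 | per-expert multiplicative (log-scale) offset; zero mean = unbiased-on-average panel |
| `noise_sd_range` | (0.15, 0.7) | per-expert log-scale judgement noise, spanning quite-accurate to order-of-magnitude-level error |
| `overconfidence_median`, `overconfidence_log_sd` | 1.3, 0.25 | ratio of the interval width a calibrated expert would need to the width given; the mildly overconfident median reproduces Round-1 calibration well below the 0.8 ideal, as typically observed |
| `stated_confidence_choices` | 50–100 by 10 | experts state their own confidence level; standardisation has real work to do |
| `p_withdraw` | 18/76 | Bernoulli withdrawal after Round 1 (≈24%) |
| `p_never_update`, `p_update_range` | 0.2, (0.15, 0.5) | a fifth of experts anchor completely; the rest revise each best estimate with moderate probability, yielding a median of ~3 best-estimate updates on 13 validated questions |
| `p_interval_only_update` | 0.3 | additional interval-only revisions (narrowing), yielding a median of ~7 interval updates |
| `update_weight` | 0.5 | geometric pull of an updated best estimate toward the Round-1 group mean |
| `interval_shrink_on_update` | 0.9 | log-scale half-width factor applied on revision |
| `grain_frac` | 0.1 | grain size = 10% of the truth, standing in for prior-data variability |

The noise model is multiplicative by default (`truth·exp(bias+noise)`)
because the accuracy score deliberately emphasises order-of-magnitude
error; an additive variant sits behind `noise_model="additive"`.
Intervals are equal-tailed around the best estimate on the log scale:
a calibrated expert's half-width at stated confidence m is
z₍(1+m/100)/2₎·noise_sd, divided by the overconfidence factor. An
expert stating 100% receives the 99.5% quantile width — a normal belief
has no finite 100% interval, yet real experts write finite bounds. With
overconfidence 1 and stated confidence equal to the target,
standardisation is the identity and interval coverage is exactly
m/100, which `coverage_oracle` verifies by brute-force simulation
independently of the pipeline path.

What the generator does **not** emulate: discussion content and
linguistic-ambiguity resolution (the big Round-2 corrections real
panels show), anchoring on supplied background data, recency effects,
and correlated errors across experts (shared biases). Mean-aggregated
intervals of independent-noise experts are therefore conservative —
simulated group calibration approaches 1.0, whereas real groups sharing
biases sit nearer the individual level. Passing tests consequently
demonstrate the correctness and invariances of the bookkeeping and
scores, and qualitative phenomena (wisdom of the crowd, overconfidence
recovery, update medians), not quantitative predictions about any real
panel. The group-mean-pull update model is a stand-in; no quantitative
model of real expert updating is claimed.

## Numerical and reporting choices

- CSV numbers are written with Python `repr`, so write→read round-trips
  are bit-exact; determinism tests compare output files byte-for-byte.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields (`seed`, `allocation_seed`, `bootstrap_seed`).
- Boxplot notches are median ± 1.58·IQR/√n — the standard approximate
  95% interval for a median — and the convention is printed in every
  figure caption. Feedback panels use a square-root axis by default
  (clearest spread for wide-ranging positive quantities); a linear axis
  is available by option.
- Feedback documents anonymise members (P1, P2, … in sorted-identifier
  order); the code↔identifier map is written only to the run log.
- Figures draw only values present in the emitted CSVs; no figure-only
  computation.

## Problem sizes

The test suite simulates studies at the default 76×8×14 shape; the
wisdom-of-the-crowd check runs 200 such studies (a few seconds each
batch), and calibration-recovery checks use cohorts of ≥ 10,000
expert-question pairs, where the binomial standard error of a mean
capture rate is below 0.4 percentage points.

## Known limitations

- The scoring rules are the interval-judgement conventions of the IDEA
  literature; they have not been certified proper, and the package does
  not implement the Classical-Model calibration/information scores,
  which presuppose elicited distribution quantiles.
- Performance-weighted aggregation and behavioural consensus procedures
  are out of scope; the scoring tables expose per-participant scores
  and metadata so such analyses can be run externally.
- The update analysis measures effects, not causes: without a control
  group, improvement cannot be attributed to discussion rather than
  mere revisiting.
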