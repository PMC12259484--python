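# Methods

## Scope and model

`riskdet` implements the computational core of a questionnaire-based
behavioural risk-assessment and tailored-advice pipeline for respiratory
pandemics, together with the analytics used to decide *which* psychological
determinants an intervention should target. It has four scientific parts: a
three-factor risk engine, an ABCD-based message-tailoring engine, CIBER /
Potential-for-Change determinant analytics, and a synthetic-cohort generator
that realises the statistical structure the analytics assume.

## Questionnaire model

A respondent record holds the ten risk-estimation answers (country, age band,
gender, work contexts, reasons for leaving the house, conditions for
isolating more, behaviours that would stop, ordinal distance keeping,
handwashing situations and thoroughness) plus a sparse map of
determinant-item scores. Determinant items operationalise the three Reasoned
Action Approach constructs — attitude, perceived norm, perceived behavioural
control — for three target behaviours (social distancing, self-isolation,
hand washing). The packaged default bank contains exactly 276 items, built as
systematic crossings of behaviour x construct x sub-determinant facet with
1–7 bipolar scales (the RAA convention). The facet *texts* are structural
placeholders: the bank reproduces the instrument's size and structure, not
its wording, which only exists in the original deployment's external
repository.

Planned missingness: each respondent opts in for an even number of items
between 0 and 20 and answers a uniformly random without-replacement subset of
that size. Because the subset is independent of the scores, the missingness
is ignorable and pairwise-complete estimators are unbiased (asserted by
simulation in the test suite).

The ordinal distance-keeping item doubles as the behaviour measure for the
determinant analysis, coded 1 ("almost never") to 5 ("almost always"). The
answer "I am never in public places" is stored verbatim but coded as missing
for analysis: without exposure to public places a distance-keeping frequency
is undefined.

## Risk engine

Risk decomposes into three factors: *exposure* (proximity / lack of
isolation), *hygiene* (lack of handwashing) and *uncontrollable*
(demographics). Each factor is

    score = clamp(100 * Σ w(a) * Π m(t) / scale_max, 0, 100)

where `w(a) >= 0` are the weights of the endorsed risk-conferring answers,
and (for the exposure factor only) `m(t) ∈ (0, 1]` are multiplicative
discounts for each endorsed willingness-to-isolate condition. Design choices
the source material leaves open, fixed here:

* **Additive aggregation within factor.** The minimal assumption given that
  only per-answer contributions, not a combination rule, are specified.
* **Protective answers carry weight 0** and act purely by displacing
  risk-conferring answers. For handwashing this is turned around: weight
  accrues for each protective practice *not* endorsed, plus explicit weights
  for the two actively risky answers ("never or occasionally wash", "none of
  the above" thoroughness). This keeps monotonicity exact: endorsing a
  protective practice can only lower the factor score.
* **Willingness-to-isolate answers as multipliers ≤ 1** (default 0.95 per
  endorsed trigger, 0.98 per behaviour the respondent would stop): they
  describe conditional rather than current behaviour, so they discount rather
  than add.
* **Weights are configuration**, loaded from JSON; the shipped default is
  uniform within factor (all risk answers weigh 1, distance graded linearly,
  age weights rising by decade, gender-neutral) with `scale_max` equal to the
  largest attainable sum, so the most risk-prone pattern scores 100. The
  engine's reproducible contract is the aggregation; any elicited weight set
  can be dropped in.
* **Categories** (low / moderate / high) use lower-inclusive cut points,
  default tertiles (33, 66) of the 0–100 range, configurable.

Structural invariants, enforced by exhaustive enumeration in the tests:
adding a risk answer never lowers the affected factor; adding a protective
answer never raises it; handwashing answers move only hygiene risk,
isolation/distance/work answers only exposure risk, demographics only
uncontrollable risk.

## Message tailoring

The message table is a flat TSV rendering of an acyclic behaviour change
diagram: each row links a persuasive *application* (the message text) to its
behaviour change principle, conditions for effectiveness, sub-determinant,
RAA determinant, and (sub-)behaviour, with a locale tag. The packaged table
is a synthetic English fixture (`abcd_en_synthetic.tsv`) with plausible
sub-determinants and messages per behaviour plus three reinforcement entries.

Selection is declarative: rules of the form `<field> <op> <value>` over the
respondent's answers, each tied to a behaviour and an integer priority. All
table entries of a behaviour with at least one firing rule are eligible;
eligible entries are ordered by firing-rule priority (descending), then the
respondent's factor risk for that behaviour (descending; distancing and
isolation share the exposure factor), then a fixed behaviour order
(self-isolation, distancing, handwashing), then stable table order; the list
is truncated to `max_messages` (default 6). Respondents for whom no rule
fires receive the reinforcement entries. Every message carries provenance
(entry + rule), emitted as JSON rather than an opaque encoded string.

## Determinant analytics (CIBER and PΔ)

Per item, against the behaviour measure:

* mean with a **99.99% t-interval** (n−1 degrees of freedom) — the ultra-wide
  interval makes the "room for improvement" judgement conservative;
* zero-order Pearson r with a **95% Fisher-z interval**
  (`tanh(atanh(r) ± z_crit / sqrt(n−3))`), pairwise-complete;
* **PΔ1** = `(max(x) − mean(x)) · r` for `r > 0`, `(min(x) − mean(x)) · r`
  for `r < 0`, 0 at `r = 0` — observed extrema, not scale bounds;
* **PΔ2** = `(q.95(x) − mean(x)) · r²` for `r > 0`; for `r < 0` the package
  computes `(q.05(x) − mean(x)) · r·|r|`, i.e. magnitude `|room| · r²` with
  the sign of r cancelling the sign of the room term exactly as it does in
  PΔ1, so both indices are non-negative whenever r ≠ 0. Trimming and
  squaring make PΔ2 less sensitive to outliers and to small correlation
  differences, hence more stable across samples (asserted numerically).

Numerical conventions that PΔ2 values depend on: quantiles use linear
interpolation between order statistics (numpy's default). Means, extrema and
quantiles are taken over all observed scores of an item; correlations over
pairwise-complete (item, behaviour) pairs. Degenerate inputs: a constant item
or behaviour vector makes r undefined — such items are *flagged* and listed
separately, never silently zeroed or dropped; an item answered by fewer than
`min_pairs` respondents (default 10) is reported as "insufficient data".
Exact linear dependence is snapped to r = ±1 and the corresponding CI bound
pinned. With only 3 complete pairs the Fisher half-width is infinite and the
CI degenerates to (−1, 1). No multiple-testing correction is applied: the
approach is estimation-based (wide intervals), not significance testing.

The cohort-level table is emitted in the three canonical orders — by PΔ1, by
PΔ2, and by r, all descending — and a target-selection flag implements the
two-criterion rule: the r interval excludes 0 in the favourable direction
AND the item mean lies below a ceiling (default `scale_min + 0.9 · range`);
a strongly correlated item whose mean already sits at the ceiling offers
nothing to change and is not selected. The diamond plot mirrors the table:
left panel jittered raw scores with 99.99% mean-CI diamonds, right panel 95%
correlation-CI diamonds on a fixed [−1, 1] axis; jitter is seeded, so the
figure is byte-reproducible.

## Synthetic cohorts

The generator is a latent Gaussian copula: one standard-normal distance-
keeping propensity per respondent drives both the ordinal behaviour answer
(via thresholds matched to the configured marginal) and every determinant
item (`x* = ρ·z + sqrt(1−ρ²)·ε`, shifted to the item scale by a latent
mean/sd — default (4.5, 1.5) on a 1–7 scale — then rounded and clipped).
Rounding attenuates the correlation; the truth record therefore stores both
the planted latent ρ and the *manifest* (post-discretisation) correlation,
estimated once by a 200,000-draw Monte Carlo seeded from the config seed.
Recovery checks compare estimates against the manifest value — expecting the
latent ρ back from discretised data would contradict the attenuation the
model itself implies.

Defaults are the pooled answer prevalences observed in the deployed tool
(e.g. distance marginal 0.9 / 1.9 / 8.7 / 23.6 / 61.5% plus 3.5% never in
public; 91.1% soap/sanitiser; funnel strata 27,424 : 11,635 : 63,850),
renormalised where the printed percentages carry rounding error. Values the
deployment did not report separately are fixed once as plausible choices and
flagged in the source: the split of "working from home or not working"
(63.1% jointly) into 40% / 23.1%, a 25% co-worker-contact rate, the split of
the pooled youngest/oldest age bands, and the opt-in distribution over
{0, 2, …, 20} (a quarter decline; mode at 20 among the willing).
`n_respondents` counts completed records; the two drop-out strata are derived
deterministically from the stratum proportions so the funnel's additivity
invariant holds exactly.

What the generator does **not** emulate: country heterogeneity, temporal
usage spikes, dependence among the multi-select risk answers or between
those answers and the determinant items (all drawn independently given the
marginals), and respondent-level response styles. Passing tests therefore
demonstrate that the pipeline recovers structure *of the kind the analysis
assumes*, not that real cohorts satisfy those assumptions.

## Problem sizes and reproducibility

The test suite and the acceptance script use cohorts of 1,000–5,000
respondents, 200 replicates for ranking recovery, 2,000 replicates for CI
coverage, and 1,000 random datasets for oracle-equivalence checks — sizes at
which sampling error is far smaller than the effects under test. All
randomness flows from explicit integer seeds (`numpy.random.default_rng`);
identical config + seed reproduces cohorts, tables and plots bit-for-bit.

## Known limitations

* The default risk weights are a documented uniform convention, not an
  expert elicitation; absolute factor scores are only meaningful relative to
  a weight set.
* The item bank reproduces structure, not item wording; analyses of real
  data must load the real bank.
* The tailoring ruleset is a faithful generalisation of answer-based
  selection, not a byte-level replica of any deployed mapping.
* Pairwise-complete correlations assume the planned missingness is the only
  missingness mechanism; respondent-initiated skipping would break
  ignorability.
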