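# Methods

## The screening model

Each candidate factor–stratum pair is reduced to a 2×2 table of
exposure ("yes" answer) against disease (self-reported allergy flag;
the OVERALL stratum counts a participant as a case when any of the
seven flags is set, mirroring a "none of the above" checkbox).
Unanswered items are excluded pairwise per question, not listwise, so
each table uses the maximum available data.

The association measure is the sample odds ratio with a Woolf (logit)
interval, `exp(ln OR ± z₁₋α/₂ · √(1/a+1/b+1/c+1/d))`, α = 0.05 by
default. The interval method is the standard choice for questionnaire
OR screens and has a closed form that an independent oracle can verify
cell by cell. Zero cells receive the Haldane–Anscombe correction
(+0.5 on all four cells, applied only when at least one cell is zero,
and flagged on the result); tables with an entirely empty margin
(nobody exposed, nobody unexposed, no cases or no controls) are
reported as non-estimable rather than corrected into a meaningless
number.

Significance is the rule the pipeline screens by: lower 95% bound
> 1.0. This is the upper one-sided 2.5% tail of the two-sided
interval, so a null factor is flagged ≈2.5% of the time per table.
**No multiple-testing correction is applied** — deliberately, since the
procedure's point is liberal hypothesis *generation*; with ~100 active
questions × 8 strata per round, tens of null findings per study are
expected, which is why the evaluation ratios (not individual flags) are
the study-level summary. This inflation is a property of the design,
documented rather than "fixed".

## Pool curation

Between rounds the pool evolves by three deterministic rules:

1. **Adequacy filter** — a proposal is dropped iff it cannot be
   answered yes/no (reason `inadequate_format`) or asks for personal
   information (`personal_info`). When both apply, the format reason is
   recorded (a question needs a fixable format before privacy review
   matters; any single-reason convention would do, this one is fixed).
2. **Synonym merge** — proposals are grouped by canonical
   `concept_key`; one survivor per group, the minimum
   `generality_rank`, ties broken by smallest question id. The manual
   free-text synonym check of a real deployment is replaced by exact
   key equality; text clustering is out of scope. Proposals whose
   concept the pool has already seen (active **or** retired) are
   dropped and counted as duplicates — retirement is permanent, and the
   duplicate count is itself a stopping diagnostic.
3. **Top-K retention** — after screening, active questions are ranked
   by (significant for ≥1 stratum first, then descending maximum OR
   across the 8 analyses, then ascending question id) and the first
   K = 99 are kept, the rest retired as `low_or`. "Maximum across all
   strata" is chosen so a factor strong for a single allergy type is
   not lost to a diluted OVERALL estimate; the id tie-break makes the
   rule a total order, hence reproducible.

Round 1 is special: seed questions only, proposal collection only, no
screening — a proposal is always validated one round after it is
collected. The engine always runs the configured number of rounds;
stopping is diagnostic-only (the per-round series of new hypotheses,
significant questions and duplicates is reported, not acted on).

## Evaluation

A finished study is scored against a registry of known risk concepts
(default instance: 16 known, 8 of them seeds). "Answered" means the
concept appeared as a screened question in any round (seeds therefore
always count); "significant" at the concept level means significant on
the OVERALL stratum in any round — per-stratum findings are reported in
the screening tables but do not feed the four ratios. Zero
denominators yield an explicit undefined marker, never an exception.

Display formatting follows the mixed conventions such studies print:
truncated integer percents and truncated two-decimal ratios for the
evaluation ratios, half-up one-decimal percents for prevalence tables.
Both are explicit styles (`format_ratio`) rather than one global rule;
decimal arithmetic on the shortest float representation avoids binary
rounding artefacts.

## The synthetic crowd

The generator emulates the study design the analysis assumes:

- **Cohort**: 502 participants per round by default (gender ≈ 303:199
  male:female, age bands 20–69). Allergy flags are independent
  Bernoulli draws at the per-type prevalences 38/502, 183/502, 130/502,
  59/502, 26/502, 13/502, 12/502; under independence the OVERALL
  prevalence is ≈65%, a little above the 59.4% a positively
  comorbid real cohort shows. An optional Gaussian-copula
  equicorrelation (`comorbidity_rho`) induces co-occurrence; the
  default is independence because no joint distribution is specified by
  the design being emulated.
- **Exposures**: generated conditionally on disease status
  (case-control style): P(exposed | control) = p₀ and
  P(exposed | case) = OR·ω/(1+ω·OR) with ω = p₀/(1−p₀), so the planted
  OR is exactly the estimand of the screen. When a factor affects
  several of a participant's allergies, the **maximum** OR governs —
  a simple documented choice; no joint effect model is implied. A 2%
  item-nonresponse rate exercises the unanswered-data path.
- **Proposals**: each participant submits 1–5 proposals, count
  distribution {1: .45, 2: .25, 3: .15, 4: .10, 5: .05} (most
  respondents satisfy the minimum, few use the cap — typical free-form
  survey behaviour). Topics are drawn from a finite universe —
  16 known risks, 30 planted true factors (default OR 3.0), 120 nulls —
  with Zipf-decaying salience weights (1/rank^1.1 over a shuffled
  order): common ideas surface in round 1, rare ones trickle in later,
  which is the mechanism behind the declining new-hypothesis series.
  10% of proposals are inadequate (format or privacy, split evenly),
  15% are synonym variants (generality rank 1 vs the canonical 0), and
  allergy-positive participants over-sample real-effect concepts
  3× (patient expertise). Known risks carry heterogeneous planted ORs
  (cycling 3.0 / 2.0 / 1.5 / 1.2) so seed significance is a genuine
  mixture rather than saturated; per-concept baseline exposure is drawn
  once from Uniform(0.1, 0.4).
- **Returners**: each participant re-enrols next round with
  probability 0.22, keeping id, profile, allergy flags and any answer
  they already gave (latent exposure is stable); fresh participants
  fill the remainder.

What the generator does **not** emulate: free-text wording and the NLP
problems of real synonym detection, demographic confounding,
self-report misclassification, panel attrition beyond the returner
fraction, and causal directionality (symptom-like or
countermeasure-like factors can be planted as associations, but no
causal semantics are modelled). Passing tests therefore demonstrate
the pipeline's statistical and procedural behaviour under its own
assumptions, not the validity of any real crowd's answers.

## Determinism and numerics

Every random draw flows through a `numpy` Generator seeded from
(crowd seed, round seed, round index), so a fixed seed makes the full
study bit-reproducible and adding rounds never perturbs earlier ones.
Surviving proposals are assigned ids in sorted concept order; all
ranking rules end in an id tie-break. The z-quantile is cached per α.
Screening uses a vectorised tally over a coded answer matrix that is
provably (and test-enforced) identical to per-pair table construction.

## Problem sizes used in tests and the acceptance script

Operating characteristics are measured at the scale where they are
stable yet quick: interval coverage and the null false-positive rate
over 2,000 simulated tables of 250 cases / 250 controls at p₀ = 0.2
(binomial Monte-Carlo error ≈0.5 and ≈0.35 percentage points
respectively); power over 250 cohort replicates per planted OR at
n = 502; the declining-series property over 20 replicate five-round
studies at 502 participants per round. Monotonicity of power across
planted ORs is asserted with a two-standard-error allowance per step
for replicate noise.

## Known limitations

- Exact/Fisher intervals, Bayesian shrinkage and stratified
  (Mantel–Haenszel) estimation are out of scope; the screen is the
  plain Woolf method by design.
- Concept-level evaluation assumes canonical keys; two genuinely
  different phrasings of one idea in real data would need text
  normalisation upstream.
- The per-study unique-participant count emerges from the per-round
  cohort size and the returner fraction; it is not controlled directly.
- With max-effect aggregation, protective effects (OR < 1) on one
  allergy cannot lower exposure below baseline for a participant who
  also has a risk-increasing allergy for the same factor.
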