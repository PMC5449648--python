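"""Sample a synthetic round-1 cohort and print its prevalence table.

The default scenario emulates a 502-adult crowdsourced cohort with the
study-design per-allergy prevalences; the prevalence report mirrors the
participant table such a study would publish (count, denominator,
half-up one-decimal percentage).
"""

import numpy as np

from crowdscreen import make_study_scenario, prevalence_report, sample_cohort

scenario = make_study_scenario(rng_seed=7)
rng = np.random.default_rng(7)
cohort = sample_cohort(
    scenario.config, 1, None, scenario.seed_pool, rng,
    universe=scenario.universe,
)

print(f"sampled {len(cohort)} participants; "
      f"seed questions: {[q.concept_key for q in scenario.seed_pool.active]}")
print(prevalence_report(cohort).to_string(index=False))
# Each row: how many unique participants report that allergy type.
# 'Total' counts anyone with at least one of the seven flags set.
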