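"""Operating-characteristic simulations for the screening procedure.

Because the original crowd's raw answers are not public, the screen is
validated by its statistical behaviour instead of by reproducing
per-factor estimates: confidence-interval coverage, the null
false-positive rate implied by the one-sided significance rule, and
power against planted effects at the study's sample size.
"""

from __future__ import annotations

import numpy as np

from .crowd import CrowdModelConfig, case_exposure_probability, sample_cohort
from .pool import QuestionPool
from .records import OVERALL, Question
from .stats import TwoByTwoTable, odds_ratio, screen_pool

__all__ = [
    "simulate_case_control_table",
    "ci_coverage",
    "null_significance_rate",
    "detection_rate",
]


def simulate_case_control_table(
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    p0: float,
    true_or: float,
) -> TwoByTwoTable:
    """One simulated 2x2 table with a known true odds ratio.

    Controls are exposed with probability ``p0``, cases with the
    odds-inverted probability, so ``true_or`` is the exact estimand.
    """
    p1 = case_exposure_probability(p0, true_or)
    a = int(rng.binomial(n_cases, p1))
    b = int(rng.binomial(n_controls, p0))
    return TwoByTwoTable(a, b, n_cases - a, n_controls - b)


def ci_coverage(
    true_or: float,
    seed: int,
    n_reps: int = 2000,
    n_cases: int = 250,
    n_controls: int = 250,
    p0: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Empirical coverage of the Woolf interval for a known OR."""
    rng = np.random.default_rng([abs(seed), 101])
    covered = 0
    for _ in range(n_reps):
        table = simulate_case_control_table(rng, n_cases, n_controls, p0, true_or)
        res = odds_ratio(table, alpha=alpha)
        covered += res.ci_low <= true_or <= res.ci_high
    return covered / n_reps


def null_significance_rate(
    seed: int,
    n_reps: int = 2000,
    n_cases: int = 250,
    n_controls: int = 250,
    p0: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Share of null (OR = 1) tables flagged significant.

    The rule "lower bound > 1" is the upper one-sided tail of the
    two-sided interval, so the expected rate is alpha / 2.
    """
    rng = np.random.default_rng([abs(seed), 202])
    flagged = 0
    for _ in range(n_reps):
        table = simulate_case_control_table(rng, n_cases, n_controls, p0, 1.0)
        flagged += odds_ratio(table, alpha=alpha).significant
    return flagged / n_reps


def detection_rate(
    true_or: float,
    seed: int,
    n_reps: int = 200,
    n_participants: int = 502,
    p0: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Power of the screen against an OVERALL-stratum planted factor.

    Each replicate samples a full synthetic cohort (allergy flags at the
    default prevalences), screens one planted question on the OVERALL
    stratum and records whether it is flagged significant.
    """
    config = CrowdModelConfig(
        n_participants=n_participants,
        factor_effects={("factor_x", OVERALL): true_or},
        baseline_exposure={"factor_x": p0},
        nonresponse_rate=0.0,
    )
    pool = QuestionPool(active=[Question("q1", "factor_x", origin="seed")])
    rng = np.random.default_rng([abs(seed), 303])
    hits = 0
    for _ in range(n_reps):
        cohort = sample_cohort(config, 1, None, pool, rng)
        screening = screen_pool(cohort, pool.active, [OVERALL], alpha=alpha)
        result = screening.results.get(("q1", OVERALL))
        hits += bool(result is not None and result.significant)
    return hits / n_reps
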