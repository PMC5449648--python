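"""The iterative generate-and-validate round engine.

One round of the procedure, for rounds 2 and later:

1. screen every active question against the round's responses
   (odds ratio per stratum, significance = lower 95% bound > 1);
2. retain the top-K questions by screening rank, retiring the rest;
3. filter the round's new proposals for adequacy, merge synonyms, drop
   concepts the pool has already seen;
4. append the surviving proposals to the pool, to be asked (and
   screened) from the next round on.

Round 1 is special: it asks only the seed questions and collects
proposals, with no screening — validation of a proposal always lags its
collection by one round.  The engine always runs the configured number
of rounds; stopping is diagnostic-only (the declining count of new
hypotheses per round is reported, not acted on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .errors import CrowdScreenError, EmptyResponsesError, StudyError
from .pool import QuestionPool, filter_inadequate, merge_synonyms, retain_top_k
from .records import ParticipantResponse, Question
from .stats import ScreeningResult, screen_pool

__all__ = [
    "RoundConfig",
    "RoundResult",
    "StudyResult",
    "make_round_configs",
    "run_round",
    "run_study",
    "stopping_diagnostics",
    "is_non_increasing",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoundConfig:
    """Configuration of one questionnaire round."""

    round_index: int
    n_participants: int = 502
    k_retain: int = 99
    alpha: float = 0.05
    proposals_min: int = 1
    proposals_max: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.k_retain < 1:
            raise ValueError("k_retain must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.proposals_min <= self.proposals_max:
            raise ValueError("need 1 <= proposals_min <= proposals_max")


def make_round_configs(
    n_rounds: int = 5,
    n_participants: int = 502,
    seed: int = 0,
    k_retain: int = 99,
    alpha: float = 0.05,
) -> list[RoundConfig]:
    """Round configs sharing one global seed (per-round streams are
    derived from (seed, round index), so earlier rounds are unaffected
    by adding rounds)."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    return [
        RoundConfig(
            round_index=r,
            n_participants=n_participants,
            k_retain=k_retain,
            alpha=alpha,
            rng_seed=seed,
        )
        for r in range(1, n_rounds + 1)
    ]


@dataclass
class RoundResult:
    """Output of one round.

    ``retained_pool`` is the pool handed to the next round: the top-K
    survivors of screening plus the round's surviving new proposals
    (round 1: seeds plus proposals).  ``n_new_proposals`` counts
    proposals that survived adequacy filtering, synonym merging and the
    already-seen check; ``n_duplicate_concepts`` counts proposals merged
    away (within-round synonyms + repeats of pool concepts);
    ``n_significant`` counts screened questions significant for at least
    one stratum.
    """

    round_index: int
    screening: ScreeningResult
    retained_pool: QuestionPool
    n_new_proposals: int
    n_significant: int
    n_duplicate_concepts: int
    responses: list[ParticipantResponse] = field(default_factory=list)


@dataclass
class StudyResult:
    """Ordered round results plus the stopping-diagnostic series."""

    rounds: list[RoundResult]
    final_pool: QuestionPool
    new_hypothesis_series: list[int]
    significant_series: list[int]
    question_index: dict[str, Question] = field(default_factory=dict)


def _collect_new_questions(
    pool: QuestionPool,
    responses: Sequence[ParticipantResponse],
    round_index: int,
) -> tuple[list[Question], int]:
    """Adequacy-filter, merge and deduplicate the round's proposals.

    Returns the surviving questions (fresh ids, introduced next round)
    and the number of proposals merged away as duplicates.
    """
    proposals = [p for record in responses for p in record.proposals]
    kept, dropped = filter_inadequate(proposals)
    merged, merge_map = merge_synonyms(kept)
    seen = pool.concept_keys_seen()
    fresh = [q for q in merged if q.concept_key not in seen]
    n_duplicates = len(merge_map) + (len(merged) - len(fresh))
    logger.info(
        "round %d proposals: %d collected, %d inadequate, %d merged/duplicate, "
        "%d new",
        round_index,
        len(proposals),
        len(dropped),
        n_duplicates,
        len(fresh),
    )
    survivors = [
        replace(
            q,
            question_id=f"r{round_index + 1}_{i:03d}",
            round_introduced=round_index + 1,
            origin="crowd",
        )
        for i, q in enumerate(sorted(fresh, key=lambda q: q.concept_key))
    ]
    return survivors, n_duplicates


def run_round(
    pool: QuestionPool,
    responses: Sequence[ParticipantResponse],
    config: RoundConfig,
) -> RoundResult:
    """Execute one round: screen, retain, collect proposals, grow pool.

    Round 1 performs no screening (seed questions only, proposal
    collection only); later rounds screen then retain before appending
    the new proposals.
    """
    responses = list(responses)
    if not pool.active:
        raise CrowdScreenError("round requires a non-empty active pool")
    if not responses:
        raise EmptyResponsesError(f"round {config.round_index}: no responses")

    if config.round_index == 1:
        screening = ScreeningResult.empty()
        working = pool
        n_significant = 0
    else:
        logger.info(
            "round %d: screening %d questions", config.round_index, len(pool.active)
        )
        screening = screen_pool(responses, pool.active, alpha=config.alpha)
        n_significant = sum(
            any(r.significant for r in entries)
            for entries in screening.by_question().values()
        )
        working = retain_top_k(pool, screening, k=config.k_retain)

    survivors, n_duplicates = _collect_new_questions(
        working, responses, config.round_index
    )
    next_pool = QuestionPool(
        active=list(working.active) + survivors,
        retired=list(working.retired),
    )
    return RoundResult(
        round_index=config.round_index,
        screening=screening,
        retained_pool=next_pool,
        n_new_proposals=len(survivors),
        n_significant=n_significant,
        n_duplicate_concepts=n_duplicates,
        responses=responses,
    )


def run_study(
    round_configs: Sequence[RoundConfig],
    crowd,
    initial_pool: QuestionPool,
) -> StudyResult:
    """Run the full multi-round study.

    ``crowd`` is anything with ``sample_round(pool, round_config,
    prior_responses)`` — a live :class:`~crowdscreen.crowd.CrowdSampler`
    or a :class:`~crowdscreen.crowd.RecordedCrowd` replaying saved
    responses.  Errors are re-raised with the failing round attached.
    """
    if not round_configs:
        raise StudyError("at least one round must be configured")
    pool = initial_pool
    prior: list[ParticipantResponse] | None = None
    rounds: list[RoundResult] = []
    question_index = {q.question_id: q for q in initial_pool.active}
    for config in round_configs:
        try:
            responses = crowd.sample_round(pool, config, prior)
            result = run_round(pool, responses, config)
        except CrowdScreenError as exc:
            raise StudyError(f"round {config.round_index}: {exc}") from exc
        pool = result.retained_pool
        question_index.update({q.question_id: q for q in pool.active})
        prior = result.responses
        rounds.append(result)
    return StudyResult(
        rounds=rounds,
        final_pool=pool,
        new_hypothesis_series=[r.n_new_proposals for r in rounds],
        significant_series=[r.n_significant for r in rounds],
        question_index=question_index,
    )


def is_non_increasing(series: Sequence[float]) -> bool:
    """True when every step of the series is flat or falling."""
    return all(x >= y for x, y in zip(series, series[1:]))


def stopping_diagnostics(study: StudyResult) -> pd.DataFrame:
    """Per-round stopping diagnostics.

    One row per round with the number of new hypotheses, significant
    questions and duplicate (merged-away) proposals.  The frame's
    ``attrs['monotone_decrease']`` flags a non-increasing new-hypothesis
    series — the study's indication that further rounds would add little.
    """
    if not study.rounds:
        raise StudyError("study has no rounds")
    frame = pd.DataFrame(
        {
            "round": [r.round_index for r in study.rounds],
            "n_new": [r.n_new_proposals for r in study.rounds],
            "n_significant": [r.n_significant for r in study.rounds],
            "n_duplicate_concepts": [r.n_duplicate_concepts for r in study.rounds],
        }
    )
    frame.attrs["monotone_decrease"] = is_non_increasing(
        study.new_hypothesis_series
    )
    return frame
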