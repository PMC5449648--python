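"""The evolving question pool: adequacy filtering, synonym merging,
top-K retention.

The pool mirrors how the study curates crowd proposals between rounds:
proposals that cannot be answered yes/no or that ask for personal
information are dropped; near-duplicate phrasings of one concept are
merged, keeping the most general variant; and after screening only the
top-K questions by odds-ratio rank survive into the next round.
Retirement is permanent: a retired question never re-enters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import MissingScreeningError
from .records import Question
from .stats import OddsRatioResult, ScreeningResult

__all__ = [
    "RETIREMENT_REASONS",
    "RetiredQuestion",
    "QuestionPool",
    "filter_inadequate",
    "merge_synonyms",
    "retain_top_k",
]

RETIREMENT_REASONS = frozenset(
    {"inadequate_format", "personal_info", "synonym_merged", "low_or"}
)


@dataclass(frozen=True)
class RetiredQuestion:
    question: Question
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in RETIREMENT_REASONS:
            raise ValueError(
                f"reason must be one of {sorted(RETIREMENT_REASONS)}, "
                f"got {self.reason!r}"
            )


@dataclass
class QuestionPool:
    """Active questions plus the retirement log.

    Invariants: question ids are unique across active + retired, and
    every retired question carries exactly one reason.
    """

    active: list[Question] = field(default_factory=list)
    retired: list[RetiredQuestion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [q.question_id for q in self.active] + [
            r.question.question_id for r in self.retired
        ]
        if len(ids) != len(set(ids)):
            raise ValueError("question ids must be unique within a pool")

    def concept_keys_seen(self) -> set[str]:
        """Every concept ever in the pool, active or retired."""
        return {q.concept_key for q in self.active} | {
            r.question.concept_key for r in self.retired
        }

    # -- JSON serialisation (lossless round-trip) ------------------------

    def to_dict(self) -> dict:
        return {
            "active": [asdict(q) for q in self.active],
            "retired": [
                {"question": asdict(r.question), "reason": r.reason}
                for r in self.retired
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "QuestionPool":
        return cls(
            active=[Question(**q) for q in payload.get("active", [])],
            retired=[
                RetiredQuestion(Question(**r["question"]), r["reason"])
                for r in payload.get("retired", [])
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuestionPool":
        return cls.from_dict(json.loads(Path(path).read_text()))


def filter_inadequate(
    proposals: Iterable[Question],
) -> tuple[list[Question], list[RetiredQuestion]]:
    """Drop proposals that fail the adequacy criteria.

    A proposal is dropped iff it does not admit a yes/no answer (reason
    ``inadequate_format``) or asks for personal information (reason
    ``personal_info``); when both apply, the format reason is recorded.
    Order of the kept proposals is preserved.
    """
    kept: list[Question] = []
    dropped: list[RetiredQuestion] = []
    for q in proposals:
        if not q.requires_yes_no:
            dropped.append(RetiredQuestion(q, "inadequate_format"))
        elif q.asks_personal_info:
            dropped.append(RetiredQuestion(q, "personal_info"))
        else:
            kept.append(q)
    return kept, dropped


def merge_synonyms(
    proposals: Sequence[Question],
) -> tuple[list[Question], dict[str, str]]:
    """Collapse proposals sharing a concept to their most general variant.

    Within each ``concept_key`` group exactly one survivor is kept: the
    minimum ``generality_rank``, ties broken by smallest question id.
    The merge map records loser id -> survivor id.  Idempotent.
    """
    groups: dict[str, list[Question]] = {}
    for q in proposals:
        groups.setdefault(q.concept_key, []).append(q)
    survivor_of = {
        key: min(members, key=lambda q: (q.generality_rank, q.question_id))
        for key, members in groups.items()
    }
    merged = [q for q in proposals if survivor_of[q.concept_key] is q]
    merge_map = {
        q.question_id: survivor_of[q.concept_key].question_id
        for q in proposals
        if survivor_of[q.concept_key] is not q
    }
    return merged, merge_map


def _rank_key(
    question: Question,
    entries: Sequence[OddsRatioResult],
) -> tuple[int, float, str]:
    significant = any(e.significant for e in entries)
    max_or = max(e.or_point for e in entries)
    return (0 if significant else 1, -max_or, question.question_id)


def retain_top_k(
    pool: QuestionPool,
    screening: ScreeningResult | Mapping[tuple[str, str], OddsRatioResult],
    k: int = 99,
) -> QuestionPool:
    """Keep the top-``k`` active questions by screening rank.

    Questions are ranked by (significant for any stratum first, then
    descending maximum odds ratio across strata, then ascending question
    id); the first ``min(k, |active|)`` are retained, the rest retired
    with reason ``low_or``.  Every active question must have at least
    one screening entry.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    results = (
        screening.results if isinstance(screening, ScreeningResult) else screening
    )
    per_question: dict[str, list[OddsRatioResult]] = {}
    for (qid, _label), res in results.items():
        per_question.setdefault(qid, []).append(res)

    def key(q: Question) -> tuple[int, float, str]:
        entries = per_question.get(q.question_id)
        if not entries:
            raise MissingScreeningError(
                f"active question {q.question_id!r} has no screening entry"
            )
        return _rank_key(q, entries)

    ranked = sorted(pool.active, key=key)
    cut = min(k, len(ranked))
    retained = ranked[:cut]
    retired = pool.retired + [RetiredQuestion(q, "low_or") for q in ranked[cut:]]
    return QuestionPool(active=retained, retired=retired)
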