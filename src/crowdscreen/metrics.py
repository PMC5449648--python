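"""Evaluation of a finished study against a registry of known risks.

Because genuinely novel hypotheses cannot be validated from inside the
study, the pipeline is evaluated by how well it re-finds and confirms
*known* risk factors, via four ratios:

- RKRR (rediscovered known risk ratio) = known risks that appeared among
  the screened questions / all known risks — the coverage of the crowd.
- SKRR (significant known risk ratio) = significant known answers /
  known answers — validity of the crowd's rediscoveries.
- SSRR (significant seed risk ratio) = significant seeds / seeds —
  validity of the method on the planted starting questions.
- SUAR (significant unknown answer ratio) = significant answers that are
  not known risks / all significant answers — the share of candidate
  novelty in the output.

"Significant" at the concept level means significant on the OVERALL
stratum in any round.  "Answered" means the concept appeared as a
screened question in any round; seed concepts always count as answered
since they are part of the questionnaire from round 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import TYPE_CHECKING, AbstractSet

from .errors import CrowdScreenError, FormatStyleError
from .records import OVERALL

if TYPE_CHECKING:  # pragma: no cover
    from .engine import StudyResult

__all__ = [
    "KnownRiskRegistry",
    "PartitionCounts",
    "EvaluationReport",
    "partition_answers",
    "compute_ratios",
    "format_ratio",
    "evaluate_study",
]


@dataclass(frozen=True)
class KnownRiskRegistry:
    """Registry of known risk concepts and the seed subset.

    The default study instance has 16 known concepts of which 8 serve as
    seed questions; both sets are configurable.
    """

    known_concepts: frozenset[str]
    seed_concepts: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "known_concepts", frozenset(self.known_concepts))
        object.__setattr__(self, "seed_concepts", frozenset(self.seed_concepts))
        if not self.seed_concepts <= self.known_concepts:
            raise ValueError("seed_concepts must be a subset of known_concepts")


@dataclass(frozen=True)
class PartitionCounts:
    """The answer-vs-known-risk partition behind the four ratios."""

    known_total: int
    known_answered: int
    known_answered_significant: int
    seed_total: int
    seed_significant: int
    unknown_significant: int
    significant_total: int

    def __post_init__(self) -> None:
        if self.known_answered > self.known_total:
            raise ValueError("known_answered cannot exceed known_total")
        if self.seed_significant > self.seed_total:
            raise ValueError("seed_significant cannot exceed seed_total")
        if (
            self.unknown_significant + self.known_answered_significant
            != self.significant_total
        ):
            raise ValueError(
                "unknown_significant + known_answered_significant must equal "
                "significant_total"
            )


@dataclass(frozen=True)
class EvaluationReport:
    """The four ratios (``None`` marks an undefined ratio) + partition."""

    rkrr: float | None
    skrr: float | None
    ssrr: float | None
    suar: float | None
    partition: PartitionCounts

    def formatted(self) -> dict[str, str]:
        """Display strings in the study's mixed rounding conventions."""
        return {
            "rkrr": format_ratio(self.rkrr, "percent_trunc"),
            "skrr": format_ratio(self.skrr, "percent_trunc"),
            "ssrr": format_ratio(self.ssrr, "ratio_trunc2"),
            "suar": format_ratio(self.suar, "ratio_trunc2"),
        }

    def to_dict(self) -> dict:
        return {
            "ratios": {
                "rkrr": self.rkrr,
                "skrr": self.skrr,
                "ssrr": self.ssrr,
                "suar": self.suar,
            },
            "formatted": self.formatted(),
            "partition": asdict(self.partition),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def partition_answers(
    registry: KnownRiskRegistry,
    answered_concepts: AbstractSet[str],
    significant_concepts: AbstractSet[str],
) -> PartitionCounts:
    """Partition concepts into the known/answered/significant cells.

    ``answered_concepts`` are concepts that appeared as a screened
    question in any round; seeds are always counted as answered.
    ``significant_concepts`` must be a subset of the answered concepts
    plus the seeds.
    """
    answered = set(answered_concepts) | set(registry.seed_concepts)
    significant = set(significant_concepts)
    stray = significant - answered
    if stray:
        raise CrowdScreenError(
            "significant concepts must be answered (or seeds); "
            f"offending: {sorted(stray)}"
        )
    known = registry.known_concepts
    seeds = registry.seed_concepts
    return PartitionCounts(
        known_total=len(known),
        known_answered=len(known & answered),
        known_answered_significant=len(known & significant),
        seed_total=len(seeds),
        seed_significant=len(seeds & significant),
        unknown_significant=len(significant - known),
        significant_total=len(significant),
    )


def _ratio(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return numerator / denominator


def compute_ratios(partition: PartitionCounts) -> EvaluationReport:
    """The four evaluation ratios from a partition.

    Zero denominators yield ``None`` (an explicit undefined marker),
    never an exception; each ratio depends only on its own denominator.
    """
    return EvaluationReport(
        rkrr=_ratio(partition.known_answered, partition.known_total),
        skrr=_ratio(partition.known_answered_significant, partition.known_answered),
        ssrr=_ratio(partition.seed_significant, partition.seed_total),
        suar=_ratio(partition.unknown_significant, partition.significant_total),
        partition=partition,
    )


def format_ratio(value: float | None, style: str) -> str:
    """Render a proportion in one of the study's display conventions.

    - ``percent_trunc``: integer percent, truncated toward zero
      (13/16 -> "81%").
    - ``ratio_trunc2``: two decimals, truncated toward zero
      (53/61 -> "0.86").
    - ``percent_round1``: one-decimal percent, rounded half-up
      (298/502 -> "59.4%").

    ``None`` renders as ``"undefined"``.  Decimal arithmetic on the
    shortest float repr avoids binary artefacts such as
    ``0.29 * 100 == 28.999...``.
    """
    if style not in ("percent_trunc", "ratio_trunc2", "percent_round1"):
        raise FormatStyleError(f"unknown format style {style!r}")
    if value is None:
        return "undefined"
    dec = Decimal(repr(float(value)))
    if style == "percent_trunc":
        pct = (dec * 100).to_integral_value(rounding=ROUND_DOWN)
        return f"{pct}%"
    if style == "ratio_trunc2":
        return str(dec.quantize(Decimal("0.01"), rounding=ROUND_DOWN))
    pct = (dec * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


def evaluate_study(
    study: "StudyResult", registry: KnownRiskRegistry
) -> EvaluationReport:
    """Evaluate a finished study against a known-risk registry.

    Answered = concept of any question screened in any round; significant
    = concept significant on the OVERALL stratum in any round.
    """
    answered: set[str] = set()
    significant: set[str] = set()
    for round_result in study.rounds:
        for (qid, label), res in round_result.screening.results.items():
            concept = study.question_index[qid].concept_key
            answered.add(concept)
            if label == OVERALL and res.significant:
                significant.add(concept)
    partition = partition_answers(registry, answered, significant)
    return compute_ratios(partition)
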