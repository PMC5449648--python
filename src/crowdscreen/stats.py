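"""Contingency tables and odds-ratio screening.

For every (candidate factor, allergy stratum) pair the screen builds a
2x2 exposure-by-disease table from the questionnaire answers and
estimates the sample odds ratio

    OR = (a d) / (b c)

with a Woolf (logit-scale) 95% confidence interval,

    exp( ln OR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ).

A factor is flagged *significant* for a stratum exactly when the lower
confidence bound exceeds 1.0.  Tables containing a zero cell receive the
Haldane-Anscombe continuity correction (+0.5 on all four cells) before
estimation, which keeps both the point estimate and the interval finite;
the correction is flagged on the result.  No multiple-testing correction
is applied: the screen deliberately keeps the per-question rule, so the
family-wise error rate grows with the pool (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    CrowdScreenError,
    DegenerateTableError,
    InvalidTableError,
    MissingQuestionError,
    UnknownAllergyError,
)
from .records import ALL_LABELS, NO, YES, ParticipantResponse, Question

__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "ScreeningResult",
    "build_table",
    "odds_ratio",
    "screen_pool",
    "screening_frame",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x disease counts.

    a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  Counts are non-negative integers (before
    any continuity correction) and at least one must be positive.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise InvalidTableError(
                    f"cell {name} must be a non-negative integer, got {value!r}"
                )
            object.__setattr__(self, name, int(value))
        if self.n_total == 0:
            raise InvalidTableError("table is empty (all four cells are zero)")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Woolf confidence interval and significance flag.

    ``significant`` is strictly equivalent to ``ci_low > 1.0``.
    ``correction_applied`` records whether the Haldane-Anscombe +0.5 was
    used; ``n_total`` is the (pre-correction) table total.
    """

    or_point: float
    ci_low: float
    ci_high: float
    significant: bool
    correction_applied: bool
    n_total: int


@lru_cache(maxsize=8)
def _z_quantile(alpha: float) -> float:
    return float(norm.ppf(1.0 - alpha / 2.0))


def build_table(
    responses: Iterable[ParticipantResponse],
    allergy_label: str,
    question_id: str,
) -> TwoByTwoTable:
    """Tally a 2x2 exposure-by-disease table for one question and stratum.

    A "yes" answer counts as exposed, "no" as unexposed; unanswered
    records (``None`` or question not asked) are excluded pairwise.
    Case status follows :meth:`ParticipantResponse.is_case`.

    Raises
    ------
    UnknownAllergyError
        If ``allergy_label`` is not one of the seven types or OVERALL.
    MissingQuestionError
        If ``question_id`` appears in no response record.
    InvalidTableError
        If every record that asked the question left it unanswered.
    """
    if allergy_label not in ALL_LABELS:
        raise UnknownAllergyError(
            f"unknown allergy label {allergy_label!r}; expected one of {ALL_LABELS}"
        )
    a = b = c = d = 0
    seen = False
    for record in responses:
        if question_id in record.answers:
            seen = True
        answer = record.answers.get(question_id)
        if answer is None:
            continue
        case = record.is_case(allergy_label)
        if answer == YES:
            if case:
                a += 1
            else:
                b += 1
        elif answer == NO:
            if case:
                c += 1
            else:
                d += 1
        else:
            raise InvalidTableError(
                f"answer for {question_id!r} must be 'yes', 'no' or None, "
                f"got {answer!r}"
            )
    if not seen:
        raise MissingQuestionError(
            f"question {question_id!r} appears in no response record"
        )
    return TwoByTwoTable(a, b, c, d)


def odds_ratio(table: TwoByTwoTable, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with a Woolf ``(1 - alpha)`` confidence interval.

    If any cell is zero, 0.5 is added to all four cells first
    (Haldane-Anscombe), which guarantees finite estimates.  Tables with
    an empty margin (no exposed, no unexposed, no cases or no controls)
    are not estimable and raise :class:`DegenerateTableError`.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    margins = {
        "exposed (a+b)": table.a + table.b,
        "unexposed (c+d)": table.c + table.d,
        "cases (a+c)": table.a + table.c,
        "controls (b+d)": table.b + table.d,
    }
    for name, total in margins.items():
        if total == 0:
            raise DegenerateTableError(
                f"empty margin: {name} = 0; odds ratio not estimable"
            )
    corrected = 0 in table.cells
    if corrected:
        a, b, c, d = (cell + 0.5 for cell in table.cells)
    else:
        a, b, c, d = table.cells
    or_point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = _z_quantile(alpha)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    return OddsRatioResult(
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=ci_low > 1.0,
        correction_applied=corrected,
        n_total=table.n_total,
    )


@dataclass
class ScreeningResult:
    """Batch screening output.

    ``results`` maps ``(question_id, allergy_label)`` to an
    :class:`OddsRatioResult`, in deterministic ``(question_id, label)``
    order; ``tables`` holds the corresponding 2x2 tables.  Pairs that
    could not be estimated are listed in ``skipped`` with a reason and
    do not abort the rest of the screen.
    """

    results: dict[tuple[str, str], OddsRatioResult] = field(default_factory=dict)
    tables: dict[tuple[str, str], TwoByTwoTable] = field(default_factory=dict)
    skipped: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    @classmethod
    def empty(cls) -> "ScreeningResult":
        return cls()

    def by_question(self) -> dict[str, list[OddsRatioResult]]:
        """Group results per question id (insertion order preserved)."""
        grouped: dict[str, list[OddsRatioResult]] = {}
        for (qid, _label), res in self.results.items():
            grouped.setdefault(qid, []).append(res)
        return grouped


def screen_pool(
    responses: Sequence[ParticipantResponse],
    questions: Sequence[Question],
    allergy_labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Screen every (question, stratum) pair over a response collection.

    Equivalent to calling :func:`build_table` + :func:`odds_ratio` per
    pair (a test enforces this), but tallies all tables at once with a
    coded answer matrix, which keeps multi-round studies fast.  Failed
    pairs (empty margins, all-unanswered questions, questions absent
    from every record) land in the skip list instead of aborting.
    """
    responses = list(responses)
    questions = list(questions)
    if not questions:
        raise InvalidTableError("screen_pool requires a non-empty question set")
    if not responses:
        raise InvalidTableError("screen_pool requires a non-empty response set")
    labels = tuple(allergy_labels) if allergy_labels is not None else ALL_LABELS
    for label in labels:
        if label not in ALL_LABELS:
            raise UnknownAllergyError(f"unknown allergy label {label!r}")
    labels = tuple(sorted(labels))
    qids = sorted({q.question_id for q in questions})

    col_of = {qid: j for j, qid in enumerate(qids)}
    code = np.full((len(responses), len(qids)), -1, dtype=np.int8)
    present = np.zeros(len(qids), dtype=bool)
    for i, record in enumerate(responses):
        for qid, answer in record.answers.items():
            j = col_of.get(qid)
            if j is None:
                continue
            present[j] = True
            if answer == YES:
                code[i, j] = 1
            elif answer == NO:
                code[i, j] = 0

    case = np.zeros((len(responses), len(labels)), dtype=bool)
    for l, label in enumerate(labels):
        for i, record in enumerate(responses):
            case[i, l] = record.is_case(label)

    yes = (code == 1).astype(np.int64)
    no = (code == 0).astype(np.int64)
    case_i = case.astype(np.int64)
    ctrl_i = (~case).astype(np.int64)
    a_mat = yes.T @ case_i
    b_mat = yes.T @ ctrl_i
    c_mat = no.T @ case_i
    d_mat = no.T @ ctrl_i

    out = ScreeningResult()
    for j, qid in enumerate(qids):
        for l, label in enumerate(labels):
            key = (qid, label)
            if not present[j]:
                out.skipped.append((key, "question absent from all responses"))
                continue
            try:
                table = TwoByTwoTable(
                    a_mat[j, l], b_mat[j, l], c_mat[j, l], d_mat[j, l]
                )
                out.results[key] = odds_ratio(table, alpha=alpha)
                out.tables[key] = table
            except CrowdScreenError as exc:
                out.skipped.append((key, str(exc)))
    return out


def screening_frame(
    screening: ScreeningResult,
    questions: Iterable[Question] | Mapping[str, Question] = (),
) -> pd.DataFrame:
    """Flatten a screening result into the serialisable CSV layout.

    Columns: question_id, concept_key, allergy_label, a, b, c, d, or,
    ci_low, ci_high, significant, correction_applied.
    """
    if isinstance(questions, Mapping):
        concept_of = {qid: q.concept_key for qid, q in questions.items()}
    else:
        concept_of = {q.question_id: q.concept_key for q in questions}
    rows = []
    for (qid, label), res in screening.results.items():
        table = screening.tables[(qid, label)]
        rows.append(
            {
                "question_id": qid,
                "concept_key": concept_of.get(qid, ""),
                "allergy_label": label,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "or": res.or_point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "significant": res.significant,
                "correction_applied": res.correction_applied,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "question_id",
            "concept_key",
            "allergy_label",
            "a",
            "b",
            "c",
            "d",
            "or",
            "ci_low",
            "ci_high",
            "significant",
            "correction_applied",
        ],
    )
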