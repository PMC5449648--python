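"""Reading and writing response files; prevalence reporting.

Responses travel as one flat CSV per questionnaire round: one row per
participant, fixed profile columns, one 0/1 column per allergy flag,
one ``q_<question_id>`` column per risk question ("yes"/"no", empty =
unanswered), and the participant's proposals as a JSON-encoded cell.
Unknown columns round-trip untouched via the record's ``extra`` dict.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ResponseFormatError
from .metrics import format_ratio
from .records import ALLERGY_TYPES, NO, YES, ParticipantResponse, Question

__all__ = ["read_responses", "write_responses", "prevalence_report"]

_FIXED_COLUMNS = ("participant_id", "round", "gender", "age_band")
_ALLERGY_COLUMNS = tuple(f"allergy_{t}" for t in ALLERGY_TYPES)
_QUESTION_PREFIX = "q_"
_PROPOSALS_COLUMN = "proposals"


def write_responses(
    responses: Sequence[ParticipantResponse], path: str | Path
) -> None:
    """Write a response collection as the flat CSV format.

    The file represents one questionnaire round: every row gets the
    union of question columns, so a collection should share a question
    set for a lossless round-trip (an absent question reads back as
    unanswered).
    """
    qids = sorted({qid for r in responses for qid in r.answers})
    extra_cols = sorted({k for r in responses for k in r.extra})
    rows = []
    for r in responses:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "round": r.round_index,
            "gender": r.gender,
            "age_band": r.age_band,
        }
        for t in ALLERGY_TYPES:
            row[f"allergy_{t}"] = int(bool(r.allergy_flags.get(t, False)))
        for qid in qids:
            answer = r.answers.get(qid)
            row[_QUESTION_PREFIX + qid] = "" if answer is None else answer
        row[_PROPOSALS_COLUMN] = json.dumps([asdict(q) for q in r.proposals])
        for col in extra_cols:
            row[col] = r.extra.get(col, "")
        rows.append(row)
    columns = (
        list(_FIXED_COLUMNS)
        + list(_ALLERGY_COLUMNS)
        + [_QUESTION_PREFIX + qid for qid in qids]
        + [_PROPOSALS_COLUMN]
        + extra_cols
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _parse_flag(value: str) -> bool:
    if value in ("1", "True", "true"):
        return True
    if value in ("0", "False", "false", ""):
        return False
    raise ValueError(f"flag must be 0/1, got {value!r}")


def read_responses(path: str | Path) -> list[ParticipantResponse]:
    """Read a response CSV back into records.

    Missing answer cells parse as unanswered; unrecognised columns are
    preserved in ``extra``.  Malformed rows are reported together with
    their line numbers (header = line 1); missing mandatory columns are
    a hard failure.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = ("participant_id", "round") + _ALLERGY_COLUMNS
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise ResponseFormatError(
            f"{path}: missing mandatory columns: {missing}"
        )
    question_cols = [c for c in frame.columns if c.startswith(_QUESTION_PREFIX)]
    known = (
        set(_FIXED_COLUMNS)
        | set(_ALLERGY_COLUMNS)
        | set(question_cols)
        | {_PROPOSALS_COLUMN}
    )
    extra_cols = [c for c in frame.columns if c not in known]

    records: list[ParticipantResponse] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        data = dict(zip(frame.columns, row))
        try:
            records.append(_parse_row(data, question_cols, extra_cols))
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ResponseFormatError(
            f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems)
        )
    return records


def _parse_row(
    data: dict[str, str],
    question_cols: Sequence[str],
    extra_cols: Sequence[str],
) -> ParticipantResponse:
    if not data["participant_id"]:
        raise ValueError("empty participant_id")
    round_index = int(data["round"])
    flags = {
        t: _parse_flag(data[f"allergy_{t}"]) for t in ALLERGY_TYPES
    }
    answers: dict[str, str | None] = {}
    for col in question_cols:
        cell = data[col]
        if cell == "":
            answers[col[len(_QUESTION_PREFIX):]] = None
        elif cell in (YES, NO):
            answers[col[len(_QUESTION_PREFIX):]] = cell
        else:
            raise ValueError(f"answer in column {col!r} must be yes/no/empty, got {cell!r}")
    proposals_cell = data.get(_PROPOSALS_COLUMN, "") or "[]"
    proposals = [Question(**q) for q in json.loads(proposals_cell)]
    return ParticipantResponse(
        participant_id=data["participant_id"],
        round_index=round_index,
        gender=data.get("gender", ""),
        age_band=data.get("age_band", ""),
        allergy_flags=flags,
        answers=answers,
        proposals=proposals,
        extra={c: data[c] for c in extra_cols},
    )


def prevalence_report(responses: Iterable[ParticipantResponse]) -> pd.DataFrame:
    """Per-allergy prevalence table (one row per type plus Total).

    Participants are deduplicated by id (first record wins); Total
    counts participants with any of the seven flags set.  Percentages
    use the one-decimal half-up convention.
    """
    seen: dict[str, ParticipantResponse] = {}
    for r in responses:
        seen.setdefault(r.participant_id, r)
    cohort = list(seen.values())
    denominator = len(cohort)
    rows = []
    n_any = sum(1 for r in cohort if any(
        r.allergy_flags.get(t, False) for t in ALLERGY_TYPES
    ))
    rows.append(("Total", n_any))
    for t in ALLERGY_TYPES:
        rows.append((t, sum(1 for r in cohort if r.allergy_flags.get(t, False))))
    return pd.DataFrame(
        {
            "allergy_type": [name for name, _ in rows],
            "n": [n for _, n in rows],
            "denominator": denominator,
            "percent": [
                format_ratio(n / denominator if denominator else None,
                             "percent_round1")
                for _, n in rows
            ],
        }
    )
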