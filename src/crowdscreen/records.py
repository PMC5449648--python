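"""Shared record types: participants and candidate risk questions.

The study screens seven self-reported allergy types plus an OVERALL
stratum in which a participant counts as a case when any of the seven
flags is set (mirroring the questionnaire's "none" box: anyone who did
not check "none" is allergy positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownAllergyError

#: The seven allergy types screened, in questionnaire order.
ALLERGY_TYPES: tuple[str, ...] = (
    "asthma",
    "pollinosis",
    "allergic_rhinitis",
    "atopic_dermatitis",
    "food_allergy",
    "drug_hypersensitivity",
    "sick_building_syndrome",
)

#: Pseudo-stratum: case = any of the seven flags set.
OVERALL = "OVERALL"

#: All analysis strata (7 types + OVERALL).
ALL_LABELS: tuple[str, ...] = ALLERGY_TYPES + (OVERALL,)

YES = "yes"
NO = "no"

SEED = "seed"
CROWD = "crowd"


@dataclass(frozen=True)
class Question:
    """A candidate risk-factor question.

    Parameters
    ----------
    question_id
        Stable identifier, unique within a pool.
    concept_key
        Canonical identifier of the underlying factor concept.  Two
        questions with the same key ask about the same factor (possibly
        with different wording / generality).
    text
        Free-text question string shown to participants.
    origin
        ``"seed"`` for the initial known-risk questions, ``"crowd"`` for
        participant proposals.
    round_introduced
        First round in which the question is part of the questionnaire.
        Seed questions have ``round_introduced == 1``.
    requires_yes_no
        False when the proposal cannot be answered yes/no (inadequate
        format, e.g. "How many cats do you have?").
    asks_personal_info
        True when the proposal would force participants to divulge
        personal information.
    generality_rank
        Lower = more general phrasing of the concept; the synonym merge
        keeps the most general variant.
    """

    question_id: str
    concept_key: str
    text: str = ""
    origin: str = CROWD
    round_introduced: int = 1
    requires_yes_no: bool = True
    asks_personal_info: bool = False
    generality_rank: int = 0

    def __post_init__(self) -> None:
        if self.origin not in (SEED, CROWD):
            raise ValueError(f"origin must be 'seed' or 'crowd', got {self.origin!r}")
        if self.round_introduced < 1:
            raise ValueError("round_introduced must be >= 1")
        if self.origin == SEED and self.round_introduced != 1:
            raise ValueError("seed questions must have round_introduced == 1")


@dataclass
class ParticipantResponse:
    """One participant-round questionnaire record.

    ``answers`` maps question ids to ``"yes"``, ``"no"`` or ``None``
    (unanswered).  ``allergy_flags`` maps each of the seven allergy types
    to a boolean; a returner keeps identical flags across rounds.
    ``proposals`` holds the 1-5 candidate questions the participant
    submitted through the novel risk-proposal prompt.
    """

    participant_id: str
    round_index: int
    gender: str = ""
    age_band: str = ""
    allergy_flags: dict[str, bool] = field(default_factory=dict)
    answers: dict[str, str | None] = field(default_factory=dict)
    proposals: list[Question] = field(default_factory=list)
    extra: dict[str, str] = field(default_factory=dict)

    def is_case(self, allergy_label: str) -> bool:
        """Case status for one analysis stratum.

        For ``OVERALL`` a participant is a case when any of the seven
        flags is set; otherwise the single flag decides.
        """
        if allergy_label == OVERALL:
            return any(self.allergy_flags.get(t, False) for t in ALLERGY_TYPES)
        if allergy_label not in ALLERGY_TYPES:
            raise UnknownAllergyError(
                f"unknown allergy label {allergy_label!r}; expected one of "
                f"{ALL_LABELS}"
            )
        return bool(self.allergy_flags.get(allergy_label, False))
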