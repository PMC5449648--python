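import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crowdscreen import (
    ALLERGY_TYPES,
    ParticipantResponse,
    Question,
    QuestionPool,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_response(pid, answers=None, flags=None, round_index=1, proposals=None):
    """Minimal response record for unit tests."""
    allergy_flags = {t: False for t in ALLERGY_TYPES}
    if flags:
        allergy_flags.update(flags)
    return ParticipantResponse(
        participant_id=pid,
        round_index=round_index,
        allergy_flags=allergy_flags,
        answers=dict(answers or {}),
        proposals=list(proposals or []),
    )


@pytest.fixture
def four_cell_responses():
    """One record per 2x2 cell for question q1 on the asthma stratum."""
    return [
        make_response("p1", {"q1": "yes"}, {"asthma": True}),
        make_response("p2", {"q1": "yes"}),
        make_response("p3", {"q1": "no"}, {"asthma": True}),
        make_response("p4", {"q1": "no"}),
    ]


@pytest.fixture
def tiny_pool():
    return QuestionPool(
        active=[
            Question("seed_01", "factor_a", origin="seed"),
            Question("seed_02", "factor_b", origin="seed"),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def cohort_with_study_counts():
    """502 participants matching the study's per-allergy counts:
    298 with any allergy; 38/183/130/59/26/13/12 per type.

    Pollinosis covers participants 0..182 and allergic rhinitis
    183..297 plus 0..14, so the union of positives is exactly 0..297
    (298 participants); every other type flags a prefix.
    """
    counts = {
        "asthma": 38,
        "pollinosis": 183,
        "allergic_rhinitis": 130,
        "atopic_dermatitis": 59,
        "food_allergy": 26,
        "drug_hypersensitivity": 13,
        "sick_building_syndrome": 12,
    }
    records = []
    for i in range(502):
        flags = {
            "pollinosis": i < 183,
            "allergic_rhinitis": 183 <= i < 298 or i < 15,
            "asthma": i < 38,
            "atopic_dermatitis": i < 59,
            "food_allergy": i < 26,
            "drug_hypersensitivity": i < 13,
            "sick_building_syndrome": i < 12,
        }
        records.append(make_response(f"p{i:03d}", flags=flags))
    totals = {t: sum(r.allergy_flags[t] for r in records) for t in counts}
    assert totals == counts
    assert sum(any(r.allergy_flags.values()) for r in records) == 298
    return records
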