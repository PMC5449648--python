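"""Synthetic crowd generator.

Emulates the questionnaire study end to end: a cohort of adults with
self-reported allergy flags at configurable prevalences, binary exposure
answers generated so that each planted factor has exactly its configured
odds ratio against the relevant stratum, 1-5 free-form proposals per
participant (with configurable shares of inadequate and synonym-variant
proposals), and cross-round repeat participation.

Exposure is generated conditionally on disease status (case-control
style): controls are exposed with probability ``p0`` and cases with

    P(exposed | case) = OR * w / (1 + OR * w),   w = p0 / (1 - p0),

which makes the planted OR exactly the estimand the screen targets.
When a factor has effects on several of a participant's allergies, the
maximum OR governs exposure.

Proposal topics are drawn from a finite concept universe with
Zipf-decaying salience weights, so common ideas surface early and rare
ones trickle in across rounds — which is what produces the declining
number of new hypotheses per round.  Allergy-positive participants
over-sample concepts with real effects (patient expertise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError, CrowdScreenError
from .metrics import KnownRiskRegistry
from .pool import QuestionPool
from .records import (
    ALLERGY_TYPES,
    CROWD,
    NO,
    OVERALL,
    SEED,
    YES,
    ParticipantResponse,
    Question,
)

__all__ = [
    "TABLE1_PREVALENCE",
    "CrowdModelConfig",
    "ConceptSpec",
    "ConceptUniverse",
    "Scenario",
    "CrowdSampler",
    "RecordedCrowd",
    "case_exposure_probability",
    "sample_cohort",
    "generate_proposals",
    "make_study_scenario",
]

#: Per-allergy cohort prevalences (counts out of 502 in the study design
#: the generator emulates: 38 asthma, 183 pollinosis, 130 allergic
#: rhinitis, 59 atopic dermatitis, 26 food allergy, 13 drug
#: hypersensitivity, 12 sick building syndrome).
TABLE1_PREVALENCE: dict[str, float] = {
    "asthma": 38 / 502,
    "pollinosis": 183 / 502,
    "allergic_rhinitis": 130 / 502,
    "atopic_dermatitis": 59 / 502,
    "food_allergy": 26 / 502,
    "drug_hypersensitivity": 13 / 502,
    "sick_building_syndrome": 12 / 502,
}

#: Proportion of men in the emulated cohort (303 of 502).
_P_MALE = 303 / 502

_AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69")


def case_exposure_probability(p0: float, true_or: float) -> float:
    """P(exposed | case) given control exposure ``p0`` and a true OR.

    Closed-form odds inversion: with control odds ``w = p0/(1-p0)``,
    case odds are ``OR * w``, so the probability is ``OR*w/(1+OR*w)``.
    Reduces to ``p0`` at ``OR = 1``.
    """
    if not 0.0 < p0 < 1.0:
        raise ConfigError(f"baseline exposure must be in (0, 1), got {p0}")
    if true_or <= 0.0:
        raise ConfigError(f"true OR must be positive, got {true_or}")
    w = p0 / (1.0 - p0)
    return true_or * w / (1.0 + true_or * w)


@dataclass(frozen=True)
class CrowdModelConfig:
    """Parameters of the synthetic crowd.

    All probabilities are validated at construction.  ``factor_effects``
    maps ``(concept_key, allergy_label)`` to a true odds ratio (1.0 =
    null); the label may be one of the seven types or ``OVERALL``
    (applies to any case).  ``baseline_exposure`` maps concepts to
    P(exposed | control); concepts without an entry use
    ``default_baseline_exposure``.
    """

    n_participants: int = 502
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(TABLE1_PREVALENCE)
    )
    comorbidity_rho: float = 0.0
    factor_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_exposure: dict[str, float] = field(default_factory=dict)
    default_baseline_exposure: float = 0.2
    proposal_rate: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    inadequate_fraction: float = 0.10
    synonym_variant_fraction: float = 0.15
    case_enrichment: float = 3.0
    nonresponse_rate: float = 0.02
    returner_fraction: float = 0.22
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        for allergy, p in self.prevalence.items():
            if allergy not in ALLERGY_TYPES:
                raise ConfigError(f"unknown allergy type in prevalence: {allergy!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence[{allergy!r}] outside [0, 1]: {p}")
        missing = set(ALLERGY_TYPES) - set(self.prevalence)
        if missing:
            raise ConfigError(f"prevalence missing allergy types: {sorted(missing)}")
        if not 0.0 <= self.comorbidity_rho < 1.0:
            raise ConfigError("comorbidity_rho must be in [0, 1)")
        for (concept, label), or_value in self.factor_effects.items():
            if label != OVERALL and label not in ALLERGY_TYPES:
                raise ConfigError(
                    f"factor_effects label {label!r} for {concept!r} unknown"
                )
            if or_value <= 0.0:
                raise ConfigError(
                    f"factor_effects[{(concept, label)!r}] must be > 0"
                )
        for concept, p0 in self.baseline_exposure.items():
            if not 0.0 < p0 < 1.0:
                raise ConfigError(
                    f"baseline_exposure[{concept!r}] must be in (0, 1), got {p0}"
                )
        if not 0.0 < self.default_baseline_exposure < 1.0:
            raise ConfigError("default_baseline_exposure must be in (0, 1)")
        if not self.proposal_rate:
            raise ConfigError("proposal_rate must be non-empty")
        if set(self.proposal_rate) - {1, 2, 3, 4, 5}:
            raise ConfigError("proposal_rate must be supported on {1..5}")
        weights = list(self.proposal_rate.values())
        if any(w < 0 for w in weights) or not math.isclose(
            sum(weights), 1.0, abs_tol=1e-9
        ):
            raise ConfigError("proposal_rate weights must be >= 0 and sum to 1")
        for name in (
            "inadequate_fraction",
            "synonym_variant_fraction",
            "nonresponse_rate",
            "returner_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]: {value}")
        if self.inadequate_fraction + self.synonym_variant_fraction > 1.0:
            raise ConfigError(
                "inadequate_fraction + synonym_variant_fraction must be <= 1"
            )
        if self.case_enrichment <= 0.0:
            raise ConfigError("case_enrichment must be positive")


# Concept categories: seeds and non-seed known risks (real effects in the
# default scenario), planted true factors, and null factors.
CATEGORIES = ("seed", "known", "factor", "null")


@dataclass(frozen=True)
class ConceptSpec:
    concept_key: str
    category: str
    weight: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown concept category {self.category!r}")
        if self.weight <= 0.0:
            raise ConfigError("concept weight must be positive")


@dataclass(frozen=True)
class ConceptUniverse:
    """The finite pool of ideas participants can propose."""

    concepts: tuple[ConceptSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "concepts", tuple(self.concepts))
        keys = [c.concept_key for c in self.concepts]
        if len(keys) != len(set(keys)):
            raise ConfigError("concept keys must be unique in the universe")

    def __len__(self) -> int:
        return len(self.concepts)

    def sampling_weights(self, is_case: bool, enrichment: float) -> np.ndarray:
        """Normalised topic weights, enriching real-effect concepts for cases."""
        w = np.array([c.weight for c in self.concepts], dtype=float)
        if is_case:
            boosted = np.array(
                [c.category in ("seed", "known", "factor") for c in self.concepts]
            )
            w = np.where(boosted, w * enrichment, w)
        return w / w.sum()


def _draw_allergy_flags(
    config: CrowdModelConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x 7 boolean flag matrix, optionally with copula co-occurrence."""
    p = np.array([config.prevalence[t] for t in ALLERGY_TYPES])
    if config.comorbidity_rho == 0.0:
        return rng.random((n, len(ALLERGY_TYPES))) < p
    # Gaussian copula with equicorrelation rho: shared + idiosyncratic latent.
    rho = config.comorbidity_rho
    shared = rng.standard_normal(n)[:, None]
    own = rng.standard_normal((n, len(ALLERGY_TYPES)))
    latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
    return latent < norm.ppf(p)


def _effective_or(
    config: CrowdModelConfig,
    concept_key: str,
    flags: np.ndarray,
    any_case: np.ndarray,
) -> np.ndarray:
    """Per-participant effective OR for one concept (max-effect rule)."""
    or_eff = np.ones(flags.shape[0])
    for (concept, label), or_value in config.factor_effects.items():
        if concept != concept_key:
            continue
        if label == OVERALL:
            mask = any_case
        else:
            mask = flags[:, ALLERGY_TYPES.index(label)]
        or_eff[mask] = np.maximum(or_eff[mask], or_value)
    return or_eff


def sample_cohort(
    config: CrowdModelConfig,
    round_index: int,
    prior_cohort: Sequence[ParticipantResponse] | None,
    pool: QuestionPool,
    rng: np.random.Generator,
    universe: ConceptUniverse | None = None,
) -> list[ParticipantResponse]:
    """Sample one round's cohort of participant responses.

    Returners are drawn from ``prior_cohort`` at ``returner_fraction``;
    they keep their id, profile, allergy flags, and their previous
    answer to any question they already answered (latent exposure is
    stable).  Fresh participants get new flags and exposures.  When
    ``universe`` is given, each participant also submits 1-5 proposals.
    """
    if not pool.active:
        raise CrowdScreenError("cannot sample a cohort for an empty question pool")
    n = config.n_participants

    returners: list[ParticipantResponse] = []
    if prior_cohort:
        keep = rng.random(len(prior_cohort)) < config.returner_fraction
        returners = [r for r, k in zip(prior_cohort, keep) if k][:n]
    n_fresh = n - len(returners)

    fresh_flags = _draw_allergy_flags(config, n_fresh, rng)
    fresh_gender = np.where(rng.random(n_fresh) < _P_MALE, "male", "female")
    fresh_age = rng.choice(_AGE_BANDS, size=n_fresh) if n_fresh else np.array([])

    cohort: list[ParticipantResponse] = []
    prior_answers: dict[str, dict[str, str | None]] = {}
    for prev in returners:
        cohort.append(
            ParticipantResponse(
                participant_id=prev.participant_id,
                round_index=round_index,
                gender=prev.gender,
                age_band=prev.age_band,
                allergy_flags=dict(prev.allergy_flags),
            )
        )
        prior_answers[prev.participant_id] = prev.answers
    for i in range(n_fresh):
        cohort.append(
            ParticipantResponse(
                participant_id=f"r{round_index}p{i:05d}",
                round_index=round_index,
                gender=str(fresh_gender[i]),
                age_band=str(fresh_age[i]),
                allergy_flags={
                    t: bool(fresh_flags[i, j]) for j, t in enumerate(ALLERGY_TYPES)
                },
            )
        )

    flags = np.array(
        [[r.allergy_flags[t] for t in ALLERGY_TYPES] for r in cohort], dtype=bool
    )
    any_case = flags.any(axis=1)

    for question in pool.active:
        p0 = config.baseline_exposure.get(
            question.concept_key, config.default_baseline_exposure
        )
        or_eff = _effective_or(config, question.concept_key, flags, any_case)
        w = p0 / (1.0 - p0)
        p_exposed = or_eff * w / (1.0 + or_eff * w)
        exposed = rng.random(n) < p_exposed
        skipped = rng.random(n) < config.nonresponse_rate
        for i, record in enumerate(cohort):
            prior = prior_answers.get(record.participant_id)
            if prior is not None and question.question_id in prior:
                record.answers[question.question_id] = prior[question.question_id]
            elif skipped[i]:
                record.answers[question.question_id] = None
            else:
                record.answers[question.question_id] = YES if exposed[i] else NO

    if universe is not None:
        for record in cohort:
            record.proposals = generate_proposals(record, universe, config, rng)
    return cohort


def generate_proposals(
    participant: ParticipantResponse,
    concept_universe: ConceptUniverse,
    config: CrowdModelConfig,
    rng: np.random.Generator,
) -> list[Question]:
    """Draw a participant's 1-5 novel risk proposals.

    Each proposal is, per the configured fractions, an inadequate
    question (wrong format or personal), a synonym variant of a concept
    (generality rank 1, i.e. less general than the canonical rank-0
    phrasing), or a canonical fresh mention of a concept.  Topic choice
    is weighted by concept salience, enriched toward real-effect
    concepts for allergy-positive participants.
    """
    if len(concept_universe) == 0:
        raise CrowdScreenError("concept universe is empty")
    counts = sorted(config.proposal_rate)
    probs = np.array([config.proposal_rate[k] for k in counts], dtype=float)
    n_proposals = int(rng.choice(counts, p=probs / probs.sum()))
    weights = concept_universe.sampling_weights(
        is_case=participant.is_case(OVERALL), enrichment=config.case_enrichment
    )
    proposals: list[Question] = []
    for j in range(n_proposals):
        concept = concept_universe.concepts[int(rng.choice(len(weights), p=weights))]
        kind = rng.random()
        requires_yes_no = True
        asks_personal = False
        rank = 0
        if kind < config.inadequate_fraction:
            if rng.random() < 0.5:
                requires_yes_no = False
            else:
                asks_personal = True
        elif kind < config.inadequate_fraction + config.synonym_variant_fraction:
            rank = 1
        proposals.append(
            Question(
                question_id=f"prop_{participant.participant_id}_{j}",
                concept_key=concept.concept_key,
                text=f"Do you have exposure related to {concept.concept_key}?",
                origin=CROWD,
                round_introduced=participant.round_index,
                requires_yes_no=requires_yes_no,
                asks_personal_info=asks_personal,
                generality_rank=rank,
            )
        )
    return proposals


class CrowdSampler:
    """Live synthetic crowd: samples each round's cohort on demand.

    The per-round RNG stream is derived from (crowd seed, round seed,
    round index), so adding rounds never perturbs earlier ones and a
    fixed seed makes the whole study bit-reproducible.
    """

    def __init__(self, config: CrowdModelConfig, universe: ConceptUniverse):
        self.config = config
        self.universe = universe

    def sample_round(self, pool, round_config, prior_responses):
        rng = np.random.default_rng(
            [abs(self.config.rng_seed), abs(round_config.rng_seed),
             round_config.round_index]
        )
        return sample_cohort(
            self.config,
            round_config.round_index,
            prior_responses,
            pool,
            rng,
            universe=self.universe,
        )


class RecordedCrowd:
    """Replay crowd: serves pre-recorded per-round response collections."""

    def __init__(self, rounds: Sequence[Sequence[ParticipantResponse]]):
        self.rounds = [list(r) for r in rounds]

    def sample_round(self, pool, round_config, prior_responses):
        index = round_config.round_index - 1
        if index >= len(self.rounds):
            raise CrowdScreenError(
                f"no recorded responses for round {round_config.round_index}"
            )
        return self.rounds[index]


# 16 known risk concepts of the default scenario (field-plausible names).
_KNOWN_RISK_CONCEPTS = (
    "family_allergy_history",
    "childhood_atopic_dermatitis",
    "pet_ownership",
    "dust_mite_exposure",
    "active_smoking",
    "passive_smoking",
    "urban_residence",
    "not_breastfed_in_infancy",
    "early_antibiotic_use",
    "mold_in_home",
    "outdoors_in_pollen_season",
    "carpet_flooring",
    "frequent_childhood_colds",
    "processed_food_diet",
    "cedar_area_residence",
    "metal_accessory_use",
)

# Heterogeneous planted ORs for the known risks (cycled in name order):
# some strongly detectable, some marginal, so seed significance is a
# genuine mixture rather than saturated.
_KNOWN_OR_CYCLE = (3.0, 2.0, 1.5, 1.2)


@dataclass(frozen=True)
class Scenario:
    """A complete simulated study setting."""

    config: CrowdModelConfig
    universe: ConceptUniverse
    registry: KnownRiskRegistry
    seed_pool: QuestionPool

    def sampler(self) -> CrowdSampler:
        return CrowdSampler(self.config, self.universe)


def make_study_scenario(
    rng_seed: int,
    n_participants: int = 502,
    n_true_factors: int = 30,
    n_null_factors: int = 120,
    true_or: float = 3.0,
    **config_overrides,
) -> Scenario:
    """Build the default study scenario.

    A registry of 16 known risk concepts with 8 randomly chosen seeds, a
    universe additionally containing ``n_true_factors`` planted factors
    (OVERALL OR ``true_or``) and ``n_null_factors`` nulls, Zipf-decaying
    salience weights over a shuffled concept order, and per-concept
    baseline exposures drawn once from Uniform(0.1, 0.4).  Two calls
    with the same seed return identical scenarios.
    """
    rng = np.random.default_rng(abs(rng_seed))
    known = list(_KNOWN_RISK_CONCEPTS)
    seeds = sorted(rng.choice(known, size=8, replace=False).tolist())
    factors = [f"factor_{i:03d}" for i in range(n_true_factors)]
    nulls = [f"null_{i:03d}" for i in range(n_null_factors)]

    concepts: list[tuple[str, str]] = []
    for key in known:
        concepts.append((key, "seed" if key in seeds else "known"))
    concepts += [(key, "factor") for key in factors]
    concepts += [(key, "null") for key in nulls]

    # Zipf salience over a shuffled order (category not tied to salience).
    order = rng.permutation(len(concepts))
    weights = np.empty(len(concepts))
    for rank, idx in enumerate(order):
        weights[idx] = 1.0 / (rank + 1) ** 1.1
    universe = ConceptUniverse(
        tuple(
            ConceptSpec(key, category, float(w))
            for (key, category), w in zip(concepts, weights)
        )
    )

    factor_effects: dict[tuple[str, str], float] = {}
    for i, key in enumerate(known):
        factor_effects[(key, OVERALL)] = _KNOWN_OR_CYCLE[i % len(_KNOWN_OR_CYCLE)]
    for key in factors:
        factor_effects[(key, OVERALL)] = true_or

    baseline = {
        key: float(p)
        for (key, _cat), p in zip(
            concepts, rng.uniform(0.1, 0.4, size=len(concepts))
        )
    }

    config = CrowdModelConfig(
        n_participants=n_participants,
        factor_effects=factor_effects,
        baseline_exposure=baseline,
        rng_seed=rng_seed,
        **config_overrides,
    )
    registry = KnownRiskRegistry(frozenset(known), frozenset(seeds))
    seed_pool = QuestionPool(
        active=[
            Question(
                question_id=f"seed_{i + 1:02d}",
                concept_key=key,
                text=f"Do you have exposure related to {key}?",
                origin=SEED,
                round_introduced=1,
            )
            for i, key in enumerate(seeds)
        ]
    )
    return Scenario(config, universe, registry, seed_pool)
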