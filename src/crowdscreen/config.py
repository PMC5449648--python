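"""Study configuration files (YAML/JSON) with schema validation.

A study config bundles the crowd-model section, the round section and
the registry/universe section under one global seed.  Validation runs
before any computation: probabilities outside [0, 1] or a round count
below 1 are rejected at load time.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .crowd import Scenario, make_study_scenario
from .engine import RoundConfig, StudyResult, make_round_configs, run_study
from .errors import ConfigError

__all__ = ["StudyConfig", "load_study_config", "run_from_config"]


class CrowdSection(BaseModel):
    n_participants: int = Field(default=502, ge=1)
    comorbidity_rho: float = Field(default=0.0, ge=0.0, lt=1.0)
    inadequate_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    synonym_variant_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    nonresponse_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    returner_fraction: float = Field(default=0.22, ge=0.0, le=1.0)
    case_enrichment: float = Field(default=3.0, gt=0.0)


class RoundsSection(BaseModel):
    n_rounds: int = Field(default=5, ge=1)
    k_retain: int = Field(default=99, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


class UniverseSection(BaseModel):
    n_true_factors: int = Field(default=30, ge=0)
    n_null_factors: int = Field(default=120, ge=0)
    true_or: float = Field(default=3.0, gt=0.0)


class StudyConfig(BaseModel):
    """Validated study configuration (the file schema)."""

    seed: int = 0
    crowd: CrowdSection = CrowdSection()
    rounds: RoundsSection = RoundsSection()
    universe: UniverseSection = UniverseSection()
    out_dir: str = "study_out"

    @field_validator("seed")
    @classmethod
    def _seed_in_range(cls, v: int) -> int:
        if abs(v) >= 2**31:
            raise ValueError("seed magnitude must be below 2^31")
        return v


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML (or JSON) study config file."""
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return StudyConfig.model_validate(payload)
    except (yaml.YAMLError, ValidationError) as exc:
        raise ConfigError(f"invalid study config {path}: {exc}") from exc


def build_scenario(config: StudyConfig, seed: int | None = None) -> Scenario:
    """Instantiate the synthetic scenario a config describes."""
    effective_seed = config.seed if seed is None else seed
    return make_study_scenario(
        rng_seed=effective_seed,
        n_participants=config.crowd.n_participants,
        n_true_factors=config.universe.n_true_factors,
        n_null_factors=config.universe.n_null_factors,
        true_or=config.universe.true_or,
        comorbidity_rho=config.crowd.comorbidity_rho,
        inadequate_fraction=config.crowd.inadequate_fraction,
        synonym_variant_fraction=config.crowd.synonym_variant_fraction,
        nonresponse_rate=config.crowd.nonresponse_rate,
        returner_fraction=config.crowd.returner_fraction,
        case_enrichment=config.crowd.case_enrichment,
    )


def run_from_config(
    config: StudyConfig, seed: int | None = None
) -> tuple[StudyResult, Scenario, list[RoundConfig]]:
    """Build the scenario and run the configured study."""
    effective_seed = config.seed if seed is None else seed
    scenario = build_scenario(config, seed=effective_seed)
    round_configs = make_round_configs(
        n_rounds=config.rounds.n_rounds,
        n_participants=config.crowd.n_participants,
        seed=effective_seed,
        k_retain=config.rounds.k_retain,
        alpha=config.rounds.alpha,
    )
    study = run_study(round_configs, scenario.sampler(), scenario.seed_pool)
    return study, scenario, round_configs
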