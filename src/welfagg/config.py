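"""Schema-validated run configuration (unknown keys rejected)."""
from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .compensation import DEFAULT_PROFILE_SETS
from .ordinal import MODEL_TERMS
from .synthetic_data import DEFAULT_PREVALENCE_SCHEME, DEFAULT_SCENARIOS


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HerdSection(_Section):
    n_farms: int = 44
    herd_size_min: int = 101
    herd_size_max: int = 452
    prevalence_scheme: list[tuple[float, float]] = Field(
        default_factory=lambda: list(DEFAULT_PREVALENCE_SCHEME)
    )


class TruthSection(_Section):
    alpha: float = -5.5
    delta: float = 1.1
    beta: dict[str, float] = Field(
        default_factory=lambda: {"mild": -6.0, "severe": -25.0}
    )
    sigma: float = 1.2


class PanelSection(_Section):
    n_respondents: int = 181
    per_respondent: int = 5
    scenarios: list[tuple[float, float]] = Field(
        default_factory=lambda: list(DEFAULT_SCENARIOS)
    )
    contamination_rate: float = 0.0
    truth: TruthSection = Field(default_factory=TruthSection)


class MeasuresSection(_Section):
    n_respondents: int = 159
    #: measure name -> (median on 0-10, respondent SD on the latent scale)
    measures: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "somatic_cell_count": (4.0, 3.0),
            "access_to_brush": (5.0, 2.5),
            "avoidance_distance": (5.0, 2.5),
            "lameness": (9.0, 0.0),
            "body_condition": (8.0, 0.0),
            "cleanliness": (7.0, 0.0),
            "integument_alterations": (8.0, 0.0),
            "mortality": (7.0, 0.0),
            "social_behaviour": (7.0, 0.0),
            "water_access": (8.0, 0.0),
        }
    )


class FitSection(_Section):
    specs: list[str] = Field(
        default_factory=lambda: [
            "linear",
            "linear+interaction",
            "linear+quadratic",
            "linear+quadratic+interaction",
        ]
    )
    gh_order: int = 31
    n_starts: int = 5

    @model_validator(mode="after")
    def _check_specs(self):
        unknown = [s for s in self.specs if s not in MODEL_TERMS]
        if unknown:
            raise ValueError(f"unknown model specs {unknown}")
        return self


class ScoringSection(_Section):
    w_mild: float = 2.0
    w_severe: float = 7.0
    anchors: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.0, 0.0), (70.0, 21.0), (80.0, 29.0),
                                 (90.0, 48.0), (100.0, 100.0)]
    )
    bands: tuple[float, float, float] = (20.0, 55.0, 80.0)
    #: Constant companion measure scores used when aggregating the lameness
    #: welfare score to criterion/principle/overall levels.
    companions: dict[str, float] = Field(
        default_factory=lambda: {
            "integument": 80.0,
            "disease": 80.0,
            "pain": 100.0,
            "feeding_measure": 80.0,
            "housing_measure": 80.0,
            "behaviour_measure": 80.0,
        }
    )


class ReportSection(_Section):
    profile_sets: dict[str, list[int]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PROFILE_SETS.items()}
    )
    ci_level: float = 0.95


class RunConfig(_Section):
    seed: int = 1
    herd: HerdSection = Field(default_factory=HerdSection)
    panel: PanelSection = Field(default_factory=PanelSection)
    measures: MeasuresSection = Field(default_factory=MeasuresSection)
    fit: FitSection = Field(default_factory=FitSection)
    scoring: ScoringSection = Field(default_factory=ScoringSection)
    report: ReportSection = Field(default_factory=ReportSection)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        from .io_utils import load_config_file

        return cls.model_validate(load_config_file(path))
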