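"""Seeded generators for herd gait data and expert rating panels.

Everything downstream (scoring, ordinal modelling, the compensation
comparison) is exercised against these generators, so they carry the full
statistical structure the analysis assumes: multinomial gait scores within
farms, cumulative-logit ratings with a per-respondent latent intercept, and
optional uniform-random contaminant respondents for the cleaning rule.

One master seed per config fans out into independent sub-streams, so adding
farms or respondents never reshuffles earlier draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ordinal import MODEL_TERMS, ModelSpec, design_matrix, ordinal_probs

__all__ = [
    "DEFAULT_SCENARIOS",
    "OrdinalTruth",
    "HerdConfig",
    "PanelConfig",
    "MeasurePanelConfig",
    "generate_herds",
    "generate_expert_ratings",
    "generate_measure_scores",
]

#: The nine (mild %, severe %) questionnaire scenarios.
DEFAULT_SCENARIOS: tuple[tuple[float, float], ...] = tuple(
    (m, s) for s in (0.0, 5.0, 15.0) for m in (10.0, 40.0, 70.0)
)

#: One representative prevalence target per profile bin, used as the default
#: herd scheme (mild in percent, severe in percent).
DEFAULT_PREVALENCE_SCHEME: tuple[tuple[float, float], ...] = (
    (10.0, 0.0),
    (25.0, 0.0),
    (55.0, 0.0),
    (80.0, 0.0),
    (25.0, 10.0),
    (55.0, 10.0),
    (75.0, 10.0),
    (25.0, 20.0),
    (55.0, 20.0),
)


@dataclass(frozen=True)
class OrdinalTruth:
    """Generative cumulative-logit parameters: threshold base and spacing,
    fixed-effect coefficients keyed by term name, and the respondent SD."""

    alpha: float = -5.5
    delta: float = 1.1
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"mild": -6.0, "severe": -25.0}
    )
    sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("threshold spacing must be positive")
        if self.sigma < 0:
            raise ValueError("respondent SD must be non-negative")
        known = set(MODEL_TERMS["linear+quadratic+interaction"])
        unknown = set(self.beta) - known
        if unknown:
            raise ValueError(f"unknown fixed-effect terms {sorted(unknown)}")

    @property
    def spec(self) -> ModelSpec:
        """Smallest named structure containing the non-zero terms."""
        terms = set(self.beta)
        for name in (
            "linear",
            "linear+interaction",
            "linear+quadratic",
            "linear+quadratic+interaction",
        ):
            if terms <= set(MODEL_TERMS[name]):
                return ModelSpec(name)
        return ModelSpec("linear+quadratic+interaction")


@dataclass(frozen=True)
class HerdConfig:
    n_farms: int = 44
    herd_size_range: tuple[int, int] = (101, 452)
    prevalence_scheme: tuple[tuple[float, float], ...] = DEFAULT_PREVALENCE_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_farms < 1:
            raise ValueError("n_farms must be positive")
        lo, hi = self.herd_size_range
        if not (0 < lo <= hi):
            raise ValueError("herd_size_range must satisfy 0 < min <= max")
        for mild, severe in self.prevalence_scheme:
            if mild < 0 or severe < 0 or mild + severe > 100.0:
                raise ValueError(
                    f"infeasible prevalence target ({mild}%, {severe}%): "
                    "need mild, severe >= 0 and mild + severe <= 100"
                )


def generate_herds(config: HerdConfig) -> pd.DataFrame:
    """Per-cow gait scores for ``n_farms`` farms.

    Herd sizes are uniform over the configured range.  Each farm gets a
    (mild, severe) target from the scheme — one-to-one when the scheme length
    equals ``n_farms``, sampled uniformly otherwise — and cow scores are drawn
    i.i.d. from the implied {0,1,2} multinomial.
    """
    ss = np.random.SeedSequence(config.seed)
    size_rng, target_rng, score_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    lo, hi = config.herd_size_range
    sizes = size_rng.integers(lo, hi + 1, size=config.n_farms)
    scheme = config.prevalence_scheme
    if len(scheme) == config.n_farms:
        targets = list(scheme)
    else:
        idx = target_rng.integers(0, len(scheme), size=config.n_farms)
        targets = [scheme[i] for i in idx]
    frames = []
    for k, (size, (mild, severe)) in enumerate(zip(sizes, targets), start=1):
        probs = [1.0 - (mild + severe) / 100.0, mild / 100.0, severe / 100.0]
        scores = score_rng.choice(3, size=size, p=probs)
        frames.append(
            pd.DataFrame(
                {
                    "farm_id": f"farm{k:03d}",
                    "cow_id": np.arange(1, size + 1),
                    "gait_score": scores,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PanelConfig:
    n_respondents: int = 181
    scenarios: tuple[tuple[float, float], ...] = DEFAULT_SCENARIOS
    per_respondent: int = 5
    truth: OrdinalTruth = field(default_factory=OrdinalTruth)
    contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if not (1 <= self.per_respondent <= len(self.scenarios)):
            raise ValueError("per_respondent must be in 1..len(scenarios)")
        if not (0.0 <= self.contamination_rate <= 1.0):
            raise ValueError("contamination_rate must lie in [0, 1]")


def generate_expert_ratings(config: PanelConfig) -> pd.DataFrame:
    """One panel of 0-10 acceptability ratings.

    Each respondent is allocated ``per_respondent`` distinct scenarios
    uniformly at random (without replacement).  Non-contaminant ratings come
    from the cumulative-logit truth with a respondent-specific N(0, sigma^2)
    latent intercept; contaminants rate i.i.d. uniform over {0,...,10}.

    Returns columns respondent_id, mild_pct, severe_pct, rating, contaminant.
    """
    ss = np.random.SeedSequence(config.seed)
    alloc_rng, contam_rng, intercept_rng, rating_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    truth = config.truth
    spec = ModelSpec("linear+quadratic+interaction")
    beta = np.array([truth.beta.get(t, 0.0) for t in spec.term_names])
    n_scen = len(config.scenarios)
    is_contam = contam_rng.random(config.n_respondents) < config.contamination_rate
    intercepts = intercept_rng.normal(0.0, truth.sigma, size=config.n_respondents)

    rows = []
    for r in range(config.n_respondents):
        rid = f"resp{r + 1:04d}"
        chosen = alloc_rng.choice(n_scen, size=config.per_respondent, replace=False)
        for si in sorted(chosen):
            mild_pct, severe_pct = config.scenarios[si]
            if is_contam[r]:
                rating = int(rating_rng.integers(0, 11))
            else:
                x = design_matrix(
                    np.array([mild_pct / 100.0]),
                    np.array([severe_pct / 100.0]),
                    spec,
                )
                eta = float((x @ beta)[0]) + intercepts[r]
                probs = ordinal_probs(truth.alpha, truth.delta, eta)[0]
                rating = int(rating_rng.choice(11, p=probs))
            rows.append(
                {
                    "respondent_id": rid,
                    "mild_pct": mild_pct,
                    "severe_pct": severe_pct,
                    "rating": rating,
                    "contaminant": bool(is_contam[r]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MeasurePanelConfig:
    """Per-measure generative settings: ``measures`` maps each measure name to
    (median on the 0-10 scale, respondent SD on the latent logit scale)."""

    measures: Mapping[str, tuple[float, float]]
    n_respondents: int = 159
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if not self.measures:
            raise ValueError("need at least one measure")
        for name, (median, sd) in self.measures.items():
            if not (0.0 <= median <= 10.0):
                raise ValueError(f"measure {name!r}: median must lie in [0, 10]")
            if sd < 0:
                raise ValueError(f"measure {name!r}: SD must be non-negative")


def generate_measure_scores(config: MeasurePanelConfig) -> pd.DataFrame:
    """One 0-10 validity rating per respondent per measure.

    For each measure the levels follow a cumulative-logit model with unit
    threshold spacing centred so the average-respondent median matches the
    configured median, shifted by a respondent intercept with the configured
    SD.  Returns columns respondent_id, measure, rating.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(len(config.measures))
    rows = []
    for (name, (median, sd)), stream in zip(config.measures.items(), streams):
        rng = np.random.default_rng(stream)
        intercepts = rng.normal(0.0, sd, size=config.n_respondents)
        alpha = 0.5 - median  # theta_{k+1} = k + 0.5 - median
        for r in range(config.n_respondents):
            probs = ordinal_probs(alpha, 1.0, intercepts[r])[0]
            rows.append(
                {
                    "respondent_id": f"resp{r + 1:04d}",
                    "measure": name,
                    "rating": int(rng.choice(11, p=probs)),
                }
            )
    return pd.DataFrame(rows)
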