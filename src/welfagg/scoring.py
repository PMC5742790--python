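"""Herd-level lameness scoring.

Turns per-cow gait scores into herd prevalences, a weighted 0-100 index,
a non-linear welfare score, a four-level category, and a nine-profile
assignment, plus a configurable skeleton for aggregating measure scores
up to criterion, principle and overall levels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CATEGORY_LABELS",
    "HerdObservation",
    "LamenessPrevalence",
    "MeasureWeights",
    "ScoreAnchors",
    "CategoryBands",
    "AggregationConfig",
    "AggregateResult",
    "compute_prevalence",
    "lameness_index",
    "index_to_welfare_score",
    "categorize",
    "aggregate",
    "assign_profile",
    "default_aggregation",
    "wq_overall_rule",
]

#: Four-level classification, worst to best.
CATEGORY_LABELS = ("Not classified", "Acceptable", "Enhanced", "Excellent")


@dataclass(frozen=True)
class HerdObservation:
    """Per-cow gait scores for one farm (0 non-lame, 1 mildly lame, 2 severely lame)."""

    farm_id: str
    gait_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.gait_scores) == 0:
            raise ValueError(f"herd {self.farm_id!r}: gait score sequence is empty")
        if any(g not in (0, 1, 2) for g in self.gait_scores):
            raise ValueError(
                f"herd {self.farm_id!r}: gait scores must all be in {{0,1,2}}"
            )

    @property
    def size(self) -> int:
        return len(self.gait_scores)


@dataclass(frozen=True)
class LamenessPrevalence:
    """Percent mildly and severely lame cows in a herd, on the 0-100 scale."""

    mild_pct: float
    severe_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mild_pct <= 100.0 and 0.0 <= self.severe_pct <= 100.0):
            raise ValueError("prevalences must lie in [0, 100]")
        if self.mild_pct + self.severe_pct > 100.0 + 1e-9:
            raise ValueError(
                f"mild + severe prevalence exceeds 100%: "
                f"{self.mild_pct} + {self.severe_pct}"
            )


@dataclass(frozen=True)
class MeasureWeights:
    """Relative welfare impact of mild vs severe lameness."""

    w_mild: float = 2.0
    w_severe: float = 7.0

    def __post_init__(self) -> None:
        if not (self.w_severe >= self.w_mild > 0):
            raise ValueError("weights must satisfy w_severe >= w_mild > 0")


#: Index -> welfare-score anchor points of the non-linear transform.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (70.0, 21.0),
    (80.0, 29.0),
    (90.0, 48.0),
    (100.0, 100.0),
)


@dataclass(frozen=True)
class ScoreAnchors:
    """Anchor points the index-to-score transform must pass through exactly."""

    points: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        if len(pts) < 2:
            raise ValueError("need at least two anchor points")
        if any(b <= a for a, b in zip(xs, xs[1:])) or any(
            b <= a for a, b in zip(ys, ys[1:])
        ):
            raise ValueError("anchors must be strictly increasing in both coordinates")
        if pts[0] != (0.0, 0.0) or pts[-1] != (100.0, 100.0):
            raise ValueError("anchors must include endpoints (0,0) and (100,100)")


@dataclass(frozen=True)
class CategoryBands:
    """Thresholds splitting [0,100] into the four categories, half-open on the left."""

    thresholds: tuple[float, float, float] = (20.0, 55.0, 80.0)

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if len(t) != 3 or not (0.0 < t[0] < t[1] < t[2] < 100.0):
            raise ValueError("need three strictly increasing thresholds inside (0,100)")


def compute_prevalence(herd: HerdObservation) -> LamenessPrevalence:
    """Herd prevalences (percent mild, percent severe) by direct counting."""
    scores = np.asarray(herd.gait_scores)
    n = scores.size
    return LamenessPrevalence(
        mild_pct=100.0 * np.count_nonzero(scores == 1) / n,
        severe_pct=100.0 * np.count_nonzero(scores == 2) / n,
    )


def lameness_index(
    prev: LamenessPrevalence, weights: MeasureWeights = MeasureWeights()
) -> float:
    """Weighted 0-100 lameness index; the weighted sum is normalized by the
    maximum weight so an all-severe herd scores 0 and a lameness-free herd 100."""
    penalty = (weights.w_mild * prev.mild_pct + weights.w_severe * prev.severe_pct) / (
        weights.w_severe
    )
    return 100.0 - penalty


@lru_cache(maxsize=16)
def _transform(points: tuple[tuple[float, float], ...]) -> PchipInterpolator:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return PchipInterpolator(xs, ys)


def index_to_welfare_score(
    index: float, anchors: ScoreAnchors = ScoreAnchors()
) -> float:
    """Monotone shape-preserving piecewise-cubic transform through the anchors."""
    if not (0.0 <= index <= 100.0):
        raise ValueError(f"index {index} outside [0, 100]")
    return float(_transform(anchors.points)(index))


def categorize(score: float, bands: CategoryBands = CategoryBands()) -> str:
    """Map a 0-100 score to one of the four categories by half-open banding."""
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    lo, mid, hi = bands.thresholds
    if score < lo:
        return "Not classified"
    if score < mid:
        return "Acceptable"
    if score < hi:
        return "Enhanced"
    return "Excellent"


# ---------------------------------------------------------------------------
# Nine-profile assignment over the (mild, severe) prevalence grid
# ---------------------------------------------------------------------------

# (mild bin, severe bin) -> profile id.  Mild bins: [5,15) [15,40) [40,70)
# [70,100]; severe bins: [0,5) [5,15) [15,100].  Combinations absent from the
# grid (mild < 5, low mild with non-zero severe, very high mild with high
# severe) are unprofiled.
_PROFILE_GRID: dict[tuple[int, int], int] = {
    (0, 0): 1,
    (1, 0): 2,
    (2, 0): 3,
    (3, 0): 4,
    (1, 1): 5,
    (2, 1): 6,
    (3, 1): 7,
    (1, 2): 8,
    (2, 2): 9,
}


def _mild_bin(mild_pct: float) -> int | None:
    if mild_pct < 5.0:
        return None
    if mild_pct < 15.0:
        return 0
    if mild_pct < 40.0:
        return 1
    if mild_pct < 70.0:
        return 2
    return 3


def _severe_bin(severe_pct: float) -> int:
    if severe_pct < 5.0:
        return 0
    if severe_pct < 15.0:
        return 1
    return 2


def assign_profile(prev: LamenessPrevalence) -> int | None:
    """Profile id 1-9 from the prevalence bins, or ``None`` when unprofiled."""
    mb = _mild_bin(prev.mild_pct)
    if mb is None:
        return None
    return _PROFILE_GRID.get((mb, _severe_bin(prev.severe_pct)))


# ---------------------------------------------------------------------------
# Aggregation skeleton: measures -> criteria -> principles -> overall
# ---------------------------------------------------------------------------


def wq_overall_rule(
    principle_scores: Mapping[str, float], bands: CategoryBands = CategoryBands()
) -> str:
    """Threshold predicate mapping the four principle scores to one category."""
    s = np.array(list(principle_scores.values()), dtype=float)
    if np.all(s > 55) and np.count_nonzero(s > 80) >= 2:
        return "Excellent"
    if np.all(s > 20) and np.count_nonzero(s > 55) >= 2:
        return "Enhanced"
    if np.all(s > 10) and np.count_nonzero(s > 20) >= 3:
        return "Acceptable"
    return "Not classified"


@dataclass(frozen=True)
class AggregationConfig:
    """Weights for combining measure scores into criteria and criteria into
    principles, plus the rule classifying the principle-score vector.

    Every combiner is a weighted mean, so [0,100] inputs stay in [0,100].
    """

    criteria: Mapping[str, Mapping[str, float]]
    principles: Mapping[str, Mapping[str, float]]
    bands: CategoryBands = CategoryBands()
    overall_rule: Callable[[Mapping[str, float]], str] = wq_overall_rule


def default_aggregation() -> AggregationConfig:
    """Minimal four-principle structure with lameness feeding the
    injury-absence criterion of the health principle."""
    return AggregationConfig(
        criteria={
            "absence_of_injuries": {"lameness": 0.5, "integument": 0.5},
            "absence_of_disease": {"disease": 1.0},
            "absence_of_pain": {"pain": 1.0},
            "feeding": {"feeding_measure": 1.0},
            "housing": {"housing_measure": 1.0},
            "behaviour": {"behaviour_measure": 1.0},
        },
        principles={
            "good_health": {
                "absence_of_injuries": 1 / 3,
                "absence_of_disease": 1 / 3,
                "absence_of_pain": 1 / 3,
            },
            "good_feeding": {"feeding": 1.0},
            "good_housing": {"housing": 1.0},
            "appropriate_behaviour": {"behaviour": 1.0},
        },
    )


@dataclass(frozen=True)
class AggregateResult:
    criterion_scores: dict[str, float]
    principle_scores: dict[str, float]
    criterion_categories: dict[str, str]
    principle_categories: dict[str, str]
    overall: str


def _weighted_mean(scores: Mapping[str, float], weights: Mapping[str, float],
                   level: str, target: str) -> float:
    total, wsum = 0.0, 0.0
    for name, w in weights.items():
        if name not in scores:
            raise KeyError(f"{level} '{target}' requires missing input '{name}'")
        v = float(scores[name])
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"input '{name}' = {v} outside [0, 100]")
        total += w * v
        wsum += w
    return float(np.clip(total / wsum, 0.0, 100.0))


def aggregate(
    measure_scores: Mapping[str, float],
    config: AggregationConfig | None = None,
) -> AggregateResult:
    """Roll measure scores up to criterion, principle and overall levels."""
    config = config or default_aggregation()
    crit = {
        c: _weighted_mean(measure_scores, w, "criterion", c)
        for c, w in config.criteria.items()
    }
    prin = {
        p: _weighted_mean(crit, w, "principle", p)
        for p, w in config.principles.items()
    }
    return AggregateResult(
        criterion_scores=crit,
        principle_scores=prin,
        criterion_categories={c: categorize(v, config.bands) for c, v in crit.items()},
        principle_categories={p: categorize(v, config.bands) for p, v in prin.items()},
        overall=config.overall_rule(prin),
    )
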