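"""Compensation comparison: profile cross-tabulation of aggregation-level
categories versus predicted expert acceptability, with proportion CIs.

All internal arithmetic is full precision; percentages are rounded to one
decimal only when rendered into output tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ordinal import CategoryBins, OrdinalFit, bin_probs, predict_probs
from .scoring import CATEGORY_LABELS

__all__ = [
    "PROFILE_SCENARIO",
    "CrossTab",
    "CompensationReport",
    "build_crosstab",
    "predict_profile_acceptability",
    "compensation_report",
    "wilson_ci",
    "profile_set_share",
    "totals_from_row_percentages",
]

#: Representative questionnaire scenario (mild %, severe %) per profile.
#: Mild bins map to the nearest scenario prevalence at or above the bin
#: ([5,15) -> 10, [15,40) -> 40, [40,70) -> 70, >70 -> 70); severe bins map to
#: their lower anchor (0, 5, 15).
PROFILE_SCENARIO: dict[int, tuple[float, float]] = {
    1: (10.0, 0.0),
    2: (40.0, 0.0),
    3: (70.0, 0.0),
    4: (70.0, 0.0),
    5: (40.0, 5.0),
    6: (70.0, 5.0),
    7: (70.0, 5.0),
    8: (40.0, 15.0),
    9: (70.0, 15.0),
}

_LEVELS = ("criterion", "principle", "overall")
# worst-to-best in scoring.CATEGORY_LABELS; tables render best-to-worst
_RENDER_CATS = tuple(reversed(CATEGORY_LABELS))


@dataclass(frozen=True)
class CrossTab:
    """Farm counts and category shares per lameness profile at the three
    aggregation levels, plus a totals row derived from counts."""

    counts: dict[int, int]
    n_unprofiled: int
    category_counts: dict[str, pd.DataFrame]  # level -> (profile x category)

    @property
    def n_farms(self) -> int:
        return sum(self.counts.values()) + self.n_unprofiled

    def row_percentages(self, level: str) -> pd.DataFrame:
        cc = self.category_counts[level]
        return 100.0 * cc.div(cc.sum(axis=1), axis=0)

    def totals_percent(self, level: str) -> pd.Series:
        cc = self.category_counts[level]
        return 100.0 * cc.sum(axis=0) / cc.to_numpy().sum()

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Render: one row per profile plus Unprofiled and Total rows."""
        total_profiled = sum(self.counts.values())
        rows = []
        for profile in sorted(self.counts):
            row = {
                "profile": str(profile),
                "n": self.counts[profile],
                "pct_of_farms": round(100.0 * self.counts[profile] / self.n_farms,
                                      decimals),
            }
            for level in _LEVELS:
                pcts = self.row_percentages(level).loc[profile]
                for cat in _RENDER_CATS:
                    row[f"{level}:{cat}"] = round(float(pcts[cat]), decimals)
            rows.append(row)
        if self.n_unprofiled:
            rows.append(
                {
                    "profile": "Unprofiled",
                    "n": self.n_unprofiled,
                    "pct_of_farms": round(
                        100.0 * self.n_unprofiled / self.n_farms, decimals
                    ),
                }
            )
        total_row = {"profile": "Total", "n": self.n_farms, "pct_of_farms": 100.0}
        for level in _LEVELS:
            tp = self.totals_percent(level)
            for cat in _RENDER_CATS:
                total_row[f"{level}:{cat}"] = round(float(tp[cat]), decimals)
        rows.append(total_row)
        return pd.DataFrame(rows)


def build_crosstab(scored: pd.DataFrame) -> CrossTab:
    """Cross-tabulate scored farms.

    Expects one row per farm with columns ``profile`` (int or NA) and
    ``category_criterion``, ``category_principle``, ``category_overall``.
    Unprofiled farms are counted separately, never dropped.
    """
    required = ["profile"] + [f"category_{lvl}" for lvl in _LEVELS]
    missing = [c for c in required if c not in scored.columns]
    if missing:
        raise ValueError(f"scored farms missing columns {missing}")
    profiled = scored[scored["profile"].notna()].copy()
    profiled["profile"] = profiled["profile"].astype(int)
    counts = profiled.groupby("profile").size().to_dict()
    cat_counts = {}
    for level in _LEVELS:
        col = f"category_{level}"
        bad = set(scored[col].dropna()) - set(CATEGORY_LABELS)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)} in {col}")
        tab = (
            profiled.groupby(["profile", col])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(CATEGORY_LABELS), fill_value=0)
        )
        cat_counts[level] = tab
    return CrossTab(
        counts=counts,
        n_unprofiled=int(scored["profile"].isna().sum()),
        category_counts=cat_counts,
    )


def totals_from_row_percentages(
    counts: Mapping[int, int],
    row_pct: Mapping[int, Mapping[str, float]],
) -> dict[str, float]:
    """Reconstruct a totals row from per-profile row percentages and counts.

    Each row percentage is converted back to a farm count (rounded to the
    nearest whole farm), counts are summed per category and expressed as a
    percent of all farms, one decimal.
    """
    if set(counts) != set(row_pct):
        raise ValueError("counts and row percentages cover different profiles")
    n_total = sum(counts.values())
    cat_totals: dict[str, float] = {}
    for profile, n in counts.items():
        for cat, pct in row_pct[profile].items():
            cat_totals[cat] = cat_totals.get(cat, 0.0) + round(pct * n / 100.0)
    return {cat: round(100.0 * c / n_total, 1) for cat, c in cat_totals.items()}


def profile_set_share(counts: Mapping[int, int], profiles: Iterable[int]) -> float:
    """Percent of all farms in the given profiles, one decimal."""
    profiles = list(profiles)
    unknown = [p for p in profiles if p not in counts]
    if unknown:
        raise ValueError(f"unknown profile ids {unknown}")
    n_total = sum(counts.values())
    return round(100.0 * sum(counts[p] for p in profiles) / n_total, 1)


def predict_profile_acceptability(
    fit_res: OrdinalFit,
    scenarios: Sequence[tuple[float, float]] | None = None,
    bins: CategoryBins = CategoryBins(),
    decimals: int = 1,
) -> pd.DataFrame:
    """Average-respondent acceptability-bin probabilities (percent) per
    (mild %, severe %) scenario."""
    if scenarios is None:
        scenarios = sorted(set(PROFILE_SCENARIO.values()))
    rows = []
    for mild_pct, severe_pct in scenarios:
        probs = predict_probs(fit_res, mild_pct / 100.0, severe_pct / 100.0)
        binned = 100.0 * bin_probs(probs, bins)
        row = {"mild_pct": mild_pct, "severe_pct": severe_pct}
        row.update(
            {label: round(float(v), decimals) for label, v in zip(bins.labels, binned)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as proportions."""
    if n <= 0 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts ({successes}, {n})")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass(frozen=True)
class CompensationReport:
    """Profile-set farm shares with CIs versus predicted expert verdicts."""

    n_farms: int
    ci_method: str
    ci_level: float
    profile_sets: dict[str, dict]
    overall_not_classified_pct: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "n_farms": self.n_farms,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "profile_sets": self.profile_sets,
            "overall_not_classified_pct": self.overall_not_classified_pct,
            "verdict": self.verdict,
        }


DEFAULT_PROFILE_SETS: dict[str, tuple[int, ...]] = {
    "low_lameness": (1, 2, 5),
    "high_lameness": (6, 7, 8, 9),
}


def compensation_report(
    crosstab: CrossTab,
    acceptability: pd.DataFrame,
    profile_sets: Mapping[str, Sequence[int]] | None = None,
    ci_level: float = 0.95,
    bins: CategoryBins = CategoryBins(),
) -> CompensationReport:
    """Summarize whether aggregation masks prevalences experts reject.

    For each configured profile set: the share of farms (with a Wilson CI)
    and the range of predicted clearly-unacceptable probabilities over the
    set's representative scenarios.  The verdict compares the worst-category
    expert probability for the high-lameness set against the share of farms
    the overall assessment leaves in its worst category.
    """
    profile_sets = dict(profile_sets or DEFAULT_PROFILE_SETS)
    known = set(PROFILE_SCENARIO)
    acc = acceptability.set_index(["mild_pct", "severe_pct"])
    worst_label = bins.labels[0]
    n_total = crosstab.n_farms
    sets_out: dict[str, dict] = {}
    for name, profiles in profile_sets.items():
        unknown = [p for p in profiles if p not in known]
        if unknown:
            raise ValueError(f"profile set {name!r} has unknown profiles {unknown}")
        n_in = sum(crosstab.counts.get(p, 0) for p in profiles)
        lo, hi = wilson_ci(n_in, n_total, ci_level)
        probs = []
        for p in profiles:
            scen = PROFILE_SCENARIO[p]
            if scen in acc.index:
                probs.append(float(acc.loc[scen, worst_label]))
        sets_out[name] = {
            "profiles": list(profiles),
            "n_farms": n_in,
            "share_pct": round(100.0 * n_in / n_total, 1),
            "ci_pct": (round(100.0 * lo, 1), round(100.0 * hi, 1)),
            "clearly_unacceptable_min_pct": round(min(probs), 1) if probs else None,
            "clearly_unacceptable_max_pct": round(max(probs), 1) if probs else None,
        }
    nc_pct = float(crosstab.totals_percent("overall")["Not classified"])
    high = sets_out.get("high_lameness")
    if high and high["clearly_unacceptable_min_pct"] is not None:
        masked = high["clearly_unacceptable_min_pct"] > nc_pct
        verdict = (
            "Compensation detected: predicted clearly-unacceptable probability "
            f"for profiles {high['profiles']} is at least "
            f"{high['clearly_unacceptable_min_pct']}%, yet only "
            f"{round(nc_pct, 1)}% of farms fall in the worst overall category."
            if masked
            else "No compensation detected: the overall assessment flags at "
            f"least as many farms ({round(nc_pct, 1)}%) as experts would "
            "reject."
        )
    else:
        verdict = "No high-lameness profile set configured; no verdict."
    return CompensationReport(
        n_farms=n_total,
        ci_method="wilson",
        ci_level=ci_level,
        profile_sets=sets_out,
        overall_not_classified_pct=round(nc_pct, 1),
        verdict=verdict,
    )
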