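"""Published summary of the 44-farm Danish dairy case study.

Only herd-level summaries were published for this study — per-profile farm
counts and the row-percent category distributions at the three aggregation
levels — so they are stored here verbatim as the input for the
arithmetic-consistency checks (profile-set shares, count-weighted totals,
mean herd size).  The raw per-cow and questionnaire data were never released.

Row-percent tuples are ordered (Excellent, Enhanced, Acceptable,
Not classified).  Note that the criterion-level row for profile 7 sums to 50,
not 100, as published; ``validate_rows`` surfaces this rather than silently
correcting it.
"""
from __future__ import annotations

from .compensation import profile_set_share, totals_from_row_percentages

__all__ = [
    "N_FARMS",
    "TOTAL_COWS",
    "PROFILE_COUNTS",
    "ROW_PCT",
    "PRINTED_TOTALS",
    "mean_herd_size",
    "share_of_profiles",
    "reconstructed_totals",
    "validate_rows",
]

N_FARMS = 44
TOTAL_COWS = 8106

#: Farms per lameness profile.
PROFILE_COUNTS: dict[int, int] = {
    1: 2, 2: 6, 3: 14, 4: 4, 5: 2, 6: 7, 7: 2, 8: 4, 9: 3,
}

#: Published per-profile row percentages at each aggregation level.
ROW_PCT: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "criterion": {
        1: (0.0, 100.0, 0.0, 0.0),
        2: (0.0, 50.0, 50.0, 0.0),
        3: (0.0, 7.1, 92.9, 0.0),
        4: (0.0, 0.0, 50.0, 50.0),
        5: (0.0, 0.0, 100.0, 0.0),
        6: (0.0, 14.3, 85.7, 0.0),
        7: (0.0, 0.0, 50.0, 0.0),
        8: (0.0, 0.0, 75.0, 25.0),
        9: (0.0, 0.0, 66.7, 33.3),
    },
    "principle": {
        1: (0.0, 100.0, 0.0, 0.0),
        2: (0.0, 50.0, 50.0, 0.0),
        3: (0.0, 0.0, 100.0, 0.0),
        4: (0.0, 0.0, 100.0, 0.0),
        5: (0.0, 0.0, 100.0, 0.0),
        6: (0.0, 14.3, 85.7, 0.0),
        7: (0.0, 0.0, 100.0, 0.0),
        8: (0.0, 0.0, 100.0, 0.0),
        9: (0.0, 0.0, 100.0, 0.0),
    },
    "overall": {
        1: (0.0, 50.0, 50.0, 0.0),
        2: (0.0, 66.7, 33.3, 0.0),
        3: (0.0, 42.9, 57.1, 0.0),
        4: (0.0, 25.0, 75.0, 0.0),
        5: (0.0, 50.0, 50.0, 0.0),
        6: (0.0, 71.4, 28.6, 0.0),
        7: (0.0, 50.0, 0.0, 50.0),
        8: (0.0, 75.0, 25.0, 0.0),
        9: (0.0, 0.0, 100.0, 0.0),
    },
}

#: Published totals rows (Excellent, Enhanced, Acceptable, Not classified).
PRINTED_TOTALS: dict[str, tuple[float, float, float, float]] = {
    "criterion": (0.0, 15.9, 72.7, 11.4),
    "principle": (0.0, 13.6, 86.4, 0.0),
    "overall": (0.0, 50.0, 47.7, 2.3),
}

_CATEGORIES = ("Excellent", "Enhanced", "Acceptable", "Not classified")


def mean_herd_size() -> int:
    """Mean cows per farm, rounded to the nearest integer."""
    return round(TOTAL_COWS / N_FARMS)


def share_of_profiles(profiles) -> float:
    """Percent of farms in the given profile set, one decimal."""
    return profile_set_share(PROFILE_COUNTS, profiles)


def reconstructed_totals(level: str) -> dict[str, float]:
    """Count-weighted totals row recomputed from the per-profile rows."""
    rows = {
        p: dict(zip(_CATEGORIES, pct)) for p, pct in ROW_PCT[level].items()
    }
    return totals_from_row_percentages(PROFILE_COUNTS, rows)


def validate_rows(tol: float = 0.2) -> list[str]:
    """Report published rows whose percentages do not sum to 100."""
    warnings = []
    for level, rows in ROW_PCT.items():
        for profile, pct in rows.items():
            total = sum(pct)
            if abs(total - 100.0) > tol:
                warnings.append(
                    f"{level}-level row for profile {profile} sums to "
                    f"{total:g}, not 100 (kept as published)"
                )
    return warnings
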