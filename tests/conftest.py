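"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the package's likelihood
code paths: probabilities are computed with inline logistic arithmetic and
the marginal likelihood by dense trapezoid integration.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from welfagg.synthetic_data import OrdinalTruth, PanelConfig, generate_expert_ratings


def cumlogit_level_probs(alpha: float, delta: float, eta: float) -> np.ndarray:
    """Closed-form 11-level probabilities, written independently."""
    probs = []
    prev = 0.0
    for j in range(10):
        cur = 1.0 / (1.0 + np.exp(-(alpha + delta * j - eta)))
        probs.append(cur - prev)
        prev = cur
    probs.append(1.0 - prev)
    return np.asarray(probs)


def fixed_effects_loglik(records: pd.DataFrame, alpha, delta, beta: dict) -> float:
    """Record-wise cumulative-logit log-likelihood with no random effect."""
    total = 0.0
    for _, row in records.iterrows():
        m = row["mild_pct"] / 100.0 if "mild_pct" in row else row["mild"]
        s = row["severe_pct"] / 100.0 if "severe_pct" in row else row["severe"]
        eta = (
            beta.get("mild", 0.0) * m
            + beta.get("severe", 0.0) * s
            + beta.get("mild^2", 0.0) * m**2
            + beta.get("severe^2", 0.0) * s**2
            + beta.get("mild:severe", 0.0) * m * s
        )
        y = int(row["rating"])
        upper = expit(alpha + delta * y - eta) if y < 10 else 1.0
        lower = expit(alpha + delta * (y - 1) - eta) if y > 0 else 0.0
        total += np.log(upper - lower)
    return total


def brute_force_loglik(
    records: pd.DataFrame,
    alpha: float,
    delta: float,
    beta: dict,
    sigma: float,
    n_points: int = 20001,
    limit: float | None = None,
) -> float:
    """Marginal log-likelihood by trapezoid integration over the latent
    intercept — the independent check on the quadrature.

    The range covers at least 8 latent SDs so truncation error stays well
    below the 1e-6 comparison tolerance; the grid is widened proportionally.
    """
    if limit is None:
        limit = max(12.0, 8.0 * sigma)
        n_points = int(n_points * limit / 12.0) | 1
    u = np.linspace(-limit, limit, n_points)
    dens = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    total = 0.0
    for _, grp in records.groupby("respondent_id"):
        prod = np.ones_like(u)
        for _, row in grp.iterrows():
            m = row["mild_pct"] / 100.0 if "mild_pct" in row else row["mild"]
            s = row["severe_pct"] / 100.0 if "severe_pct" in row else row["severe"]
            eta = (
                beta.get("mild", 0.0) * m
                + beta.get("severe", 0.0) * s
                + beta.get("mild^2", 0.0) * m**2
                + beta.get("severe^2", 0.0) * s**2
                + beta.get("mild:severe", 0.0) * m * s
            ) + u
            y = int(row["rating"])
            upper = expit(alpha + delta * y - eta) if y < 10 else np.ones_like(u)
            lower = expit(alpha + delta * (y - 1) - eta) if y > 0 else np.zeros_like(u)
            prod = prod * (upper - lower)
        total += np.log(np.trapezoid(prod * dens, u))
    return total


#: Well-separated generative truth used across recovery/selection tests.
RECOVERY_BETA = {
    "mild": -8.0,
    "severe": -30.0,
    "mild^2": 5.0,
    "severe^2": 60.0,
    "mild:severe": -25.0,
}
RECOVERY_TRUTH = OrdinalTruth(alpha=-5.5, delta=1.1, beta=RECOVERY_BETA, sigma=1.2)


@pytest.fixture(scope="session")
def small_panel() -> pd.DataFrame:
    """3 respondents x 5 scenarios with heterogeneity, for oracle checks."""
    cfg = PanelConfig(
        n_respondents=3, per_respondent=5, seed=7, truth=OrdinalTruth(sigma=1.5)
    )
    return generate_expert_ratings(cfg)


@pytest.fixture(scope="session")
def standard_panel() -> pd.DataFrame:
    """181 respondents x 5 scenarios from the recovery truth."""
    return generate_expert_ratings(PanelConfig(seed=20, truth=RECOVERY_TRUTH))
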