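"""Cumulative-link (mixed) ordinal models for 0-10 acceptability ratings.

The response has 11 ordered levels and 10 thresholds constrained to an
arithmetic progression theta_j = alpha + (j-1)*delta.  The linear predictor is
x'beta plus a normally distributed per-respondent intercept whose marginal is
integrated out by Gauss-Hermite quadrature:

    P(Y <= j | u) = logistic(theta_{j+1} - x'beta - u),   u ~ N(0, sigma^2).

Fitting is maximum likelihood on the unconstrained scale
(alpha, log delta, beta, log sigma) with deterministic multistarts.
Covariates are prevalence proportions in [0, 1].
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermite

__all__ = [
    "MODEL_TERMS",
    "N_LEVELS",
    "ModelSpec",
    "OrdinalFit",
    "CategoryBins",
    "design_matrix",
    "ordinal_probs",
    "clmm_loglik",
    "fit",
    "select_by_aic",
    "predict_probs",
    "bin_probs",
    "prob_acceptable",
    "clean_panel",
    "fit_agreement",
]

N_LEVELS = 11  # ratings 0..10
_N_THRESH = N_LEVELS - 1

#: Fixed-effect structures considered for the acceptability analysis.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "none": (),
    "linear": ("mild", "severe"),
    "linear+interaction": ("mild", "severe", "mild:severe"),
    "linear+quadratic": ("mild", "severe", "mild^2", "severe^2"),
    "linear+quadratic+interaction": (
        "mild",
        "severe",
        "mild^2",
        "severe^2",
        "mild:severe",
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a named fixed-effect structure with logit link,
    equidistant thresholds and a respondent random intercept."""

    terms: str = "linear"

    def __post_init__(self) -> None:
        if self.terms not in MODEL_TERMS:
            raise ValueError(
                f"unknown term structure {self.terms!r}; "
                f"choose from {sorted(MODEL_TERMS)}"
            )

    @property
    def term_names(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.terms]


def design_matrix(mild: np.ndarray, severe: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Fixed-effect design columns for prevalence proportions in [0, 1]."""
    mild = np.asarray(mild, dtype=float)
    severe = np.asarray(severe, dtype=float)
    cols = {
        "mild": mild,
        "severe": severe,
        "mild^2": mild**2,
        "severe^2": severe**2,
        "mild:severe": mild * severe,
    }
    names = spec.term_names
    if not names:
        return np.empty((mild.shape[0], 0))
    return np.column_stack([cols[t] for t in names])


def ordinal_probs(alpha: float, delta: float, eta) -> np.ndarray:
    """Probabilities of the 11 levels given linear predictor(s) ``eta``
    (fixed effects plus any latent intercept)."""
    if delta <= 0:
        raise ValueError("threshold spacing delta must be positive")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    theta = alpha + delta * np.arange(_N_THRESH)
    cum = expit(theta[None, :] - eta[:, None])  # (n, 10)
    full = np.concatenate(
        [np.zeros((eta.size, 1)), cum, np.ones((eta.size, 1))], axis=1
    )
    return np.diff(full, axis=1)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _prepare(records: pd.DataFrame):
    """Extract (y, mild, severe, group starts) sorted by respondent.

    Accepts prevalence columns either as proportions (``mild``/``severe``) or
    percents (``mild_pct``/``severe_pct``).
    """
    df = records
    if "mild" in df.columns:
        mild = df["mild"].to_numpy(dtype=float)
        severe = df["severe"].to_numpy(dtype=float)
    elif "mild_pct" in df.columns:
        mild = df["mild_pct"].to_numpy(dtype=float) / 100.0
        severe = df["severe_pct"].to_numpy(dtype=float) / 100.0
    else:
        raise ValueError("records need mild/severe or mild_pct/severe_pct columns")
    if np.any(mild < 0) or np.any(mild > 1) or np.any(severe < 0) or np.any(severe > 1):
        raise ValueError("prevalences outside the unit interval after scaling")
    y = df["rating"].to_numpy()
    if not np.all((y == np.floor(y)) & (y >= 0) & (y <= 10)):
        raise ValueError("ratings must be integers in 0..10")
    y = y.astype(np.int64)
    codes, _ = pd.factorize(df["respondent_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    y, mild, severe, codes = y[order], mild[order], severe[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    return y, mild, severe, starts


def _data_hash(y: np.ndarray, mild: np.ndarray, severe: np.ndarray,
               starts: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in (y, mild, severe, starts):
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Marginal log-likelihood
# ---------------------------------------------------------------------------


def _loglik_core(
    alpha: float,
    delta: float,
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    starts: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    if delta <= 0:
        raise ValueError("threshold spacing delta must be positive")
    if sigma < 0:
        raise ValueError("random-effect SD sigma must be non-negative")
    eta = X @ beta if X.shape[1] else np.zeros(y.shape[0])
    upper = np.where(y < 10, alpha + delta * y, np.inf)
    lower = np.where(y > 0, alpha + delta * (y - 1), -np.inf)
    if sigma == 0.0:
        p = expit(upper - eta) - expit(lower - eta)
        return float(np.sum(np.log(np.clip(p, 1e-300, None))))
    u = np.sqrt(2.0) * sigma * nodes  # (K,)
    a = upper[:, None] - eta[:, None] - u[None, :]
    b = lower[:, None] - eta[:, None] - u[None, :]
    logp = np.log(np.clip(expit(a) - expit(b), 1e-300, None))  # (n, K)
    per_group = np.add.reduceat(logp, starts, axis=0)  # (G, K)
    return float(logsumexp(per_group + log_weights[None, :], axis=1).sum())


def _gh(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    nodes, weights = roots_hermite(order)
    return nodes, np.log(weights) - 0.5 * np.log(np.pi)


def clmm_loglik(
    records: pd.DataFrame,
    spec: ModelSpec,
    alpha: float,
    delta: float,
    beta: Mapping[str, float] | Sequence[float],
    sigma: float,
    gh_order: int = 31,
) -> float:
    """Marginal log-likelihood of the mixed cumulative-logit model.

    ``beta`` may be a mapping from term name to coefficient or a sequence
    aligned with ``spec.term_names``.  ``sigma = 0`` reduces exactly to the
    fixed-effects cumulative-logit log-likelihood.
    """
    y, mild, severe, starts = _prepare(records)
    X = design_matrix(mild, severe, spec)
    b = _beta_vector(beta, spec)
    nodes, logw = _gh(gh_order)
    return _loglik_core(alpha, delta, b, sigma, y, X, starts, nodes, logw)


def _beta_vector(beta, spec: ModelSpec) -> np.ndarray:
    names = spec.term_names
    if isinstance(beta, Mapping):
        missing = [t for t in names if t not in beta]
        if missing:
            raise ValueError(f"missing coefficients for terms {missing}")
        return np.array([float(beta[t]) for t in names])
    b = np.asarray(beta, dtype=float)
    if b.shape != (len(names),):
        raise ValueError(f"expected {len(names)} coefficients, got {b.shape}")
    return b


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinalFit:
    """Maximum-likelihood estimates of one cumulative-link (mixed) model."""

    spec: ModelSpec
    alpha: float
    delta: float
    beta: dict[str, float]
    sigma: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_obs: int
    n_groups: int
    data_hash: str
    se: dict[str, float] | None = None

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[t] for t in self.spec.term_names])

    def to_dict(self) -> dict:
        return {
            "terms": self.spec.terms,
            "alpha": self.alpha,
            "delta": self.delta,
            "beta": dict(self.beta),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "se": dict(self.se) if self.se else None,
        }


def _initial_thresholds(y: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of an arithmetic progression to empirical cumulative
    logits — a cheap but well-placed starting point."""
    freq = np.bincount(y, minlength=N_LEVELS) / y.size
    cum = np.clip(np.cumsum(freq)[:-1], 0.01, 0.99)
    logits = np.log(cum / (1 - cum))
    j = np.arange(_N_THRESH, dtype=float)
    slope, intercept = np.polyfit(j, logits, 1)
    return float(intercept), float(max(slope, 0.05))


_START_SIGMAS = (0.5, 1.5, 0.05, 3.0, 1.0)


def fit(
    records: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    gh_order: int = 31,
    n_starts: int = 5,
    sigma_floor: float = 0.02,
    compute_se: bool = False,
) -> OrdinalFit:
    """Fit the model by quasi-Newton maximization with deterministic multistarts.

    Degenerate random effects (fitted SD below ``sigma_floor``) are reported
    as sigma = 0 with the log-likelihood re-evaluated there, never as failure.
    """
    y, mild, severe, starts = _prepare(records)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct rating levels to fit")
    X = design_matrix(mild, severe, spec)
    p = X.shape[1]
    if p:
        scen = np.unique(np.column_stack([mild, severe]), axis=0)
        Xs = design_matrix(scen[:, 0], scen[:, 1], spec)
        if np.linalg.matrix_rank(Xs) < p:
            raise ValueError(
                f"design for terms {spec.terms!r} is rank-deficient over the "
                f"{scen.shape[0]} observed scenario(s); coefficients unidentifiable"
            )
    nodes, logw = _gh(gh_order)

    def nll(x: np.ndarray) -> float:
        alpha, delta = x[0], np.exp(x[1])
        beta = x[2 : 2 + p]
        sigma = np.exp(x[-1])
        return -_loglik_core(alpha, delta, beta, sigma, y, X, starts, nodes, logw)

    a0, d0 = _initial_thresholds(y)
    bounds = [(-60, 60), (-6, 3)] + [(-200, 200)] * p + [(-8, 3)]
    best = None
    for k in range(max(1, n_starts)):
        s0 = _START_SIGMAS[k % len(_START_SIGMAS)]
        x0 = np.r_[a0, np.log(d0), np.zeros(p), np.log(s0)]
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res

    alpha = float(best.x[0])
    delta = float(np.exp(best.x[1]))
    beta = best.x[2 : 2 + p].astype(float)
    sigma = float(np.exp(best.x[-1]))
    if sigma < sigma_floor:
        sigma = 0.0
    loglik = _loglik_core(alpha, delta, beta, sigma, y, X, starts, nodes, logw)
    n_params = 2 + p + 1  # alpha, delta, beta, sigma
    fit_res = OrdinalFit(
        spec=spec,
        alpha=alpha,
        delta=delta,
        beta={t: float(b) for t, b in zip(spec.term_names, beta)},
        sigma=sigma,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        converged=bool(best.success),
        n_obs=int(y.size),
        n_groups=int(starts.size),
        data_hash=_data_hash(y, mild, severe, starts),
        se=None,
    )
    if compute_se:
        se = _standard_errors(fit_res, y, X, starts, nodes, logw)
        fit_res = OrdinalFit(**{**fit_res.__dict__, "se": se})
    return fit_res


def _standard_errors(f: OrdinalFit, y, X, starts, nodes, logw) -> dict[str, float]:
    """Wald SEs from a central-difference Hessian on the natural scale."""
    names = ["alpha", "delta", *f.spec.term_names, "sigma"]
    x = np.r_[f.alpha, f.delta, f.beta_vector(), f.sigma]

    def ll(v: np.ndarray) -> float:
        return _loglik_core(
            v[0], v[1], v[2:-1], max(v[-1], 0.0), y, X, starts, nodes, logw
        )

    n = x.size
    h = 1e-4 * np.maximum(np.abs(x), 1.0)
    if f.sigma == 0.0:  # boundary: no Wald SE for sigma
        h[-1] = 0.0
    H = np.zeros((n, n))
    for i in range(n):
        if h[i] == 0:
            continue
        for j in range(i, n):
            if h[j] == 0:
                continue
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ll(x + ei + ej) - ll(x + ei - ej) - ll(x - ei + ej) + ll(x - ei - ej)
            ) / (4 * h[i] * h[j])
    active = np.flatnonzero(h > 0)
    se = np.full(n, np.nan)
    try:
        cov = np.linalg.inv(-H[np.ix_(active, active)])
        d = np.diag(cov)
        se[active] = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    return dict(zip(names, se.tolist()))


def select_by_aic(fits: Sequence[OrdinalFit]) -> tuple[OrdinalFit, pd.DataFrame]:
    """Minimum-AIC choice among fits of the same data; ties go to the model
    with fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1 or len({f.n_obs for f in fits}) > 1:
        raise ValueError("fits were not computed on identical data")
    table = pd.DataFrame(
        {
            "terms": [f.spec.terms for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values(["aic", "n_params"], kind="stable").reset_index(drop=True)
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    return best, table


# ---------------------------------------------------------------------------
# Prediction and binning
# ---------------------------------------------------------------------------


def predict_probs(fit_res: OrdinalFit, mild: float, severe: float) -> np.ndarray:
    """Ordinal probabilities of the 11 levels for the average respondent
    (latent intercept 0) at a (mild, severe) prevalence-proportion scenario."""
    if not (0.0 <= mild <= 1.0 and 0.0 <= severe <= 1.0):
        raise ValueError(f"scenario ({mild}, {severe}) outside the unit square")
    x = design_matrix(np.array([mild]), np.array([severe]), fit_res.spec)
    eta = float((x @ fit_res.beta_vector())[0]) if x.shape[1] else 0.0
    return ordinal_probs(fit_res.alpha, fit_res.delta, eta)[0]


@dataclass(frozen=True)
class CategoryBins:
    """Rating groups used to summarize the 0-10 acceptability scale."""

    edges: tuple[tuple[int, int], ...] = ((0, 2), (3, 4), (5, 7), (8, 10))
    labels: tuple[str, ...] = (
        "clearly unacceptable",
        "unacceptable",
        "acceptable",
        "clearly acceptable",
    )
    acceptable_threshold: int = 6

    def __post_init__(self) -> None:
        covered = [lvl for lo, hi in self.edges for lvl in range(lo, hi + 1)]
        if sorted(covered) != list(range(N_LEVELS)):
            raise ValueError("bins must partition the levels 0..10")
        if len(self.labels) != len(self.edges):
            raise ValueError("one label per bin required")


def _check_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (N_LEVELS,):
        raise ValueError(f"expected {N_LEVELS} probabilities, got shape {p.shape}")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def bin_probs(probs, bins: CategoryBins = CategoryBins()) -> np.ndarray:
    """Sum level probabilities into the four acceptability bins."""
    p = _check_probs(probs)
    return np.array([p[lo : hi + 1].sum() for lo, hi in bins.edges])


def prob_acceptable(probs, threshold: int = 6) -> float:
    """P(rating >= threshold) = 1 - P(rating <= threshold - 1)."""
    p = _check_probs(probs)
    return float(p[threshold:].sum())


# ---------------------------------------------------------------------------
# Panel cleaning
# ---------------------------------------------------------------------------


def _count_violations(sub: pd.DataFrame) -> int:
    """Ordered scenario pairs where the componentwise-worse scenario got a
    strictly higher acceptability rating."""
    m = sub["_mild"].to_numpy()
    s = sub["_severe"].to_numpy()
    r = sub["rating"].to_numpy()
    n = len(sub)
    count = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            worse = m[j] >= m[i] and s[j] >= s[i] and (m[j] > m[i] or s[j] > s[i])
            if worse and r[j] > r[i]:
                count += 1
    return count


def clean_panel(
    records: pd.DataFrame,
    expected_per_respondent: int | None = 5,
    min_violations: int = 2,
) -> tuple[pd.DataFrame, list, dict]:
    """Remove nonsensical and incomplete respondents.

    A respondent is nonsensical when at least ``min_violations`` ordered
    scenario pairs show a strictly higher rating at a componentwise strictly
    worse prevalence.  Respondents with fewer than
    ``expected_per_respondent`` ratings are removed as incomplete
    (pass ``None`` to disable).  Returns the kept records in deterministic
    order, the removed respondent ids, and a reason per removed id.
    """
    df = records.copy()
    if "mild" in df.columns:
        df["_mild"], df["_severe"] = df["mild"], df["severe"]
    elif "mild_pct" in df.columns:
        df["_mild"], df["_severe"] = df["mild_pct"], df["severe_pct"]
    else:
        raise ValueError("records need mild/severe or mild_pct/severe_pct columns")
    dup = df.duplicated(subset=["respondent_id", "_mild", "_severe"])
    if dup.any():
        bad = df.loc[dup, "respondent_id"].iloc[0]
        raise ValueError(f"duplicate scenario for respondent {bad!r}")

    removed_ids: list = []
    reasons: dict = {}
    for rid, sub in df.groupby("respondent_id", sort=True):
        nviol = _count_violations(sub)
        if nviol >= min_violations:
            removed_ids.append(rid)
            reasons[rid] = f"nonsensical ({nviol} dominance violations)"
        elif (
            expected_per_respondent is not None
            and len(sub) < expected_per_respondent
        ):
            removed_ids.append(rid)
            reasons[rid] = f"incomplete ({len(sub)}/{expected_per_respondent} ratings)"
    kept = (
        df[~df["respondent_id"].isin(removed_ids)]
        .sort_values(["respondent_id", "_mild", "_severe"], kind="stable")
        .drop(columns=["_mild", "_severe"])
        .reset_index(drop=True)
    )
    return kept, removed_ids, reasons


# ---------------------------------------------------------------------------
# Per-measure agreement model
# ---------------------------------------------------------------------------


def fit_agreement(
    measure_scores: pd.DataFrame,
    gh_order: int = 31,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Respondent-SD estimates per measure from an intercept-only
    cumulative-link random-effects model.

    Expects columns respondent_id, measure, rating.  Measures whose scores are
    constant (or otherwise unfittable) are returned flagged, not dropped.
    """
    rows = []
    for measure, sub in measure_scores.groupby("measure", sort=True):
        if sub.groupby("respondent_id").size().min() < 1 or sub["respondent_id"].nunique() < 2:
            raise ValueError(f"measure {measure!r}: need >= 2 respondents")
        df = sub.assign(mild=0.0, severe=0.0)
        try:
            f = fit(df, ModelSpec("none"), gh_order=gh_order, n_starts=n_starts)
            rows.append(
                {
                    "measure": measure,
                    "sigma": f.sigma,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "converged": f.converged,
                }
            )
        except ValueError:
            rows.append(
                {
                    "measure": measure,
                    "sigma": np.nan,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "converged": False,
                }
            )
    return pd.DataFrame(rows)
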