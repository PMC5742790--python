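import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    RECOVERY_TRUTH,
    brute_force_loglik,
    cumlogit_level_probs,
    fixed_effects_loglik,
)
from welfagg.ordinal import (
    CategoryBins,
    ModelSpec,
    OrdinalFit,
    bin_probs,
    clean_panel,
    clmm_loglik,
    fit,
    fit_agreement,
    predict_probs,
    prob_acceptable,
    select_by_aic,
)
from welfagg.synthetic_data import (
    MeasurePanelConfig,
    OrdinalTruth,
    PanelConfig,
    generate_expert_ratings,
    generate_measure_scores,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["respondent_id", "mild_pct", "severe_pct",
                                       "rating"])


class TestLoglik:
    def test_closed_form_single_record(self):
        df = _records([("a", 0.0, 0.0, 0)])
        ll = clmm_loglik(df, ModelSpec("linear"), alpha=0.0, delta=1.0,
                         beta={"mild": 0.0, "severe": 0.0}, sigma=0.0)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_sigma_zero_reduces_to_fixed_effects_exactly(self, small_panel):
        beta = {"mild": -5.0, "severe": -20.0}
        ll = clmm_loglik(small_panel, ModelSpec("linear"), alpha=-4.5, delta=1.0,
                         beta=beta, sigma=0.0)
        oracle = fixed_effects_loglik(small_panel, -4.5, 1.0, beta)
        assert ll == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.5])
    def test_quadrature_matches_brute_force(self, small_panel, sigma):
        beta = {"mild": -5.0, "severe": -20.0}
        ll = clmm_loglik(small_panel, ModelSpec("linear"), alpha=-4.5, delta=1.0,
                         beta=beta, sigma=sigma, gh_order=101)
        oracle = brute_force_loglik(small_panel, -4.5, 1.0, beta, sigma)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_invalid_parameters_rejected(self, small_panel):
        beta = {"mild": 0.0, "severe": 0.0}
        with pytest.raises(ValueError, match="delta"):
            clmm_loglik(small_panel, ModelSpec("linear"), alpha=0, delta=-1,
                        beta=beta, sigma=1.0)
        with pytest.raises(ValueError, match="sigma"):
            clmm_loglik(small_panel, ModelSpec("linear"), alpha=0, delta=1,
                        beta=beta, sigma=-0.5)

    def test_quadrature_order_validated(self, small_panel):
        with pytest.raises(ValueError, match="order"):
            clmm_loglik(small_panel, ModelSpec("linear"), alpha=0, delta=1,
                        beta={"mild": 0.0, "severe": 0.0}, sigma=1.0, gh_order=0)


class TestFit:
    def test_recovery_linear(self, standard_panel):
        # truth has quadratic+interaction terms; a linear fit still converges
        f = fit(standard_panel, ModelSpec("linear"), n_starts=2)
        assert f.converged
        assert f.beta["mild"] < 0 and f.beta["severe"] < 0
        assert f.sigma > 0.5

    def test_sigma_zero_boundary(self):
        truth = OrdinalTruth(alpha=-4.0, delta=0.8,
                             beta={"mild": -4.0, "severe": -15.0}, sigma=0.0)
        rec = generate_expert_ratings(PanelConfig(n_respondents=300, seed=17,
                                                  truth=truth))
        f = fit(rec, ModelSpec("linear"), n_starts=2)
        assert f.sigma < 0.05

    def test_single_scenario_unidentifiable(self):
        rec = generate_expert_ratings(
            PanelConfig(n_respondents=30, scenarios=((40.0, 5.0),),
                        per_respondent=1, seed=2)
        )
        with pytest.raises(ValueError, match="rank-deficient|unidentifiable"):
            fit(rec, ModelSpec("linear"))

    def test_constant_response_rejected(self):
        df = _records([("a", 10.0, 0.0, 5), ("b", 40.0, 0.0, 5),
                       ("c", 70.0, 0.0, 5)])
        with pytest.raises(ValueError, match="distinct rating"):
            fit(df, ModelSpec("linear"))

    def test_aic_identity(self, standard_panel):
        f = fit(standard_panel, ModelSpec("linear"), n_starts=1)
        assert f.n_params == 2 + 2 + 1
        assert f.aic == pytest.approx(-2.0 * f.loglik + 2.0 * f.n_params)


class TestSelectByAic:
    def _fake_fit(self, terms, loglik, n_obs=905, data_hash="x"):
        spec = ModelSpec(terms)
        k = 2 + len(spec.term_names) + 1
        return OrdinalFit(
            spec=spec, alpha=-5.0, delta=1.0,
            beta={t: 0.0 for t in spec.term_names}, sigma=1.0,
            loglik=loglik, aic=-2 * loglik + 2 * k, n_params=k,
            converged=True, n_obs=n_obs, n_groups=181, data_hash=data_hash,
        )

    def test_aic_arithmetic(self):
        # oracle: AIC = -2*loglik + 2*k
        f1 = self._fake_fit("linear+quadratic+interaction", -1197.3)  # k=8
        f2 = self._fake_fit("linear+interaction", -1183.9)  # k=6
        assert f1.aic == pytest.approx(2410.6)
        assert f2.aic == pytest.approx(2379.8)
        best, table = select_by_aic([f1, f2])
        assert best is f2
        assert list(table["terms"])[0] == "linear+interaction"

    def test_ties_break_toward_fewer_parameters(self):
        f_small = self._fake_fit("linear", -1000.0)
        # larger model with loglik tuned so the AICs tie exactly
        f_big = self._fake_fit("linear+interaction", -999.0)
        assert f_small.aic == f_big.aic
        best, _ = select_by_aic([f_big, f_small])
        assert best.spec.terms == "linear"

    def test_differing_data_rejected(self):
        f1 = self._fake_fit("linear", -1000.0, data_hash="a")
        f2 = self._fake_fit("linear+interaction", -990.0, data_hash="b")
        with pytest.raises(ValueError, match="identical data"):
            select_by_aic([f1, f2])


class TestPrediction:
    def test_probabilities_sum_to_one_on_grid(self, standard_panel):
        f = fit(standard_panel, ModelSpec("linear"), n_starts=1)
        for mild in (0.0, 0.1, 0.4, 0.7, 1.0):
            for severe in (0.0, 0.05, 0.15, 0.3):
                p = predict_probs(f, mild, severe)
                assert p.min() >= 0
                assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_acceptability_decreases_with_severe(self, standard_panel):
        f = fit(standard_panel, ModelSpec("linear"), n_starts=1)
        assert all(b < 0 for b in f.beta.values())
        vals = [prob_acceptable(predict_probs(f, 0.1, s))
                for s in np.linspace(0, 0.5, 11)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_scenario_domain_checked(self, standard_panel):
        f = fit(standard_panel, ModelSpec("linear"), n_starts=1)
        with pytest.raises(ValueError, match="unit square"):
            predict_probs(f, 1.5, 0.0)

    def test_affine_reencoding_invariance(self, small_panel):
        # halving the covariate units while doubling coefficients leaves
        # the likelihood unchanged
        beta = {"mild": -5.0, "severe": -20.0}
        ll1 = clmm_loglik(small_panel, ModelSpec("linear"), alpha=-4.5,
                          delta=1.0, beta=beta, sigma=1.0)
        rescaled = small_panel.assign(
            mild=small_panel["mild_pct"] / 100.0 / 2.0,
            severe=small_panel["severe_pct"] / 100.0 / 2.0,
        ).drop(columns=["mild_pct", "severe_pct"])
        ll2 = clmm_loglik(rescaled, ModelSpec("linear"), alpha=-4.5, delta=1.0,
                          beta={"mild": -10.0, "severe": -40.0}, sigma=1.0)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestBinning:
    def test_uniform_bins(self):
        p = np.full(11, 1 / 11)
        assert bin_probs(p) == pytest.approx([3 / 11, 2 / 11, 3 / 11, 3 / 11])
        assert prob_acceptable(p) == pytest.approx(5 / 11)

    def test_point_mass(self):
        p = np.zeros(11)
        p[0] = 1.0
        assert bin_probs(p) == pytest.approx([1, 0, 0, 0])
        assert prob_acceptable(p) == 0.0

    def test_malformed_vector_rejected(self):
        with pytest.raises(ValueError):
            bin_probs(np.full(10, 0.1))
        with pytest.raises(ValueError):
            bin_probs(np.full(11, 0.5))

    def test_bins_partition_levels(self):
        with pytest.raises(ValueError, match="partition"):
            CategoryBins(edges=((0, 2), (3, 4), (5, 7), (8, 9)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_bin_sums_conserve_mass(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(11))
        assert bin_probs(p).sum() == pytest.approx(1.0, abs=1e-9)


class TestCleanPanel:
    def test_three_violations_removed(self):
        df = _records([("a", 10, 0, 2), ("a", 40, 0, 5), ("a", 70, 0, 8)])
        kept, removed, reasons = clean_panel(df, expected_per_respondent=None)
        assert removed == ["a"]
        assert "3 dominance violations" in reasons["a"]
        assert kept.empty

    def test_constant_ratings_kept(self):
        df = _records([("a", m, s, 4) for m, s in
                       [(10, 0), (40, 0), (70, 0), (10, 5), (40, 5)]])
        kept, removed, _ = clean_panel(df, expected_per_respondent=5)
        assert removed == []
        assert len(kept) == 5

    def test_single_violation_kept(self):
        df = _records([("a", 10, 0, 5), ("a", 40, 0, 6), ("a", 70, 0, 3),
                       ("a", 40, 5, 2), ("a", 40, 15, 1)])
        kept, removed, _ = clean_panel(df, expected_per_respondent=5)
        assert removed == []
        assert len(kept) == 5

    def test_incomplete_respondent_removed(self):
        df = _records([("a", 10, 0, 5), ("a", 40, 0, 4)])
        kept, removed, reasons = clean_panel(df, expected_per_respondent=5)
        assert removed == ["a"]
        assert "incomplete" in reasons["a"]

    def test_duplicate_scenario_rejected(self):
        df = _records([("a", 10, 0, 5), ("a", 10, 0, 4)])
        with pytest.raises(ValueError, match="duplicate"):
            clean_panel(df)

    def test_idempotent(self):
        cfg = PanelConfig(n_respondents=60, contamination_rate=0.3, seed=33)
        rec = generate_expert_ratings(cfg)
        kept1, removed1, _ = clean_panel(rec, expected_per_respondent=5)
        kept2, removed2, _ = clean_panel(kept1, expected_per_respondent=5)
        assert removed2 == []
        pd.testing.assert_frame_equal(
            kept1.reset_index(drop=True), kept2.reset_index(drop=True)
        )

    def test_contaminants_mostly_caught(self):
        cfg = PanelConfig(n_respondents=100, contamination_rate=0.5, seed=44)
        rec = generate_expert_ratings(cfg)
        kept, removed, _ = clean_panel(rec, expected_per_respondent=5)
        contaminants = set(rec.loc[rec["contaminant"], "respondent_id"])
        # uniform raters almost surely produce >= 2 dominance violations
        assert len(contaminants & set(removed)) >= 0.7 * len(contaminants)


@pytest.fixture(scope="module")
def measure_panel():
    cfg = MeasurePanelConfig(
        measures={"low_sd": (5.0, 0.5), "high_sd": (5.0, 3.0)},
        n_respondents=500, seed=77,
    )
    return generate_measure_scores(cfg)


class TestAgreement:
    def test_sd_rank_order_recovered(self, measure_panel):
        res = fit_agreement(measure_panel, gh_order=21).set_index("measure")
        assert res.loc["high_sd", "sigma"] > res.loc["low_sd", "sigma"] + 1.0

    def test_relabelling_invariance(self, measure_panel):
        res1 = fit_agreement(measure_panel, gh_order=21)
        relabelled = measure_panel.copy()
        relabelled["respondent_id"] = (
            relabelled["respondent_id"].map(lambda r: f"z_{r}")
        )
        res2 = fit_agreement(relabelled, gh_order=21)
        assert np.allclose(res1["sigma"], res2["sigma"], atol=1e-6)

    def test_constant_measure_flagged(self):
        df = pd.DataFrame(
            {
                "respondent_id": [f"r{i}" for i in range(20)],
                "measure": "const",
                "rating": 7,
            }
        )
        res = fit_agreement(df)
        assert not res.loc[0, "converged"]
        assert np.isnan(res.loc[0, "sigma"])

    def test_sd_zero_measure_estimated_near_zero(self):
        # one rating per respondent makes (delta, sigma) trade off along a
        # flat likelihood ridge, so the no-heterogeneity check needs large n
        cfg = MeasurePanelConfig(measures={"flat": (5.0, 0.0)},
                                 n_respondents=2000, seed=88)
        res = fit_agreement(generate_measure_scores(cfg), gh_order=21)
        assert res.loc[0, "sigma"] < 0.1
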