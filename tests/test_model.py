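"""Cumulative-logit model: link, likelihood, estimation, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steppedwedge.model import (
    CoefEstimate,
    CumulativeProbabilities,
    FitOptions,
    FitResult,
    LinkageError,
    ModelDesign,
    ModelSpec,
    build_model_matrix,
    cumulative_link,
    expected_cell_design,
    fit,
    fit_fixed_effects,
    negative_log_likelihood_fixed,
    population_or_oracle,
    wald_summary,
)
from steppedwedge.simulate import ScenarioConfig, simulate_dataset

LOG3 = np.log(3.0)


class TestModelSpec:
    @pytest.mark.parametrize(
        "number, terms",
        [
            (1, ["intercept", "qtr", "treat", "qtr_x_treat"]),
            (2, ["intercept", "female", "nonwhite"]),
            (3, ["intercept", "med", "lg"]),
            (4, ["intercept", "qtr", "treat", "qtr_x_treat", "female", "nonwhite", "med", "lg"]),
        ],
    )
    def test_standard_models_select_their_blocks(self, number, terms):
        assert ModelSpec.from_number(number).terms == terms

    def test_unknown_model_number_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_number(5)


class TestBuildModelMatrix:
    def test_fixed_parameter_counts(self, small_dataset, schedule):
        # Model 1: intercept + 3 time predictors (+2 thresholds = 6 fixed parameters)
        d1 = build_model_matrix(small_dataset, schedule, ModelSpec.from_number(1))
        assert d1.p == 4
        d4 = build_model_matrix(small_dataset, schedule, ModelSpec.from_number(4))
        assert d4.p == 8

    def test_cluster_structure(self, small_dataset, schedule):
        d = build_model_matrix(small_dataset, schedule, ModelSpec.from_number(1))
        assert d.n_cells == 108
        assert d.n_sites == 9
        assert d.counts.sum() == len(small_dataset)

    def test_control_cell_rows_have_zero_treat(self, small_dataset, schedule):
        d = build_model_matrix(small_dataset, schedule, ModelSpec.from_number(1))
        row = d.cell_keys.reset_index().set_index(["site_id", "quarter"])
        site1_q1 = d.cell_idx == row.loc[(1, 1), "index"]
        assert (d.X[site1_q1, 2] == 0).all()  # treat
        assert (d.X[site1_q1, 3] == 0).all()  # qtr_x_treat

    def test_out_of_schedule_record_rejected(self, small_dataset, schedule):
        bad = small_dataset.copy()
        bad.loc[bad.index[0], "quarter"] = 13
        with pytest.raises(LinkageError):
            build_model_matrix(bad, schedule, ModelSpec.from_number(1))

    def test_aggregation_is_permutation_invariant(self, small_dataset, schedule):
        shuffled = small_dataset.sample(frac=1.0, random_state=0)
        a = build_model_matrix(small_dataset, schedule, ModelSpec.from_number(4))
        b = build_model_matrix(shuffled, schedule, ModelSpec.from_number(4))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestCumulativeLink:
    def test_zero_everything_gives_half(self):
        probs = cumulative_link(0.0, (0.0, 0.0, 0.0))
        assert (probs.phi_star_1, probs.phi_star_2, probs.phi_star_3) == (0.5, 0.5, 0.5)

    def test_uniform_distribution_inverts_exactly(self):
        # logit(0.25) = -log 3, logit(0.5) = 0, logit(0.75) = +log 3
        probs = cumulative_link(-LOG3, (0.0, LOG3, 2 * LOG3))
        assert probs.category_probs() == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_large_predictor_puts_all_mass_on_always(self):
        probs = cumulative_link(20.0, (0.0, 1.0, 2.0))
        assert probs.phi_star_1 > 1 - 1e-8
        assert probs.category_probs()[0] > 1 - 1e-8

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cumulative_link(0.0, (0.0, 2.0, 1.0))
        with pytest.raises(ValueError):
            CumulativeProbabilities(0.9, 0.5, 0.95)


def intercept_only_design(counts_row: np.ndarray) -> ModelDesign:
    return ModelDesign(
        X=np.ones((1, 1)),
        counts=np.atleast_2d(np.asarray(counts_row, dtype=float)),
        cell_idx=np.zeros(1, dtype=int),
        site_idx=np.zeros(1, dtype=int),
        cell_site=np.zeros(1, dtype=int),
        terms=["intercept"],
        cell_keys=pd.DataFrame(),
        n_obs=float(np.sum(counts_row)),
    )


class TestFixedNLL:
    def test_single_always_record_contributes_log_half(self):
        design = intercept_only_design([1, 0, 0, 0])
        nll = negative_log_likelihood_fixed(np.array([0.0, LOG3, 2 * LOG3]), design)
        assert nll == pytest.approx(-np.log(0.5))

    def test_unordered_thresholds_rejected_with_infinite_nll(self):
        design = intercept_only_design([1, 0, 0, 0])
        assert negative_log_likelihood_fixed(np.array([0.0, 2.0, 1.0]), design) == np.inf
        assert negative_log_likelihood_fixed(np.array([0.0, -1.0, 1.0]), design) == np.inf

    def test_intercept_only_optimum_matches_empirical_proportions(self):
        """On a single uniform cell the ML category probabilities are the
        empirical proportions, so the optimal NLL equals n times the
        empirical entropy."""
        counts = np.array([30.0, 25.0, 25.0, 20.0])
        design = intercept_only_design(counts)
        params, nll, _ = fit_fixed_effects(design)
        props = counts / counts.sum()
        plug_in = -np.sum(counts * np.log(props))
        assert nll == pytest.approx(plug_in, abs=1e-6)
        fitted = cumulative_link(params[0], (0.0, params[1], params[2])).category_probs()
        assert fitted == pytest.approx(tuple(props), abs=1e-5)

    def test_nll_never_beats_the_entropy_bound(self):
        """Brute force over a toy 20-record cell: no parameter setting
        beats the empirical-distribution plug-in."""
        counts = np.array([8.0, 6.0, 4.0, 2.0])
        design = intercept_only_design(counts)
        props = counts / counts.sum()
        bound = -np.sum(counts * np.log(props))
        rng = np.random.default_rng(0)
        for _ in range(200):
            beta0 = rng.normal(scale=2.0)
            d2 = rng.uniform(0.05, 4.0)
            d3 = d2 + rng.uniform(0.05, 4.0)
            assert negative_log_likelihood_fixed(np.array([beta0, d2, d3]), design) >= bound - 1e-9


class TestFitAgainstIndependentOracle:
    def test_zero_variance_fit_matches_statsmodels_ordered_model(self, schedule):
        """With both variances pinned at 0 the fit must agree with an
        independent proportional-odds optimizer (statsmodels OrderedModel;
        its parameterization is logit P(Y<=m) = alpha_m - x'beta, so signs
        flip and thresholds accumulate from log-increments)."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        from steppedwedge.schedule import design_frame

        config = ScenarioConfig(n_per_cell=60, seed=77)
        data = simulate_dataset(config)
        ours = fit(data, schedule, ModelSpec.from_number(1), FitOptions(fix_variances=(0.0, 0.0)))

        merged = data.merge(design_frame(schedule), on=["site_id", "quarter"])
        endog = pd.Categorical(merged["access"], categories=[1, 2, 3, 4], ordered=True)
        exog = merged[["qtr", "treat", "qtr_x_treat"]].astype(float)
        sm_fit = OrderedModel(endog, exog, distr="logit").fit(method="bfgs", maxiter=500, disp=False, gtol=1e-10)
        sm = np.asarray(sm_fit.params)
        alpha = np.array([sm[3], sm[3] + np.exp(sm[4]), sm[3] + np.exp(sm[4]) + np.exp(sm[5])])

        assert ours.coefficients["intercept"].estimate == pytest.approx(alpha[0], abs=1e-4)
        assert ours.coefficients["qtr"].estimate == pytest.approx(-sm[0], abs=1e-4)
        assert ours.coefficients["treat"].estimate == pytest.approx(-sm[1], abs=1e-4)
        assert ours.coefficients["qtr_x_treat"].estimate == pytest.approx(-sm[2], abs=1e-4)
        assert ours.delta2 == pytest.approx(alpha[1] - alpha[0], abs=1e-4)
        assert ours.delta3 == pytest.approx(alpha[2] - alpha[0], abs=1e-4)


class TestMixedFit:
    def test_record_order_does_not_change_estimates(self, schedule):
        config = ScenarioConfig(n_per_cell=30, seed=13)
        data = simulate_dataset(config)
        shuffled = data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = fit(data, schedule, ModelSpec.from_number(1))
        b = fit(shuffled, schedule, ModelSpec.from_number(1))
        for term in a.coefficients:
            assert abs(a.coefficients[term].estimate - b.coefficients[term].estimate) < 1e-10
        assert abs(a.delta2 - b.delta2) < 1e-10
        assert abs(a.delta3 - b.delta3) < 1e-10

    def test_thresholds_ordered_and_variances_nonnegative(self, schedule):
        for seed in (1, 2):
            data = simulate_dataset(ScenarioConfig(n_per_cell=40, seed=seed))
            res = fit(data, schedule, ModelSpec.from_number(1))
            assert 0.0 < res.delta2 < res.delta3
            assert res.variance_time >= 0.0 and res.variance_site >= 0.0
            assert res.converged

    def test_null_dataset_gives_treat_near_zero_and_boundary_variances(self, schedule):
        data = simulate_dataset(ScenarioConfig(n_per_cell=150, seed=3, null_effect=True))
        res = fit(data, schedule, ModelSpec.from_number(1))
        c = res.coefficients["treat"]
        assert abs(c.estimate) < 3 * c.se
        assert res.boundary_variance  # nothing to absorb: variances collapse

    def test_odds_ratio_is_exp_estimate(self, schedule):
        data = simulate_dataset(ScenarioConfig(n_per_cell=30, seed=21))
        res = fit(data, schedule, ModelSpec.from_number(4))
        for c in res.coefficients.values():
            assert c.odds_ratio == pytest.approx(np.exp(c.estimate))

    def test_population_average_mode_runs_with_cluster_ses(self, schedule):
        data = simulate_dataset(ScenarioConfig(n_per_cell=30, seed=2))
        res = fit(data, schedule, ModelSpec.from_number(1), FitOptions(estimator="population_average"))
        assert res.estimator == "population_average"
        assert all(np.isfinite(c.se) and c.se > 0 for c in res.coefficients.values())

    def test_empty_dataset_rejected(self, schedule):
        with pytest.raises(ValueError):
            fit(pd.DataFrame(), schedule, ModelSpec.from_number(1))


class TestWaldSummary:
    def make_result(self, estimate, se):
        coef = CoefEstimate("treat", estimate, se, float(np.exp(estimate)),
                            float(2 * stats.norm.sf(abs(estimate) / se)) if se > 0 else np.nan)
        return FitResult(
            spec=ModelSpec.from_number(1), estimator="laplace", coefficients={"treat": coef},
            delta2=1.0, delta3=2.0, delta2_se=0.01, delta3_se=0.01,
            variance_time=0.0, variance_site=0.0, nll=0.0, converged=True,
            n_iterations=1, gradient_norm=0.0, n_obs=10,
        )

    def test_strongly_significant_estimate_marked(self):
        row = wald_summary(self.make_result(0.265, 0.048)).set_index("term").loc["treat"]
        assert row["z"] == pytest.approx(5.52, abs=0.01)
        assert row["p_value"] < 0.001
        assert row["mark"] == "**"
        assert row["cell"] == "0.265 (0.048)/1.303**"

    def test_null_estimate_unmarked(self):
        row = wald_summary(self.make_result(0.0, 1.0)).set_index("term").loc["treat"]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["mark"] == ""

    def test_one_sigma_estimate_not_significant(self):
        row = wald_summary(self.make_result(0.005, 0.005)).set_index("term").loc["treat"]
        assert row["p_value"] > 0.05
        assert row["mark"] == ""


class TestPopulationOracle:
    def test_null_scenario_implies_unit_odds_ratios(self):
        config = ScenarioConfig(null_effect=True, seed=1)
        oracle = population_or_oracle(config)
        assert oracle.pooled_or == pytest.approx((1.0, 1.0, 1.0))
        assert oracle.projected["treat"] == pytest.approx(0.0, abs=1e-5)
        assert oracle.implied_treatment_or == pytest.approx(1.0, abs=1e-3)

    def test_first_split_or_closed_form(self):
        """Every on-cell at (1/3, 1/4, 1/4, 1/6) against uniform control:
        first-split OR = (1/3 / 2/3) / (1/4 / 3/4) = 1.5 exactly."""
        config = ScenarioConfig(
            jump_always=(1 / 3, 1 / 3),
            jump_usually=(0.25, 0.25),
            jump_sometimes=(0.25, 0.25),
            jump_never=(1 / 6, 1 / 6),
            drift_range=(0.0, 0.0),
            seed=8,
        )
        oracle = population_or_oracle(config)
        assert oracle.pooled_or[0] == pytest.approx(1.5, abs=1e-9)

    def test_expected_design_counts_are_cell_sized(self):
        config = ScenarioConfig(seed=5)
        design = expected_cell_design(config)
        assert design.counts.shape == (108, 4)
        np.testing.assert_allclose(design.counts.sum(axis=1), config.n_per_cell)
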