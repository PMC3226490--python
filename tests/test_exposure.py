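"""Exposure-model operations: annual means, screening, fits, assignment."""

import numpy as np
import pandas as pd
import pytest

from facohort.config import DWELLING_PREDICTORS, SynthConfig
from facohort.errors import FacohortError, SchemaError
from facohort.exposure import (
    aic_search,
    annual_means,
    assign_cohort_exposure,
    classify_linear_predictions,
    compute_annual_mean,
    exposure_thresholds,
    fit_linear_exposure_model,
    fit_logistic_exposure_model,
    fit_multinomial_tertile_model,
    handle_below_loq,
    select_model_aic,
    univariate_screen,
)
from facohort.synth import generate_dwellings, generate_seasonal_measurements, generate_true_fa


def _meas(dwelling, season_levels):
    return pd.DataFrame(
        {
            "dwelling_id": dwelling,
            "season": list(season_levels),
            "fa_level": [season_levels[s] for s in season_levels],
        }
    )


class TestAnnualMean:
    def test_four_equal_seasons(self):
        m = _meas("D1", {"winter": 19.5, "spring": 19.5, "summer": 19.5, "autumn": 19.5})
        rec = compute_annual_mean(m)
        assert rec["annual_mean"] == pytest.approx(19.5)
        assert rec["n_seasons"] == 4

    def test_arithmetic_mean(self):
        m = _meas("D1", {"winter": 10, "spring": 20, "summer": 20, "autumn": 30})
        assert compute_annual_mean(m)["annual_mean"] == pytest.approx(20.0)

    def test_too_few_seasons_excluded(self):
        m = _meas("D1", {"winter": 10, "spring": 20, "summer": 30})
        assert compute_annual_mean(m, min_seasons=4) is None
        assert compute_annual_mean(m, min_seasons=3)["n_seasons"] == 3

    def test_duplicated_season_raises(self):
        m = pd.DataFrame({"dwelling_id": "D1", "season": ["winter", "winter"],
                          "fa_level": [10.0, 12.0]})
        with pytest.raises(FacohortError, match="duplicated season"):
            compute_annual_mean(m)

    def test_season_order_invariance_and_scaling(self):
        m1 = _meas("D1", {"winter": 10, "spring": 20, "summer": 20, "autumn": 30})
        m2 = m1.iloc[::-1].reset_index(drop=True)
        assert (compute_annual_mean(m1)["annual_mean"]
                == compute_annual_mean(m2)["annual_mean"])
        m3 = m1.copy()
        m3["fa_level"] *= 2.5
        assert compute_annual_mean(m3)["annual_mean"] == pytest.approx(50.0)


class TestBelowLoq:
    def _flagged(self):
        return pd.DataFrame({"dwelling_id": "D1", "season": ["winter", "spring"],
                             "fa_level": [2.0, 10.0], "below_loq": [1, 0]})

    def test_half_loq_substitution(self):
        out = handle_below_loq(self._flagged(), "half_loq")
        assert out["fa_level"].iloc[0] == pytest.approx(1.2)
        assert out["fa_level"].iloc[1] == pytest.approx(10.0)

    def test_no_flags_identity(self):
        m = self._flagged().assign(below_loq=0)
        pd.testing.assert_frame_equal(handle_below_loq(m, "half_loq"), m)

    def test_as_reported_unchanged(self):
        m = self._flagged()
        out = handle_below_loq(m, "as_reported")
        pd.testing.assert_frame_equal(out, m)


@pytest.fixture(scope="module")
def measured_sample():
    """A clean measured sample: 400 dwellings, full seasons, annual means."""
    cfg = SynthConfig(seed=31, missing_season_prob=0.0)
    dwellings = generate_dwellings(400, cfg, seed=31)
    fa = generate_true_fa(dwellings, cfg, seed=31)
    meas = generate_seasonal_measurements(fa, cfg, seed=31)
    ann = annual_means(meas, min_seasons=4)
    return cfg, dwellings, ann


class TestScreen:
    def test_forced_in_retained_even_if_null(self, measured_sample):
        _, dwellings, ann = measured_sample
        res = univariate_screen(ann, dwellings, alpha=1e-9,
                                forced_in=("mech_ventilation",))
        assert "mech_ventilation" in res["candidates"]

    def test_alpha_one_retains_all(self, measured_sample):
        _, dwellings, ann = measured_sample
        res = univariate_screen(ann, dwellings, alpha=1.0)
        assert set(res["candidates"]) == set(DWELLING_PREDICTORS)

    def test_constant_predictor_warns_not_raises(self, measured_sample):
        _, dwellings, ann = measured_sample
        dw = dwellings.copy()
        dw["mech_ventilation"] = "0"
        with pytest.warns(UserWarning, match="constant"):
            res = univariate_screen(ann, dw)
        assert "mech_ventilation" not in res["candidates"]
        assert np.isnan(res["pvalues"]["mech_ventilation"])

    def test_null_predictor_excluded_at_expected_rate(self):
        # p ~ Uniform(0,1) under the null -> P(p <= 0.20) = 0.20
        rng_keep = 0
        n_rep = 120
        for rep in range(n_rep):
            cfg = SynthConfig(seed=5000 + rep, missing_season_prob=0.0,
                              exposure_coeffs={"double_glazing": 0.28})
            dwellings = generate_dwellings(120, cfg, seed=5000 + rep)
            fa = generate_true_fa(dwellings, cfg, seed=5000 + rep)
            meas = generate_seasonal_measurements(fa, cfg, seed=5000 + rep)
            ann = annual_means(meas, min_seasons=4)
            res = univariate_screen(ann, dwellings)
            if "mech_ventilation" in res["candidates"]:  # a null predictor here
                rng_keep += 1
        rate = rng_keep / n_rep
        se = np.sqrt(0.2 * 0.8 / n_rep)
        assert abs(rate - 0.20) < 3 * se


class TestLinearFit:
    def test_noiseless_recovery_of_generating_coefficients(self):
        cfg = SynthConfig(seed=41, residual_sd=1e-9, measurement_noise_sd=0.0,
                          missing_season_prob=0.0,
                          seasonal_offsets={s: 0.0 for s in
                                            ("winter", "spring", "summer", "autumn")})
        dwellings = generate_dwellings(300, cfg, seed=41)
        fa = generate_true_fa(dwellings, cfg, seed=41)
        meas = generate_seasonal_measurements(fa, cfg, seed=41)
        ann = annual_means(meas, min_seasons=4)
        fit = fit_linear_exposure_model(ann, dwellings)
        for key, beta in cfg.exposure_coeffs.items():
            assert fit.params[key] == pytest.approx(beta, abs=5e-4), key
        assert fit.params["const"] == pytest.approx(cfg.exposure_intercept, abs=5e-4)

    def test_vif_of_orthogonal_predictor_is_one(self):
        rng = np.random.default_rng(0)
        n = 200
        dw = pd.DataFrame({
            "dwelling_id": [f"D{i}" for i in range(n)],
            "annual_mean": np.exp(rng.normal(3, 0.3, n)),
        })
        # orthogonal balanced binary designs
        a = np.tile([0, 1], n // 2)
        b = np.repeat([0, 1], n // 2)
        dwellings = pd.DataFrame({
            "dwelling_id": dw["dwelling_id"],
            "mech_ventilation": a.astype(str),
            "double_glazing": b.astype(str),
        })
        fit = fit_linear_exposure_model(
            dw[["dwelling_id", "annual_mean"]], dwellings,
            candidates=("mech_ventilation", "double_glazing"),
        )
        assert fit.vif["mech_ventilation"] == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_design_names_column(self, measured_sample):
        _, dwellings, ann = measured_sample
        dw = dwellings.copy()
        dw["double_glazing"] = dw["mech_ventilation"]  # perfect collinearity
        with pytest.raises(FacohortError, match="collinear"):
            fit_linear_exposure_model(ann, dw,
                                      candidates=("mech_ventilation", "double_glazing"))


class TestLogisticFit:
    def test_intercept_only_5050_split(self):
        n = 60
        rng = np.random.default_rng(3)
        levels = np.concatenate([np.full(n // 2, 10.0), np.full(n // 2, 30.0)])
        ann = pd.DataFrame({"dwelling_id": [f"D{i}" for i in range(n)],
                            "annual_mean": levels + rng.uniform(-0.1, 0.1, n)})
        dwellings = pd.DataFrame({"dwelling_id": ann["dwelling_id"],
                                  "mech_ventilation": "0"})
        # with no informative predictors the fit is intercept + constant col;
        # use a single constant predictor removed by screening: intercept only
        fit = fit_logistic_exposure_model(ann, dwellings, candidates=())
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-6)

    def test_mle_matches_grid_search(self):
        # 8 observations, one binary covariate; oracle = nested grid search
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ann = pd.DataFrame({"dwelling_id": [f"D{i}" for i in range(8)],
                            "annual_mean": np.where(y == 1, 30.0, 10.0)})
        dwellings = pd.DataFrame({"dwelling_id": ann["dwelling_id"],
                                  "mech_ventilation": x.astype(str)})
        fit = fit_logistic_exposure_model(ann, dwellings,
                                          candidates=("mech_ventilation",))

        def nll(a, b):
            eta = a + b * x
            return -(y * eta - np.logaddexp(0, eta)).sum()

        a_grid = np.linspace(-4, 4, 81)
        b_grid = np.linspace(-6, 6, 121)
        for _ in range(4):  # nested refinement
            vals = [(nll(a, b), a, b) for a in a_grid for b in b_grid]
            _, a0, b0 = min(vals)
            a_grid = np.linspace(a0 - (a_grid[1] - a_grid[0]) * 2, a0 + (a_grid[1] - a_grid[0]) * 2, 41)
            b_grid = np.linspace(b0 - (b_grid[1] - b_grid[0]) * 2, b0 + (b_grid[1] - b_grid[0]) * 2, 41)
        assert fit.params["const"] == pytest.approx(a0, abs=1e-3)
        assert fit.params["mech_ventilation"] == pytest.approx(b0, abs=1e-3)

    def test_or_equals_exp_coefficient(self, measured_sample):
        _, dwellings, ann = measured_sample
        fit = fit_logistic_exposure_model(ann, dwellings)
        for term in fit.or_table.index:
            assert fit.or_table.loc[term, "OR"] == pytest.approx(
                np.exp(fit.params[term]), rel=1e-12
            )


class TestMultinomialFit:
    def test_probabilities_sum_to_one_and_null_is_thirds(self):
        rng = np.random.default_rng(8)
        n = 99
        ann = pd.DataFrame({"dwelling_id": [f"D{i}" for i in range(n)],
                            "annual_mean": np.sort(rng.uniform(5, 40, n))})
        dwellings = pd.DataFrame({"dwelling_id": ann["dwelling_id"],
                                  "mech_ventilation": "0"})
        fit = fit_multinomial_tertile_model(ann, dwellings, candidates=())
        # intercept-only: fitted class shares = 1/3 each (balanced tertiles)
        p2, p3 = np.exp(fit.params.loc["const"])
        total = 1 + p2 + p3
        probs = np.array([1, p2, p3]) / total
        assert np.allclose(probs, 1 / 3, atol=1e-6)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_collapsing_upper_classes_matches_binary_fit(self, measured_sample):
        # merging the two upper tertiles and refitting binary on the tertile-1
        # boundary equals a logistic fit at that threshold
        _, dwellings, ann = measured_sample
        t1, _ = exposure_thresholds(ann["annual_mean"])["tertiles"]
        fit_b = fit_logistic_exposure_model(ann, dwellings, threshold=t1,
                                            candidates=("particle_board",))
        y = (ann["annual_mean"] > t1).astype(int)
        assert fit_b.n == len(y)
        assert (fit_b.diagnostics["tp"] + fit_b.diagnostics["fn"]) == int(y.sum())


class TestModelSelection:
    def test_single_candidate_returned(self, measured_sample):
        _, dwellings, ann = measured_sample
        fit = fit_linear_exposure_model(ann, dwellings, candidates=("double_glazing",))
        assert select_model_aic([fit]) is fit

    def test_differing_rows_raise(self, measured_sample):
        _, dwellings, ann = measured_sample
        f1 = fit_linear_exposure_model(ann, dwellings, candidates=("double_glazing",))
        f2 = fit_linear_exposure_model(ann.iloc[:-5], dwellings,
                                       candidates=("double_glazing",))
        with pytest.raises(FacohortError, match="differing"):
            select_model_aic([f1, f2])

    def test_tie_prefers_smaller_model(self, measured_sample):
        _, dwellings, ann = measured_sample
        f1 = fit_linear_exposure_model(ann, dwellings, candidates=("double_glazing",))
        f2 = fit_linear_exposure_model(ann, dwellings,
                                       candidates=("double_glazing", "mech_ventilation"))
        f2.aic = f1.aic  # forced tie
        assert select_model_aic([f2, f1]) is f1

    def test_aic_search_drops_pure_noise_term(self):
        # only particle_board has a real effect; a null extra predictor should
        # usually be dropped by the AIC search
        cfg = SynthConfig(seed=77, missing_season_prob=0.0,
                          exposure_coeffs={"particle_board[ge_1yr]": 0.37,
                                           "particle_board[lt_1yr]": 0.42})
        dwellings = generate_dwellings(500, cfg, seed=77)
        fa = generate_true_fa(dwellings, cfg, seed=77)
        meas = generate_seasonal_measurements(fa, cfg, seed=77)
        ann = annual_means(meas, min_seasons=4)
        best = aic_search(ann, dwellings, ("particle_board", "mech_ventilation"))
        assert "particle_board" in best.predictors


class TestClassification:
    def test_prediction_at_median_is_low(self):
        assert classify_linear_predictions([19.5], 19.5)[0] == "low"
        assert classify_linear_predictions([19.51], 19.5)[0] == "high"

    def test_monotone_transform_preserves_classes(self):
        levels = np.array([5.0, 12.0, 19.5, 22.0, 30.0, 41.0])
        c1 = classify_linear_predictions(levels, 19.5)
        c2 = classify_linear_predictions(levels * 2, 39.0)
        assert (c1 == c2).all()

    def test_fixture_direct_comparison(self):
        levels = [10.0, 14.4, 19.5, 19.6, 26.8, 50.0]
        expected = ["low", "low", "low", "high", "high", "high"]
        assert list(classify_linear_predictions(levels, 19.5)) == expected


@pytest.fixture(scope="module")
def fitted(measured_sample):
    _, dwellings, ann = measured_sample
    fit = fit_linear_exposure_model(ann, dwellings)
    return dwellings, fit


class TestAssignExposure:
    def _subjects(self, history):
        return pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(history))],
                             "residence_history": history})

    def test_single_dwelling_equals_prediction(self, fitted):
        dwellings, fit = fitted
        d0 = dwellings["dwelling_id"].iloc[0]
        subs = self._subjects([[(d0, 1.0)]])
        out = assign_cohort_exposure(subs, dwellings, fit)
        pred = fit.predict_level(dwellings.iloc[[0]]).iloc[0]
        assert out["annual_level"].iloc[0] == pytest.approx(pred, rel=1e-12)

    def test_time_weighted_mean(self, fitted):
        dwellings, fit = fitted
        preds = fit.predict_level(dwellings)
        d0, d1 = dwellings["dwelling_id"].iloc[:2]
        subs = self._subjects([[(d0, 0.5), (d1, 0.5)]])
        out = assign_cohort_exposure(subs, dwellings, fit)
        expected = 0.5 * preds.iloc[0] + 0.5 * preds.iloc[1]
        assert out["annual_level"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_straddling_mover_not_high_all_year(self, fitted):
        dwellings, fit = fitted
        preds = fit.predict_level(dwellings)
        preds.index = dwellings["dwelling_id"]
        cut = fit.thresholds["median"]
        high_d = preds.idxmax()
        low_d = preds.idxmin()
        assert preds[high_d] > cut > preds[low_d]
        subs = self._subjects([[(high_d, 0.9), (low_d, 0.1)]])
        out = assign_cohort_exposure(subs, dwellings, fit)
        assert out["high_all_year"].iloc[0] == 0

    def test_dangling_dwelling_raises_with_subject(self, fitted):
        dwellings, fit = fitted
        subs = self._subjects([[("NOPE", 1.0)]])
        with pytest.raises(SchemaError, match="S0"):
            assign_cohort_exposure(subs, dwellings, fit)
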