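"""Generator behaviour: determinism, marginal calibration, generative moments."""

import numpy as np
import pandas as pd
import pytest

from facohort.config import DEFAULT_PREDICTOR_FREQS, SynthConfig
from facohort.errors import ConfigError
from facohort.exposure import annual_means
from facohort.synth import (
    generate_dwellings,
    generate_outcomes,
    generate_seasonal_measurements,
    generate_subjects,
    generate_true_fa,
    make_cohort,
)


@pytest.fixture(scope="module")
def cfg():
    return SynthConfig(seed=101)


@pytest.fixture(scope="module")
def big_dwellings(cfg):
    return generate_dwellings(10_000, cfg, seed=202)


class TestDwellings:
    def test_single_record_fully_populated(self, cfg):
        df = generate_dwellings(1, cfg, seed=1)
        assert len(df) == 1
        assert not df.isna().any().any()

    def test_determinism(self, cfg):
        a = generate_dwellings(50, cfg, seed=7)
        b = generate_dwellings(50, cfg, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "field,level,freq",
        [
            ("particle_board", "none", 0.334),  # 66.6% have particle board
            ("construction_era", "pre1975", 0.718),
            ("double_glazing", "1", 0.643),
            ("mech_ventilation", "1", 0.245),
        ],
    )
    def test_marginal_frequencies_within_3_se(self, big_dwellings, field, level, freq):
        n = len(big_dwellings)
        observed = (big_dwellings[field] == level).mean()
        se = np.sqrt(freq * (1 - freq) / n)
        assert abs(observed - freq) < 3 * se

    def test_missing_frequency_raises_naming_field(self, cfg):
        bad = SynthConfig(seed=1)
        del bad.predictor_freqs["double_glazing"]
        with pytest.raises(ConfigError, match="double_glazing"):
            generate_dwellings(5, bad, seed=1)


class TestTrueFa:
    def _reference_dwelling(self):
        return pd.DataFrame(
            {
                "dwelling_id": ["D1"],
                "construction_era": ["pre1975"],
                "area_ge_70m2": ["0"],
                "occupants_gt_3": ["0"],
                "wall_coating": ["none"],
                "wood_flooring": ["none"],
                "particle_board": ["none"],
                "mech_ventilation": ["0"],
                "double_glazing": ["0"],
                "season_of_declaration": ["winter"],
                "window_open_hours": [0.0],
            }
        )

    def test_all_reference_no_noise_equals_intercept(self, cfg):
        noiseless = SynthConfig(seed=1, residual_sd=1e-12)
        fa = generate_true_fa(self._reference_dwelling(), noiseless, seed=1)
        assert fa.iloc[0] == pytest.approx(noiseless.exposure_intercept, abs=1e-6)

    def test_double_glazing_effect_is_additive(self):
        noiseless = SynthConfig(seed=1, residual_sd=1e-12)
        base = self._reference_dwelling()
        glazed = base.copy()
        glazed["dwelling_id"] = ["D2"]
        glazed["double_glazing"] = ["1"]
        both = pd.concat([base, glazed], ignore_index=True)
        fa = generate_true_fa(both, noiseless, seed=1)
        assert fa.iloc[1] - fa.iloc[0] == pytest.approx(0.28, abs=1e-9)

    def test_particle_board_multiplies_geometric_mean(self):
        noiseless = SynthConfig(seed=1, residual_sd=1e-12)
        base = self._reference_dwelling()
        pb = base.copy()
        pb["dwelling_id"] = ["D2"]
        pb["particle_board"] = ["lt_1yr"]
        fa = generate_true_fa(pd.concat([base, pb], ignore_index=True), noiseless, seed=1)
        ratio = np.exp(fa.iloc[1]) / np.exp(fa.iloc[0])
        assert ratio == pytest.approx(np.exp(0.42), rel=1e-9)

    def test_residual_sd_recovered_from_moments(self, cfg, big_dwellings):
        fa = generate_true_fa(big_dwellings, cfg, seed=33)
        quiet = SynthConfig(seed=1, residual_sd=1e-12)
        lp = generate_true_fa(big_dwellings, quiet, seed=33)
        lp = lp + (cfg.exposure_intercept - quiet.exposure_intercept)
        resid_sd = np.std(fa.to_numpy() - lp.to_numpy())
        assert resid_sd == pytest.approx(cfg.residual_sd, rel=0.05)

    def test_unknown_level_raises(self, cfg):
        bad = self._reference_dwelling()
        bad["particle_board"] = ["brand_new"]
        with pytest.raises(Exception, match="particle_board"):
            generate_true_fa(bad, cfg, seed=1)


class TestSeasonalMeasurements:
    def test_no_offsets_no_noise_four_identical(self):
        c = SynthConfig(
            seed=1,
            seasonal_offsets={s: 0.0 for s in ("winter", "spring", "summer", "autumn")},
            measurement_noise_sd=0.0,
            missing_season_prob=0.0,
        )
        fa = pd.Series([np.log(19.5)], index=pd.Index(["D1"], name="dwelling_id"))
        meas = generate_seasonal_measurements(fa, c, seed=2)
        assert len(meas) == 4
        assert np.allclose(meas["fa_level"], 19.5, atol=0.001)

    def test_season_ratio_closed_form(self):
        offs = {"winter": -0.1, "spring": -0.05, "summer": 0.2, "autumn": -0.05}
        c = SynthConfig(seed=1, seasonal_offsets=offs, measurement_noise_sd=0.0,
                        missing_season_prob=0.0)
        fa = pd.Series([3.0], index=pd.Index(["D1"], name="dwelling_id"))
        meas = generate_seasonal_measurements(fa, c, seed=2).set_index("season")
        ratio = meas.loc["summer", "fa_level"] / meas.loc["winter", "fa_level"]
        assert ratio == pytest.approx(np.exp(0.2 - (-0.1)), rel=1e-3)

    def test_per_season_mean_recovers_offset(self, cfg):
        c = SynthConfig(seed=1, missing_season_prob=0.0)
        fa = pd.Series(np.full(4000, 3.0),
                       index=pd.Index([f"D{i}" for i in range(4000)], name="dwelling_id"))
        meas = generate_seasonal_measurements(fa, c, seed=5)
        for season, off in c.seasonal_offsets.items():
            mean_log = np.log(meas[meas["season"] == season]["fa_level"]).mean()
            assert mean_log - 3.0 == pytest.approx(off, abs=0.02)


class TestOutcomes:
    def test_null_model_gives_equal_thirds(self, cfg):
        subs, _ = generate_subjects(SynthConfig(seed=4, n_subjects=30_000,
                                                n_measured_dwellings=10), seed=4)
        null = SynthConfig(
            seed=4,
            outcome_logits={
                "non_wLRI": {"intercept": 0.0},
                "wLRI": {"intercept": 0.0},
            },
            fa_effect_per_unit={"non_wLRI": 0.0, "wLRI": 0.0},
        )
        expo = pd.Series(20.0, index=pd.Index(subs["subject_id"]))
        out = generate_outcomes(subs, expo, null, seed=4)
        shares = out["outcome"].value_counts(normalize=True)
        for share in shares:
            assert share == pytest.approx(1 / 3, abs=0.01)

    def test_incidence_calibration(self):
        cfg = SynthConfig(seed=9, n_subjects=20_000, n_measured_dwellings=100)
        _, _, subjects, _ = make_cohort(cfg)
        lri = (subjects["outcome"] != "never_LRI").mean()
        wlri = (subjects["outcome"] == "wLRI").mean()
        se = np.sqrt(0.458 * 0.542 / 20_000)
        assert abs(lri - 0.458) < 3 * se
        se_w = np.sqrt(0.223 * 0.777 / 20_000)
        assert abs(wlri - 0.223) < 3 * se_w

    def test_fa_effect_changes_only_outcome_stream(self):
        base = SynthConfig(seed=17, n_subjects=500, n_measured_dwellings=50)
        doubled = SynthConfig(seed=17, n_subjects=500, n_measured_dwellings=50,
                              fa_effect_per_unit={k: 2 * v for k, v in
                                                  base.fa_effect_per_unit.items()})
        d1, m1, s1, _ = make_cohort(base)
        d2, m2, s2, _ = make_cohort(doubled)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(m1, m2)
        cov_cols = [c for c in s1.columns if c != "outcome"]
        pd.testing.assert_frame_equal(s1[cov_cols], s2[cov_cols])
        assert (s1["outcome"] != s2["outcome"]).any()


class TestCohortStructure:
    def test_residence_fractions_sum_to_one(self, small_cohort):
        _, _, subjects, _ = small_cohort
        for hist in subjects["residence_history"]:
            assert sum(f for _, f in hist) == pytest.approx(1.0, abs=1e-6)

    def test_mover_fraction_matches_config(self):
        cfg = SynthConfig(seed=23, n_subjects=10_000, n_measured_dwellings=100)
        subs, _ = generate_subjects(cfg, seed=23)
        movers = subs["residence_history"].map(len).gt(1).mean()
        se = np.sqrt(0.103 * 0.897 / 10_000)
        assert abs(movers - 0.103) < 3 * se

    def test_measured_subsample_size_and_coverage(self, small_cohort, small_config):
        dwellings, measurements, subjects, _ = small_cohort
        assert subjects["measured"].sum() == small_config.n_measured_dwellings
        measured_d = {
            d
            for hist, flag in zip(subjects["residence_history"], subjects["measured"])
            if flag
            for d, _ in hist
        }
        assert set(measurements["dwelling_id"]) <= measured_d

    def test_annual_level_defined_for_most_measured_dwellings(self, small_cohort):
        # with ~15% seasonal missingness and a >=3-season rule, most but not
        # all measured dwellings keep a defined annual level
        _, measurements, _, _ = small_cohort
        ann = annual_means(measurements, min_seasons=3)
        n_meas = measurements["dwelling_id"].nunique()
        assert 0.75 * n_meas <= len(ann) < n_meas

    def test_seasonal_offsets_must_average_zero(self):
        with pytest.raises(ConfigError, match="average"):
            SynthConfig(seasonal_offsets={"winter": 0.1, "spring": 0.0,
                                          "summer": 0.0, "autumn": 0.0})
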