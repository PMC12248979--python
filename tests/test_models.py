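"""Mixed models: standardization, fitting, bootstrap, BIC selection, subsets."""

import numpy as np
import pandas as pd
import pytest

from fixfill.models import (
    ModelSpec,
    back_transform,
    case_bootstrap,
    cortical_distance,
    fit_lmm,
    predict_fixed,
    primary_ft_spec,
    ms_rate_spec,
    select_terms_by_bic,
    standardize_predictors,
    subset_models,
)
from fixfill.synth import simulate_outcome


def sim_design(rng, n_participants=8, trials=40):
    rows = []
    for p in range(n_participants):
        for _ in range(trials):
            rows.append((f"p{p:02d}", rng.choice([10, 20, 30]),
                         rng.choice([2.0, 4.0, 6.0]), rng.integers(1, 41),
                         max(0.05, rng.normal(0.75, 0.15))))
    return pd.DataFrame(rows, columns=["participant", "contrast", "eccentricity",
                                       "trial_num", "ocular_drift"])


class TestStandardize:
    def test_balanced_three_level_zscores(self):
        df = pd.DataFrame({"eccentricity": [2.0, 4.0, 6.0] * 10})
        out, scalers = standardize_predictors(df)
        assert sorted(set(np.round(out["eccentricity"], 4))) == [-1.2247, 0.0, 1.2247]
        assert scalers["eccentricity"][0] == pytest.approx(4.0)

    def test_binary_left_untouched(self):
        df = pd.DataFrame({"contrast": [10.0, 30.0] * 5, "ms_presence": [0, 1] * 5})
        out, scalers = standardize_predictors(df, ["contrast", "ms_presence"])
        assert set(out["ms_presence"]) == {0, 1}
        assert "ms_presence" not in scalers

    def test_constant_predictor_rejected_by_name(self):
        df = pd.DataFrame({"contrast": [10.0] * 5})
        with pytest.raises(ValueError, match="contrast"):
            standardize_predictors(df)


class TestModelSpec:
    def test_interaction_without_parent_rejected(self):
        with pytest.raises(ValueError, match="lacks main effect"):
            ModelSpec("log_ft", ("contrast", "contrast:eccentricity"))

    def test_random_slope_needs_fixed_main(self):
        with pytest.raises(ValueError, match="random slopes"):
            ModelSpec("log_ft", ("contrast",), ("eccentricity",))


class TestFitLMM:
    def test_intercept_only_on_near_constant_response(self, rng):
        df = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(4)], 20),
            "log_ft": 1.7 + rng.normal(0, 1e-4, 80),
        })
        fit = fit_lmm(ModelSpec("log_ft", ()), df)
        assert fit.estimates["intercept"] == pytest.approx(1.7, abs=1e-3)

    def test_noiseless_recovery_is_exact(self, rng):
        design, _ = standardize_predictors(sim_design(rng))
        coefs = {"intercept": 0.5, "contrast": 0.156, "eccentricity": -0.0876,
                 "trial_num": -0.101, "ocular_drift": 0.104}
        design["log_ft"] = simulate_outcome(design, coefs, {"intercept": 0.0}, 0.0, rng)
        fit = fit_lmm(ModelSpec("log_ft", tuple(t for t in coefs if t != "intercept")), design)
        for t, b in coefs.items():
            assert fit.estimates[t] == pytest.approx(b, abs=1e-6)

    def test_random_intercept_recovery_within_mc_error(self, rng):
        design, _ = standardize_predictors(sim_design(rng, 12, 60))
        coefs = {"intercept": 0.3, "contrast": 0.2, "eccentricity": -0.1,
                 "trial_num": -0.05, "ocular_drift": 0.1}
        design["log_ft"] = simulate_outcome(design, coefs, {"intercept": 0.25}, 0.3, rng)
        fit = fit_lmm(ModelSpec("log_ft", tuple(t for t in coefs if t != "intercept")), design)
        se = 0.3 / np.sqrt(len(design))
        for t in ("contrast", "eccentricity", "trial_num"):
            assert abs(fit.estimates[t] - coefs[t]) < 4 * se
        assert 0.1 < fit.random_sd["intercept"] < 0.45
        assert fit.converged

    def test_fewer_than_two_participants_rejected(self):
        df = pd.DataFrame({"participant": ["a"] * 10, "log_ft": np.ones(10)})
        with pytest.raises(ValueError, match="participants"):
            fit_lmm(ModelSpec("log_ft", ()), df)

    def test_missing_columns_named(self, rng):
        df = sim_design(rng)
        with pytest.raises(ValueError, match="log_ft"):
            fit_lmm(ModelSpec("log_ft", ("contrast",)), df)


class TestBackTransform:
    def test_predictions_match_to_1e8(self, rng):
        raw = sim_design(rng)
        raw["ms_presence"] = rng.integers(0, 2, len(raw))
        std, scalers = standardize_predictors(raw)
        coefs = {"intercept": 0.3, "contrast": 0.1, "eccentricity": -0.05,
                 "ms_presence": 0.3, "contrast:eccentricity": 0.02,
                 "ms_presence:eccentricity": -0.07}
        spec_terms = tuple(t for t in coefs if t != "intercept")
        std["log_ft"] = simulate_outcome(std, coefs, {"intercept": 0.1}, 0.2, rng)
        fit = fit_lmm(ModelSpec("log_ft", spec_terms), std)
        raw_coefs = back_transform(fit.estimates, scalers)
        np.testing.assert_allclose(
            predict_fixed(raw_coefs, raw), predict_fixed(fit.estimates, std),
            atol=1e-8)


@pytest.fixture(scope="module")
def boot():
    rng = np.random.default_rng(5)
    design, _ = standardize_predictors(sim_design(rng, 8, 15))
    design["log_ft"] = simulate_outcome(
        design, {"intercept": 0.3, "contrast": 0.25, "eccentricity": 0.0},
        {"intercept": 0.2}, 0.3, rng)
    spec = ModelSpec("log_ft", ("contrast", "eccentricity"))
    return case_bootstrap(spec, design, n_boot=80, alpha=0.05, seed=1), spec, design


class TestCaseBootstrap:

    def test_bonferroni_level(self, boot):
        bs, _, _ = boot
        assert bs.alpha_corrected == pytest.approx(0.05 / 2)

    def test_intervals_widen_as_alpha_shrinks(self, boot):
        """On the same resamples, a stricter level gives wider intervals."""
        bs, _, _ = boot
        wide = bs.ci_at(0.005)
        narrow = bs.ci_at(0.05)
        for t in bs.terms:
            assert wide[t][0] <= narrow[t][0] and wide[t][1] >= narrow[t][1]

    def test_strong_effect_significant_null_effect_not(self, boot):
        bs, _, _ = boot
        assert bs.significant["contrast"]
        assert not bs.significant["eccentricity"]

    def test_reproducible_under_seed(self, boot):
        bs, spec, design = boot
        again = case_bootstrap(spec, design, n_boot=80, alpha=0.05, seed=1)
        np.testing.assert_array_equal(bs.samples, again.samples)

    def test_primary_spec_correction_uses_ten_terms(self):
        assert len([t for t in primary_ft_spec().fixed_terms]) == 10
        assert len(ms_rate_spec().fixed_terms) == 3  # 0.05/3 -> 98.33% CIs


class TestSelectTermsByBIC:
    def test_strong_kept_noise_removed(self, rng):
        design, _ = standardize_predictors(sim_design(rng, 10, 80))
        design["log_ft"] = simulate_outcome(
            design, {"intercept": 0.3, "contrast": 0.3, "eccentricity": 0.0},
            {"intercept": 0.15}, 0.3, rng)
        spec = ModelSpec("log_ft", ("contrast", "eccentricity"))
        pruned = select_terms_by_bic(spec, design)
        assert "contrast" in pruned.fixed_terms
        assert "eccentricity" not in pruned.fixed_terms

    def test_empty_candidates_is_identity(self, rng):
        design, _ = standardize_predictors(sim_design(rng, 6, 20))
        design["log_ft"] = simulate_outcome(
            design, {"intercept": 0.3, "contrast": 0.2}, {"intercept": 0.1}, 0.3, rng)
        spec = ModelSpec("log_ft", ("contrast",))
        assert select_terms_by_bic(spec, design, candidates=()) == spec

    def test_parent_of_retained_interaction_never_removed(self, rng):
        design, _ = standardize_predictors(sim_design(rng, 10, 60))
        coefs = {"intercept": 0.3, "contrast": 0.0, "eccentricity": 0.2,
                 "contrast:eccentricity": 0.3}
        design["log_ft"] = simulate_outcome(design, coefs, {"intercept": 0.1}, 0.3, rng)
        spec = ModelSpec("log_ft", ("contrast", "eccentricity", "contrast:eccentricity"))
        pruned = select_terms_by_bic(spec, design, candidates=("contrast",))
        assert "contrast" in pruned.fixed_terms


class TestSubsetModels:
    @pytest.fixture
    def metrics_df(self, rng):
        df = sim_design(rng, 6, 60)
        df["ms_presence"] = rng.random(len(df)) < 0.6
        df["num_blinks"] = rng.poisson(0.3, len(df))
        df["log_ft"] = rng.normal(2.0, 0.3, len(df))
        return df

    def test_balanced_counts_per_participant(self, metrics_df):
        out = subset_models(metrics_df, seed=0)
        ms_df, no_df = out["tables"]
        a = ms_df.groupby("participant").size()
        b = no_df.groupby("participant").size()
        assert (a == b.reindex(a.index)).all()

    def test_smaller_subset_untouched(self, metrics_df):
        free = metrics_df[metrics_df["num_blinks"] == 0]
        out = subset_models(metrics_df, seed=0)
        ms_df, no_df = out["tables"]
        for pid, grp in free.groupby("participant"):
            smaller_is_no = (~grp["ms_presence"]).sum() <= grp["ms_presence"].sum()
            small = no_df if smaller_is_no else ms_df
            want = grp[~grp["ms_presence"]] if smaller_is_no else grp[grp["ms_presence"]]
            got = small[small["participant"] == pid]
            assert len(got) == len(want)

    def test_seed_determinism(self, metrics_df):
        a = subset_models(metrics_df, seed=3)
        b = subset_models(metrics_df, seed=3)
        pd.testing.assert_frame_equal(a["tables"][0], b["tables"][0])

    def test_participant_with_empty_subset_dropped(self, metrics_df):
        df = metrics_df.copy()
        mask = df["participant"] == "p00"
        df.loc[mask, "ms_presence"] = True  # p00 has no microsaccade-free trials
        out = subset_models(df, seed=0)
        assert "p00" in out["dropped"]
        assert "p00" not in set(out["tables"][0]["participant"])


class TestCorticalDistance:
    def test_reference_eccentricity_maps_near_zero(self):
        assert abs(cortical_distance(10.0)) < 0.05

    def test_strictly_increasing(self):
        E = np.linspace(0.5, 12, 50)
        assert np.all(np.diff(cortical_distance(E)) > 0)

    def test_printed_design_levels(self):
        d = cortical_distance(np.array([2.0, 4.0, 6.0]))
        assert d[0] < d[1] < d[2] < 0  # all central to the 10-deg reference

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cortical_distance(0.0)
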