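import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from evorepeat import DesignSpec, ExperimentTable, fit_lmm, generate_experiment, pairwise_contrasts
from evorepeat.mixed_model import DesignError, _design_frame


class TestFit:
    def test_noise_free_data_recovers_cell_contrasts_exactly(self, noiseless_spec):
        spec = DesignSpec(
            treatments=("no", "moderate", "strong"),
            replicates_per_treatment=3,
            mu0=7.0,
            beta_week=2.0,
            beta_treatment={"no": 0.0, "moderate": -1.3, "strong": 0.8},
            beta_interaction={"no": 0.0, "moderate": 0.9, "strong": -0.9},
            sigma_replicate=0.0,
            sigma_response=0.0,
            sigma_day=0.0,
            sigma_error=0.0,
            seed=0,
        )
        fit = fit_lmm(generate_experiment(spec))
        est = {k: v["estimate"] for k, v in fit.fixed_effects.items()}
        assert est["intercept"] == pytest.approx(7.0, abs=1e-8)
        assert est["week15"] == pytest.approx(2.0, abs=1e-8)
        assert est["trt[moderate]"] == pytest.approx(-1.3, abs=1e-8)
        assert est["trt[strong]"] == pytest.approx(0.8, abs=1e-8)
        assert est["week15:trt[moderate]"] == pytest.approx(0.9, abs=1e-8)
        assert est["week15:trt[strong]"] == pytest.approx(-0.9, abs=1e-8)
        assert fit.variance_components["replicate"] == 0.0
        assert fit.variance_components["assessment_day"] == 0.0
        assert fit.variance_components["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_single_random_effect_reml_matches_ems_closed_form(self):
        # Balanced 2x4x2x3 design with only a replicate random intercept:
        # REML variance components must equal the expected-mean-squares
        # (ANOVA method-of-moments) estimator.
        spec = DesignSpec(
            treatments=("no", "moderate"),
            replicates_per_treatment=4,
            tech_per_day=3,
            sigma_replicate=0.7,
            sigma_response=0.0,
            sigma_day=0.0,
            sigma_error=0.4,
            seed=2,
        )
        table = generate_experiment(spec)
        fit = fit_lmm(table, random_effects=("replicate",))

        df = table.with_log_size()
        T, R, W, n = 2, 4, 2, 3
        N = T * R * W * n
        repm = df.groupby(["treatment", "replicate"])["log_size"].mean().reset_index(name="rm")
        trtm = df.groupby("treatment")["log_size"].mean().reset_index(name="tm")
        mm = repm.merge(trtm, on="treatment")
        ms_rep = W * n * ((mm["rm"] - mm["tm"]) ** 2).sum() / (T * (R - 1))
        cellm = df.groupby(["treatment", "week"])["log_size"].transform("mean")
        repdev = df.merge(mm, on=["treatment", "replicate"])
        resid = df["log_size"].to_numpy() - cellm.to_numpy() - (
            repdev["rm"] - repdev["tm"]
        ).to_numpy()
        ms_res = (resid**2).sum() / (N - T * W - T * (R - 1))

        assert fit.variance_components["residual"] == pytest.approx(ms_res, abs=1e-6)
        assert fit.variance_components["replicate"] == pytest.approx(
            (ms_rep - ms_res) / (W * n), abs=1e-6
        )

    def test_parameter_recovery_on_noisy_tables(self, small_noisy_table):
        fit = fit_lmm(small_noisy_table)
        # generating week-15 effect is 2.2; a single fit should land well
        # within a few SE of it
        w = fit.fixed_effects["week15"]
        assert abs(w["estimate"] - 2.2) < 4 * w["SE"]
        assert all(v >= 0 for v in fit.variance_components.values())
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_missing_week_is_design_error(self, small_noisy_table):
        df = small_noisy_table.data
        broken = ExperimentTable(
            df[~((df.treatment == "strong") & (df.week == 15))].reset_index(drop=True)
        )
        with pytest.raises(DesignError):
            fit_lmm(broken)

    def test_single_treatment_is_design_error(self, small_noisy_table):
        df = small_noisy_table.data
        one = ExperimentTable(df[df.treatment == "no"].reset_index(drop=True))
        with pytest.raises(DesignError):
            fit_lmm(one)

    def test_adding_constant_shifts_only_intercept(self, small_noisy_table):
        fit0 = fit_lmm(small_noisy_table)
        shifted = small_noisy_table.data.copy()
        shifted["population_size"] = shifted["population_size"] * np.e**2  # +2 log units
        fit1 = fit_lmm(ExperimentTable(shifted))
        for term in fit0.fixed_effects:
            d0 = fit0.fixed_effects[term]["estimate"]
            d1 = fit1.fixed_effects[term]["estimate"]
            expected = d0 + 2.0 if term == "intercept" else d0
            assert d1 == pytest.approx(expected, abs=1e-5)

    def test_forced_zero_variance_equals_ols(self, small_noisy_table):
        fit = fit_lmm(small_noisy_table, method="ols")
        df, _, terms = _design_frame(small_noisy_table)
        ols = sm.OLS(df["log_size"].to_numpy(), df[terms].to_numpy()).fit()
        for i, term in enumerate(terms):
            assert fit.fixed_effects[term]["estimate"] == pytest.approx(ols.params[i], abs=1e-10)
        assert fit.variance_components["replicate"] == 0.0


class TestContrasts:
    def test_noise_free_within_treatment_contrasts(self, noiseless_spec):
        fit = fit_lmm(generate_experiment(noiseless_spec))
        contrasts = pairwise_contrasts(fit, "within_treatment_between_weeks")
        assert len(contrasts) == 2
        for c in contrasts:  # week 0 minus week 15 = -2 log units everywhere
            assert c.estimate == pytest.approx(-2.0, abs=1e-8)

    def test_tukey_adjustment_never_shrinks_p(self, small_noisy_table):
        fit = fit_lmm(small_noisy_table)
        for family in ("within_treatment_between_weeks", "within_week_between_treatments"):
            for c in pairwise_contrasts(fit, family):
                assert c.adjusted_p >= c.p_unadjusted - 1e-12
                assert 0 <= c.adjusted_p <= 1

    def test_contrast_families_have_expected_sizes(self, small_noisy_table):
        fit = fit_lmm(small_noisy_table)
        within_trt = pairwise_contrasts(fit, "within_treatment_between_weeks")
        within_week = pairwise_contrasts(fit, "within_week_between_treatments")
        assert len(within_trt) == 3
        assert len(within_week) == 6  # 3 pairs x 2 weeks
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, "bogus_family")

    def test_contrasts_invariant_to_reference_relabeling(self):
        # same data under two label schemes whose sort order flips the
        # reference level; the week-0 between-treatment difference must
        # only change sign with the label swap
        spec = DesignSpec(
            treatments=("no", "moderate"),
            replicates_per_treatment=3,
            sigma_replicate=0.2,
            sigma_response=0.1,
            sigma_day=0.1,
            sigma_error=0.3,
            seed=9,
        )
        table = generate_experiment(spec)

        def relabel(df, mapping):
            out = df.copy()
            out["treatment"] = out["treatment"].map(mapping)
            return ExperimentTable(out)

        fit_ab = fit_lmm(relabel(table.data, {"no": "alpha", "moderate": "beta"}))
        fit_ba = fit_lmm(relabel(table.data, {"no": "beta", "moderate": "alpha"}))
        c_ab = {c.label: c for c in pairwise_contrasts(fit_ab, "within_week_between_treatments")}
        c_ba = {c.label: c for c in pairwise_contrasts(fit_ba, "within_week_between_treatments")}
        # alpha-beta in scheme 1 is the "no"-"moderate" difference; in
        # scheme 2 alpha is "moderate", so the same label is its negative
        assert c_ab["week 0 (alpha - beta)"].estimate == pytest.approx(
            -c_ba["week 0 (alpha - beta)"].estimate, abs=1e-4
        )

    def test_week15_estimate_matches_cell_mean_difference(self, small_noisy_table):
        fit = fit_lmm(small_noisy_table)
        c = pairwise_contrasts(fit, "within_treatment_between_weeks")[0]
        assert c.estimate == pytest.approx(
            fit.cell_mean("no", 0) - fit.cell_mean("no", 15), abs=1e-10
        )
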