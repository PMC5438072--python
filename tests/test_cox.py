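"""Cox engine checks against independent oracles: brute-force partial
likelihood, hand Breslow calculations, parametric simulations and lifelines."""

import numpy as np
import pandas as pd
import pytest

from kinsurv import fit_cox, km_life_years, martingale_residuals, truncate_age_window
from kinsurv.cox import per_allele_years
from kinsurv.errors import ConsistencyError, DegenerateDataError, InvalidParameterError


def _grid_search_loglik(df, betas):
    """Brute-force Breslow log partial likelihood for one covariate."""
    t = df["observed_age"].to_numpy()
    d = df["event"].to_numpy()
    x = df["covariate_1"].to_numpy()
    lls = []
    for b in betas:
        ll = 0.0
        for i in np.flatnonzero(d):
            risk = t >= t[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        lls.append(ll)
    return np.asarray(lls)


class TestFitCox:
    def test_matches_brute_force_grid_search(self, six_record_cox):
        betas = np.arange(-5, 5, 1e-4)
        oracle = betas[np.argmax(_grid_search_loglik(six_record_cox, betas))]
        fit = fit_cox(six_record_cox, entry_age=40)
        assert abs(float(fit.params.iloc[0]) - oracle) <= 1e-3

    def test_null_covariate_gives_nelson_aalen_baseline(self, six_record_cox):
        df = six_record_cox.assign(covariate_1=0.0)
        fit = fit_cox(df, entry_age=40)
        assert float(fit.params.iloc[0]) == 0.0
        # Nelson-Aalen by hand: deaths at 41,46,50,55 with 6,4,3,1 at risk
        expected = np.cumsum([1 / 6, 1 / 4, 1 / 3, 1 / 1])
        np.testing.assert_allclose(fit.baseline["cumhaz"].to_numpy(), expected, rtol=1e-12)

    def test_two_group_exponential_recovers_hr2(self):
        rng = np.random.default_rng(20)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * 2**x))
        c = rng.uniform(0, 30, n)
        df = pd.DataFrame(
            {
                "observed_age": 40 + np.minimum(t, c),
                "event": (t <= c).astype(int),
                "covariate_1": x,
            }
        )
        fit = fit_cox(df, entry_age=40)
        beta, se = float(fit.params.iloc[0]), float(fit.se.iloc[0])
        assert abs(beta - np.log(2)) < 3 * se

    def test_agrees_with_lifelines(self):
        """Independent implementation cross-check (estimates and s.e.)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        n = 1500
        Z = rng.standard_normal((n, 2))
        t = rng.exponential(1.0 / (0.05 * np.exp(Z @ [0.4, -0.3])))
        c = rng.uniform(0, 40, n)
        df = pd.DataFrame(Z, columns=["covariate_1", "covariate_2"])
        df["observed_age"] = 40 + np.minimum(t, c)
        df["event"] = (t <= c).astype(int)
        fit = fit_cox(df, entry_age=40)
        ldf = df.assign(T=df["observed_age"] - 40).drop(columns="observed_age")
        cph = CoxPHFitter().fit(ldf, duration_col="T", event_col="event")
        np.testing.assert_allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_ties_efron_vs_breslow_differ_on_tied_data(self):
        df = pd.DataFrame(
            {
                "observed_age": [42, 42, 42, 45, 45, 50, 52, 53],
                "event": [1, 1, 0, 1, 1, 1, 0, 1],
                "covariate_1": [1.0, 0, 1, 0, 1, 0, 1, 0],
            }
        )
        b_efron = float(fit_cox(df, ties="efron").params.iloc[0])
        b_breslow = float(fit_cox(df, ties="breslow").params.iloc[0])
        assert b_efron != b_breslow  # tie corrections genuinely applied

    def test_no_events_is_degenerate(self, six_record_cox):
        with pytest.raises(DegenerateDataError):
            fit_cox(six_record_cox.assign(event=0))


class TestMartingaleResiduals:
    def test_single_death_hand_breslow(self):
        df = pd.DataFrame({"observed_age": [41.0, 42, 43, 44], "event": [1, 0, 0, 0]})
        fit = fit_cox(df, covariates=[], entry_age=40)
        resid = martingale_residuals(fit, df)
        np.testing.assert_allclose(resid, [1 - 1 / 4, -1 / 4, -1 / 4, -1 / 4], rtol=1e-12)

    def test_sum_identity_and_upper_bound(self, six_record_cox, small_cohort):
        fit = fit_cox(six_record_cox)
        resid = martingale_residuals(fit, six_record_cox)
        assert abs(resid.sum()) < 1e-8
        assert np.all(resid <= 1.0)

        _, pheno, _, _ = small_cohort
        from kinsurv import apply_exclusions

        clean, _ = apply_exclusions(pheno)
        fathers = clean[clean["parent_sex"] == "father"].reset_index(drop=True)
        fit2 = fit_cox(fathers)
        resid2 = martingale_residuals(fit2, fathers)
        assert abs(resid2.sum()) < 1e-8
        assert np.all(resid2 <= 1.0)

    def test_record_mismatch_rejected(self, six_record_cox):
        fit = fit_cox(six_record_cox)
        with pytest.raises(ConsistencyError):
            martingale_residuals(fit, six_record_cox.iloc[:4])


class TestKaplanMeierLifeYears:
    def test_no_censoring_reduces_to_mean(self):
        ages = np.array([55.0, 62.0, 71.0, 80.0, 91.0])
        df = pd.DataFrame({"observed_age": ages, "event": 1})
        ly = km_life_years(df, np.zeros(len(df)), horizon=85.0)
        expected = np.minimum(ages, 85.0).mean()
        assert ly["expected_age"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_all_censored_gives_horizon(self):
        df = pd.DataFrame({"observed_age": [70.0, 75.0, 80.0], "event": 0})
        ly = km_life_years(df, np.zeros(3), horizon=80.0)
        assert ly["expected_age"].iloc[0] == pytest.approx(80.0)

    def test_null_genotype_classes_have_similar_lifespans(self, small_cohort):
        _, pheno, geno, _ = small_cohort
        from kinsurv import apply_exclusions

        clean, _ = apply_exclusions(pheno)
        mothers = clean[clean["parent_sex"] == "mother"].reset_index(drop=True)
        dosage = np.rint(geno.subset_subjects(mothers["subject_id"].to_numpy()).dosages[1])
        ly = km_life_years(mothers, dosage)  # variant 2 is null by construction
        assert abs(per_allele_years(ly)) < 1.0

    def test_added_hazard_lowers_restricted_mean(self):
        rng = np.random.default_rng(22)
        base = 40 + rng.exponential(25, 4000)
        worse = 40 + rng.exponential(18, 4000)
        df = pd.DataFrame(
            {
                "observed_age": np.concatenate([base, worse]),
                "event": 1,
            }
        )
        ly = km_life_years(df, np.repeat([0, 1], 4000), horizon=95.0)
        assert ly["expected_age"].iloc[1] < ly["expected_age"].iloc[0]


class TestAgeWindows:
    def test_death_after_75_becomes_survivor_in_early_window(self):
        df = pd.DataFrame({"observed_age": [80.0], "event": [1]})
        out = truncate_age_window(df, "40-75")
        assert out["observed_age"].iloc[0] == 75.0 and out["event"].iloc[0] == 0

    def test_early_death_excluded_from_late_window(self):
        df = pd.DataFrame({"observed_age": [60.0, 80.0], "event": [1, 1]})
        out = truncate_age_window(df, "75+")
        assert list(out["observed_age"]) == [80.0]

    def test_early_death_unchanged_in_early_window(self):
        df = pd.DataFrame({"observed_age": [74.5], "event": [1]})
        out = truncate_age_window(df, "40-75")
        assert out["observed_age"].iloc[0] == 74.5 and out["event"].iloc[0] == 1

    def test_unknown_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            truncate_age_window(pd.DataFrame({"observed_age": [70.0], "event": [1]}), "90+")
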