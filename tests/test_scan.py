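"""Residual-scan checks: Blom transform, per-variant regression, conditional
scan, genomic inflation and variance explained."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from kinsurv import (
    GenotypeMatrix,
    ScanCalibration,
    conditional_scan,
    correlated_proxy,
    genomic_inflation,
    rank_normal,
    scan_variants,
    variance_explained,
)
from kinsurv.errors import ConfigurationError, DegenerateDataError, InvalidParameterError


def _matrix(dosages, freqs=None):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    m = dosages.shape[0]
    variants = pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1),
            "effect_allele": ["A"] * m,
            "freq": freqs if freqs is not None else [np.nan] * m,
        }
    )
    subjects = np.array([f"s{j}" for j in range(dosages.shape[1])])
    return GenotypeMatrix(dosages, subjects, variants)


class TestRankNormal:
    def test_two_values_blom_closed_form(self):
        c = stats.norm.ppf((2 - 0.375) / 2.25)
        np.testing.assert_allclose(rank_normal([1.0, 5.0]), [-c, c], rtol=1e-12)

    def test_scores_sum_to_zero_without_ties(self):
        rng = np.random.default_rng(0)
        scores = rank_normal(rng.standard_normal(501))
        assert abs(scores.sum()) < 1e-9

    def test_ties_share_average_rank(self):
        scores = rank_normal([1.0, 2.0, 2.0, 3.0])
        assert scores[1] == scores[2]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60, unique=True))
    def test_monotone(self, values):
        scores = rank_normal(np.array(values))
        order = np.argsort(values)
        assert np.all(np.diff(scores[order]) >= 0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            rank_normal([3.0, 3.0, 3.0])


class TestScanVariants:
    def test_perfect_association(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 200).astype(float)
        gm = _matrix([x])
        scores = (x - x.mean()) / x.std()
        out = scan_variants(scores, gm)
        assert out["R2"].iloc[0] == pytest.approx(1.0)
        assert out["P"].iloc[0] < 1e-100

    def test_null_type_one_error_in_binomial_band(self):
        rng = np.random.default_rng(2)
        n, m = 20_000, 500
        G = rng.binomial(2, 0.3, size=(m, n)).astype(float)
        scores = rng.standard_normal(n)
        out = scan_variants(scores, _matrix(G))
        rate = (out["P"] < 0.05).mean()
        assert 0.032 <= rate <= 0.068

    def test_effect_recovery_with_and_without_calibration(self):
        rng = np.random.default_rng(3)
        n = 50_000
        x = rng.binomial(2, 0.3, n).astype(float)
        scores = 0.1 * x + rng.standard_normal(n)
        out = scan_variants(scores, _matrix([x]))
        assert abs(out["BETA_OFF"].iloc[0] - 0.1) < 3 * out["SE_OFF"].iloc[0]
        # calibration is a pure rescaling of estimate and s.e.
        calib = ScanCalibration(sigma=0.8, n=n, n_events=n // 2)
        out2 = scan_variants(scores, _matrix([x]), calibration=calib)
        assert out2["BETA_OFF"].iloc[0] == pytest.approx(out["BETA_OFF"].iloc[0] * calib.kappa)
        assert out2["P"].iloc[0] == pytest.approx(out["P"].iloc[0])

    def test_parent_scale_doubling_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(2, 0.4, 500).astype(float)
        out = scan_variants(rng.standard_normal(500), _matrix([x]))
        assert out["BETA_PARENT"].iloc[0] == pytest.approx(2 * out["BETA_OFF"].iloc[0])
        assert out["SE_PARENT"].iloc[0] == pytest.approx(2 * out["SE_OFF"].iloc[0])

    def test_monomorphic_variant_flagged_not_raised(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.4, 100).astype(float)
        out = scan_variants(rng.standard_normal(100), _matrix([x, np.ones(100)]))
        assert out["NOTE"].iloc[1] == "monomorphic"
        assert np.isnan(out["P"].iloc[1])
        assert len(out) == 2  # row count preserved

    def test_high_missingness_dropped_low_missingness_imputed(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.4, 1000).astype(float)
        x_low = x.copy()
        x_low[:20] = np.nan  # 2% missing
        x_high = x.copy()
        x_high[:200] = np.nan  # 20% missing
        out = scan_variants(rng.standard_normal(1000), _matrix([x_low, x_high]))
        assert out["NOTE"].iloc[0] == "" and np.isfinite(out["P"].iloc[0])
        assert out["NOTE"].iloc[1] == "high_missingness"

    def test_pvalues_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.3, size=(5, 300)).astype(float)
        scores = rng.standard_normal(300)
        out1 = scan_variants(scores, _matrix(G))
        perm = rng.permutation(300)
        out2 = scan_variants(scores[perm], _matrix(G[:, perm]))
        np.testing.assert_allclose(out1["P"], out2["P"], rtol=1e-9)


class TestConditionalScan:
    def test_sentinel_against_itself_is_na(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.3, 400).astype(float)
        gm = _matrix([x], freqs=[0.3])
        out = conditional_scan(rng.standard_normal(400), gm, ["v0"])
        assert out["NOTE"].iloc[0] == "collinear_with_sentinel"
        assert np.isnan(out["P"].iloc[0])

    def test_correlated_proxy_signal_removed_by_conditioning(self):
        rng = np.random.default_rng(9)
        uncond_p, cond_p = [], []
        for _ in range(20):
            n = 2000
            x = rng.binomial(2, 0.3, n).astype(float)
            gm = correlated_proxy(_matrix([x], freqs=[0.3]), "v0", r=0.9, rng=rng)
            scores = 0.3 * x + rng.standard_normal(n)
            uncond_p.append(scan_variants(scores, gm)["P"].iloc[1])
            cond_p.append(conditional_scan(scores, gm, ["v0"])["P"].iloc[1])
        assert max(uncond_p) < 1e-3  # proxy shows strong marginal signal
        assert np.mean(cond_p) > 0.2  # conditioning removes it (p uniform-like)

    def test_independent_causal_variant_unchanged(self):
        rng = np.random.default_rng(10)
        n = 5000
        x_sent = rng.binomial(2, 0.3, n).astype(float)
        x_ind = rng.binomial(2, 0.4, n).astype(float)
        scores = 0.2 * x_sent + 0.15 * x_ind + rng.standard_normal(n)
        gm = _matrix([x_sent, x_ind], freqs=[0.3, 0.4])
        uncond = scan_variants(scores, gm)
        cond = conditional_scan(scores, gm, ["v0"])
        assert abs(cond["BETA_OFF"].iloc[1] - uncond["BETA_OFF"].iloc[1]) < uncond["SE_OFF"].iloc[1]

    def test_monomorphic_sentinel_rejected(self):
        rng = np.random.default_rng(11)
        gm = _matrix([np.ones(100), rng.binomial(2, 0.4, 100).astype(float)])
        with pytest.raises(ConfigurationError):
            conditional_scan(rng.standard_normal(100), gm, ["v0"])


class TestGenomicInflation:
    def test_all_half_gives_exactly_one(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(12)
        lam = genomic_inflation(rng.uniform(size=10_000))
        assert 0.95 <= lam <= 1.05

    def test_monotone_distortion_moves_lambda(self):
        """Shrinking p-values inflates lambda; stretching them deflates it."""
        rng = np.random.default_rng(13)
        p = rng.uniform(size=10_000)
        assert genomic_inflation(np.sqrt(p)) < 1.0  # p drawn toward 1: deflation
        assert genomic_inflation(p**2) > 1.0  # p drawn toward 0: inflation

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(InvalidParameterError):
            genomic_inflation(np.full(50, 0.5))


class TestVarianceExplained:
    def test_perfect_correlation(self):
        x = np.arange(100.0)
        assert variance_explained(x, x) == pytest.approx(1.0)

    def test_independent_pair_is_tiny(self):
        rng = np.random.default_rng(14)
        r2 = variance_explained(rng.standard_normal(10_000), rng.binomial(2, 0.3, 10_000))
        assert r2 < 0.002

    def test_matches_regression_algebra(self):
        rng = np.random.default_rng(15)
        x = rng.binomial(2, 0.3, 2000).astype(float)
        y = 0.2 * x + rng.standard_normal(2000)
        beta = np.polyfit(x, y, 1)[0]
        expected = (beta * x.std() / y.std()) ** 2
        assert variance_explained(y, x) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            variance_explained(np.ones(10), np.arange(10.0))
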