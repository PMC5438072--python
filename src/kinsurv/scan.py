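"""Stage-2 GWAS scan of rank-normalized Martingale residuals.

The two-stage design fits one covariate-only Cox model per stratum, takes
Martingale residuals (linearly related to omitted genotype effects), maps
them to normal scores by a rank-based inverse-normal transform, and regresses
the scores on each variant's dosage. Because the covariates were absorbed in
the Cox stage, the per-variant step is a simple linear regression, cheap
enough for genome-wide work.

A raw score-on-dosage slope lives on the score scale. To report scan
estimates in log-hazard-ratio units the one-step Cox score calibration is
applied: the score statistic for adding dosage ``X`` to the fitted model is
``sum_i X_i M_i`` and its information is approximately ``d * var(X)`` (``d``
events), so ``beta_hat ~= slope_M * n / d``; with scores ``s ~= M / sd(M)``
this gives ``beta_hat ~= slope_s * sd(M) * n / d``. Pass a
:class:`ScanCalibration` to enable this; without one the slopes are reported
untransformed (the published workflow, which re-estimated effect sizes in a
full Cox model instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .errors import ConfigurationError, DegenerateDataError, InvalidParameterError

#: median of the chi-square(1) distribution
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))

ASSOC_COLUMNS = [
    "CHR",
    "SNP",
    "BP",
    "A1",
    "N",
    "BETA_OFF",
    "SE_OFF",
    "BETA_PARENT",
    "SE_PARENT",
    "P",
    "R2",
    "NOTE",
]


@dataclass(frozen=True)
class ScanCalibration:
    """Quantities converting score-scale slopes into log-HR units."""

    sigma: float  # sd of the raw Martingale residuals
    n: int        # records in the Cox fit
    n_events: int

    @property
    def kappa(self) -> float:
        return self.sigma * self.n / self.n_events


def rank_normal(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transform, Blom offset by default.

    ``score = Phi^{-1}((rank - offset) / (n - 2*offset + 1))``; ties get
    average ranks.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InvalidParameterError("need a 1-d vector of at least 2 values")
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("values must be finite")
    if np.ptp(v) == 0:
        raise DegenerateDataError("all values identical; ranks are undefined")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (len(v) - 2 * offset + 1))


def _prepare_dosages(G: np.ndarray):
    """Mean-impute missing dosages; report per-variant missing fraction."""
    G = np.array(G, dtype=float)
    miss = np.isnan(G)
    miss_frac = miss.mean(axis=1)
    if miss.any():
        col_mean = np.where(
            miss.all(axis=1), np.nan, np.nanmean(np.where(miss, np.nan, G), axis=1)
        )
        G = np.where(miss, col_mean[:, None], G)
    return G, miss_frac, (~miss).sum(axis=1)


def scan_variants(
    scores: np.ndarray,
    genotypes: GenotypeMatrix,
    calibration: ScanCalibration | None = None,
    max_missing: float = 0.05,
    min_maf: float = 0.001,
) -> pd.DataFrame:
    """Per-variant linear regression of survival scores on dosage.

    Vectorized across variants. Monomorphic / rare (MAF below ``min_maf``) /
    high-missingness variants are emitted as NA rows with an explanatory
    NOTE, preserving the row count.
    """
    y = np.asarray(scores, dtype=float)
    if len(y) != genotypes.n_subjects:
        raise InvalidParameterError(
            f"{len(y)} scores for {genotypes.n_subjects} genotype columns"
        )
    n = len(y)
    G, miss_frac, n_obs = _prepare_dosages(genotypes.dosages)

    yc = y - y.mean()
    syy = float(yc @ yc)
    xbar = G.mean(axis=1)
    Xc = G - xbar[:, None]
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxy = Xc @ yc

    maf = np.minimum(xbar / 2.0, 1 - xbar / 2.0)
    bad_missing = miss_frac > max_missing
    monomorphic = sxx <= 0
    rare = maf < min_maf

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        r2 = np.where(syy > 0, (beta * sxy) / syy, np.nan)

    kappa = calibration.kappa if calibration is not None else 1.0
    beta_off = beta * kappa
    se_off = se * kappa

    note = np.array([""] * genotypes.n_variants, dtype=object)
    note[rare] = "maf_below_threshold"
    note[monomorphic] = "monomorphic"
    note[bad_missing] = "high_missingness"
    na = bad_missing | monomorphic | rare
    for arr in (beta_off, se_off, pvals, r2):
        arr[na] = np.nan

    meta = genotypes.variants
    return pd.DataFrame(
        {
            "CHR": meta["chrom"].to_numpy(),
            "SNP": meta["snp"].to_numpy(),
            "BP": meta["pos"].to_numpy(),
            "A1": meta["effect_allele"].to_numpy(),
            "N": n_obs,
            "BETA_OFF": beta_off,
            "SE_OFF": se_off,
            "BETA_PARENT": 2.0 * beta_off,
            "SE_PARENT": 2.0 * se_off,
            "P": pvals,
            "R2": r2,
            "NOTE": note,
        },
        columns=ASSOC_COLUMNS,
    )


def conditional_scan(
    scores: np.ndarray,
    genotypes: GenotypeMatrix,
    sentinel_ids: list[str],
    calibration: ScanCalibration | None = None,
    max_missing: float = 0.05,
    min_maf: float = 0.001,
) -> pd.DataFrame:
    """Per-variant regression with sentinel dosages as additional covariates.

    A variant collinear with the sentinels (including each sentinel scanned
    against itself) is reported as an NA row rather than an error.
    """
    y = np.asarray(scores, dtype=float)
    n = len(y)
    G, miss_frac, n_obs = _prepare_dosages(genotypes.dosages)
    sent = genotypes.subset_variants(sentinel_ids)
    S, _, _ = _prepare_dosages(sent.dosages)
    if np.any(S.std(axis=1) == 0):
        raise ConfigurationError("a sentinel variant is monomorphic in this subset")

    C = np.column_stack([np.ones(n), S.T])  # intercept + sentinels
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    base = scan_variants(
        np.zeros(n), genotypes, max_missing=max_missing, min_maf=min_maf
    )  # reuse NA flags only
    note = base["NOTE"].to_numpy(dtype=object)

    kappa = calibration.kappa if calibration is not None else 1.0
    dof = n - C.shape[1] - 1
    beta_off = np.full(genotypes.n_variants, np.nan)
    se_off = np.full(genotypes.n_variants, np.nan)
    pvals = np.full(genotypes.n_variants, np.nan)
    r2 = np.full(genotypes.n_variants, np.nan)
    syy = float(y_res @ y_res)
    for v in range(genotypes.n_variants):
        if note[v]:
            continue
        x = G[v]
        x_res = x - Q @ (Q.T @ x)
        sxx = float(x_res @ x_res)
        if sxx < 1e-10 * float(x @ x):
            note[v] = "collinear_with_sentinel"
            continue
        b = float(x_res @ y_res) / sxx
        rss = syy - b * b * sxx
        sigma2 = rss / dof
        se_v = np.sqrt(sigma2 / sxx)
        tv = b / se_v
        beta_off[v] = b * kappa
        se_off[v] = se_v * kappa
        pvals[v] = 2 * stats.t.sf(abs(tv), df=dof)
        r2[v] = (b * b * sxx) / syy if syy > 0 else np.nan

    meta = genotypes.variants
    return pd.DataFrame(
        {
            "CHR": meta["chrom"].to_numpy(),
            "SNP": meta["snp"].to_numpy(),
            "BP": meta["pos"].to_numpy(),
            "A1": meta["effect_allele"].to_numpy(),
            "N": n_obs,
            "BETA_OFF": beta_off,
            "SE_OFF": se_off,
            "BETA_PARENT": 2.0 * beta_off,
            "SE_PARENT": 2.0 * se_off,
            "P": pvals,
            "R2": r2,
            "NOTE": note,
        },
        columns=ASSOC_COLUMNS,
    )


def genomic_inflation(pvals) -> float:
    """Genomic-control lambda: median association chi-square over its null
    expectation (0.4549...)."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise InvalidParameterError(f"need at least 100 p-values, got {len(p)}")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def variance_explained(scores, dosage) -> float:
    """Squared correlation between survival score and dosage (fraction)."""
    s = np.asarray(scores, dtype=float)
    x = np.asarray(dosage, dtype=float)
    if np.std(s) == 0 or np.std(x) == 0:
        raise DegenerateDataError("zero-variance input")
    r = np.corrcoef(s, x)[0, 1]
    return float(r * r)


def qq_manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready export: one row per scanned variant with -log10 p and a
    cumulative genome position."""
    out = assoc[["SNP", "CHR", "BP", "P"]].copy()
    offset = 0
    cumpos = np.empty(len(out), dtype=float)
    for chrom, idx in out.groupby("CHR", sort=False).groups.items():
        bp = out.loc[idx, "BP"].to_numpy(dtype=float)
        cumpos[out.index.get_indexer(idx)] = bp + offset
        offset += bp.max() if len(bp) else 0
    out["CUMPOS"] = cumpos
    with np.errstate(divide="ignore"):
        out["NEG_LOG10_P"] = -np.log10(out["P"])
    return out[["SNP", "NEG_LOG10_P", "CUMPOS"]]
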