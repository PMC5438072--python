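"""Statsmodels-style surface for the kin-cohort survival association analysis.

:class:`KinCohortModel` is constructed from a parent-record phenotype table
and an offspring genotype matrix; :meth:`KinCohortModel.fit` runs the full
workflow — QC exclusions, per-sex covariate-only Cox fits, Martingale
residuals, rank-normal scores, per-variant scan (with optional conditional
scan), full-Cox verification of sentinel variants, doubling onto the parental
scale, inverse-variance meta-analysis across the parental sexes, sex and
age-window contrasts, and Kaplan-Meier life-year summaries — and returns a
:class:`KinCohortResults` carrying every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as kio
from .containers import GenotypeMatrix, covariate_columns, validate_phenotypes
from .cox import (
    CoxFit,
    fit_cox,
    km_life_years,
    martingale_residuals,
    per_allele_years,
    truncate_age_window,
)
from .dosage import rescale_to_parent_scale
from .errors import ConfigurationError
from .meta import StudyEstimate, contrast_test, ivw_meta
from .qc import ExclusionTally, apply_exclusions
from .scan import (
    ScanCalibration,
    conditional_scan,
    genomic_inflation,
    qq_manhattan_table,
    rank_normal,
    scan_variants,
)

SEXES = ("father", "mother")
WINDOWS = ("40-75", "75+")


class KinCohortModel:
    """Kin-cohort survival association model.

    Parameters
    ----------
    phenotypes
        Parent-record table (see :mod:`kinsurv.containers`).
    genotypes
        Offspring dosages; subjects are aligned by id (intersection taken).
    covariates
        Covariate column names; defaults to every ``covariate_*`` column.
    entry_age
        Common entry age of the survival records (40 unless records were
        pre-transformed onto the late age window).
    ties
        Tie-handling for the Cox stage, ``"efron"`` (default) or ``"breslow"``.
    rank_offset
        Offset of the rank-based inverse-normal transform (Blom 3/8 default).
    calibrate
        If True (default), scan estimates are converted to log-HR units via
        the one-step score calibration; otherwise they stay on the score
        scale as in the published workflow.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        genotypes: GenotypeMatrix,
        covariates: list[str] | None = None,
        entry_age: float = 40.0,
        ties: str = "efron",
        rank_offset: float = 0.375,
        calibrate: bool = True,
        min_maf: float = 0.001,
        max_missing: float = 0.05,
    ):
        validate_phenotypes(phenotypes)
        if genotypes.n_variants == 0:
            raise ConfigurationError("genotype stage: the genotype matrix has zero variants")
        self.phenotypes = phenotypes.copy()
        self.phenotypes["subject_id"] = self.phenotypes["subject_id"].astype(str)
        self.genotypes = GenotypeMatrix(
            genotypes.dosages, np.asarray(genotypes.subjects, dtype=str), genotypes.variants
        )
        self.covariates = (
            covariates if covariates is not None else covariate_columns(phenotypes)
        )
        self.entry_age = entry_age
        self.ties = ties
        self.rank_offset = rank_offset
        self.calibrate = calibrate
        self.min_maf = min_maf
        self.max_missing = max_missing
        self.truth = None  # populated by from_simulation

    @classmethod
    def from_simulation(cls, config, **kwargs) -> "KinCohortModel":
        """Build the model from a freshly generated synthetic cohort."""
        from .simulate import generate_cohort

        pheno, geno, truth = generate_cohort(config)
        model = cls(pheno, geno, **kwargs)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    def fit(
        self,
        sentinels: list[str] | None = None,
        conditional: bool = False,
        age_windows: bool = False,
        life_years: bool = False,
        life_year_horizon: float | None = None,
        qc: bool = True,
    ) -> "KinCohortResults":
        sentinels = list(sentinels) if sentinels else []
        if qc:
            clean, tally = apply_exclusions(self.phenotypes)
        else:
            clean, tally = self.phenotypes, None

        cox_fits: dict[str, CoxFit] = {}
        association: dict[str, pd.DataFrame] = {}
        conditional_assoc: dict[str, pd.DataFrame] = {}
        calibrations: dict[str, ScanCalibration] = {}
        lambda_gc: dict[str, float] = {}
        verification_rows = []
        life_rows = []

        for sex in SEXES:
            sub = clean.loc[clean["parent_sex"] == sex].reset_index(drop=True)
            if sub.empty:
                continue
            fit = fit_cox(
                sub,
                covariates=self.covariates,
                entry_age=self.entry_age,
                ties=self.ties,
            )
            cox_fits[sex] = fit
            resid = martingale_residuals(fit, sub)
            scores = rank_normal(resid, offset=self.rank_offset)
            calib = (
                ScanCalibration(
                    sigma=float(np.std(resid)), n=fit.n, n_events=fit.n_events
                )
                if self.calibrate
                else None
            )
            calibrations[sex] = calib
            gm = self.genotypes.subset_subjects(sub["subject_id"].to_numpy())
            assoc = scan_variants(
                scores,
                gm,
                calibration=calib,
                max_missing=self.max_missing,
                min_maf=self.min_maf,
            )
            association[sex] = assoc
            pvals = assoc["P"].dropna()
            if len(pvals) >= 100:
                lambda_gc[sex] = genomic_inflation(pvals)
            if conditional and sentinels:
                conditional_assoc[sex] = conditional_scan(
                    scores,
                    gm,
                    sentinels,
                    calibration=calib,
                    max_missing=self.max_missing,
                    min_maf=self.min_maf,
                )
            for snp in sentinels:
                verification_rows.append(
                    self._verify_sentinel(sub, gm, snp, sex, self.entry_age)
                )
                if life_years:
                    dosage = np.rint(gm.dosage_for(snp))
                    ly = km_life_years(
                        sub, dosage, horizon=life_year_horizon, entry_age=self.entry_age
                    )
                    years_off = per_allele_years(ly)
                    life_rows.append(
                        {
                            "parent_sex": sex,
                            "SNP": snp,
                            "years_per_offspring_allele": years_off,
                            "years_per_parental_allele": 2.0 * years_off,
                        }
                    )

        verification = pd.DataFrame(verification_rows)
        meta_table = self._meta_across_sexes(association)
        sex_contrasts = self._sex_contrasts(verification, sentinels)
        window_fits, window_contrasts = (
            self._window_analysis(clean, sentinels) if age_windows and sentinels else (None, None)
        )

        return KinCohortResults(
            model=self,
            qc_tally=tally,
            clean_phenotypes=clean,
            cox_fits=cox_fits,
            association=association,
            conditional=conditional_assoc or None,
            association_meta=meta_table,
            verification=verification if len(verification) else None,
            sex_contrasts=sex_contrasts,
            window_fits=window_fits,
            window_contrasts=window_contrasts,
            life_years=pd.DataFrame(life_rows) if life_rows else None,
            lambda_gc=lambda_gc,
            calibrations=calibrations,
        )

    # ------------------------------------------------------------------
    def _verify_sentinel(self, sub, gm, snp, sex, entry_age, window=None) -> dict:
        """Full Cox fit with the sentinel dosage alongside the covariates."""
        frame = sub.copy()
        frame["_dosage"] = gm.dosage_for(snp)
        frame = frame.dropna(subset=["_dosage"])
        fit = fit_cox(
            frame,
            covariates=["_dosage"] + list(self.covariates),
            entry_age=entry_age,
            ties=self.ties,
        )
        beta_off = float(fit.params["_dosage"])
        se_off = float(fit.se["_dosage"])
        beta_par, se_par = rescale_to_parent_scale(beta_off, se_off)
        from scipy import stats

        z = beta_off / se_off
        return {
            "parent_sex": sex,
            "SNP": snp,
            "window": window or "40+",
            "n": fit.n,
            "deaths": fit.n_events,
            "beta_offspring": beta_off,
            "se_offspring": se_off,
            "beta_parent": beta_par,
            "se_parent": se_par,
            "HR_parent": float(np.exp(beta_par)),
            "P": float(2 * stats.norm.sf(abs(z))),
        }

    def _meta_across_sexes(self, association) -> pd.DataFrame | None:
        if len(association) < 2:
            return None
        rows = []
        fa, mo = association["father"], association["mother"]
        for i in range(len(fa)):
            ra, rm = fa.iloc[i], mo.iloc[i]
            if not np.isfinite(ra["BETA_PARENT"]) or not np.isfinite(rm["BETA_PARENT"]):
                rows.append({"SNP": ra["SNP"], "BETA_PARENT": np.nan})
                continue
            m = ivw_meta(
                [
                    StudyEstimate("father", ra["BETA_PARENT"], ra["SE_PARENT"]),
                    StudyEstimate("mother", rm["BETA_PARENT"], rm["SE_PARENT"]),
                ]
            )
            rows.append(
                {
                    "SNP": ra["SNP"],
                    "CHR": ra["CHR"],
                    "BP": ra["BP"],
                    "A1": ra["A1"],
                    "BETA_PARENT": m.beta,
                    "SE_PARENT": m.se,
                    "HR_PARENT": m.hr,
                    "P": m.p,
                    "Q": m.q,
                }
            )
        return pd.DataFrame(rows)

    def _sex_contrasts(self, verification, sentinels) -> pd.DataFrame | None:
        if verification is None or not len(verification) or not sentinels:
            return None
        rows = []
        for snp in sentinels:
            sub = verification.loc[verification["SNP"] == snp]
            fa = sub.loc[sub["parent_sex"] == "father"]
            mo = sub.loc[sub["parent_sex"] == "mother"]
            if fa.empty or mo.empty:
                continue
            c = contrast_test(
                float(fa["beta_parent"].iloc[0]),
                float(fa["se_parent"].iloc[0]),
                float(mo["beta_parent"].iloc[0]),
                float(mo["se_parent"].iloc[0]),
            )
            rows.append(
                {"SNP": snp, "contrast": "mother-father", "diff": c.diff, "se": c.se, "z": c.z, "P": c.p}
            )
        return pd.DataFrame(rows) if rows else None

    def _window_analysis(self, clean, sentinels):
        """Full-Cox sentinel fits per sex within each age window, plus the
        young-vs-old contrast per sex and sentinel."""
        rows = []
        for window in WINDOWS:
            entry = self.entry_age if window == "40-75" else 75.0
            for sex in SEXES:
                sub = clean.loc[clean["parent_sex"] == sex].reset_index(drop=True)
                if sub.empty:
                    continue
                win = truncate_age_window(sub, window).reset_index(drop=True)
                if win.empty or win["event"].sum() == 0:
                    continue
                gm = self.genotypes.subset_subjects(win["subject_id"].to_numpy())
                for snp in sentinels:
                    rows.append(self._verify_sentinel(win, gm, snp, sex, entry, window=window))
        fits = pd.DataFrame(rows)
        contrasts = []
        for snp in sentinels:
            for sex in SEXES:
                young = fits.loc[
                    (fits["SNP"] == snp) & (fits["parent_sex"] == sex) & (fits["window"] == "40-75")
                ]
                old = fits.loc[
                    (fits["SNP"] == snp) & (fits["parent_sex"] == sex) & (fits["window"] == "75+")
                ]
                if young.empty or old.empty:
                    continue
                c = contrast_test(
                    float(young["beta_parent"].iloc[0]),
                    float(young["se_parent"].iloc[0]),
                    float(old["beta_parent"].iloc[0]),
                    float(old["se_parent"].iloc[0]),
                )
                contrasts.append(
                    {
                        "SNP": snp,
                        "parent_sex": sex,
                        "contrast": "75+ minus 40-75",
                        "diff": c.diff,
                        "se": c.se,
                        "z": c.z,
                        "P": c.p,
                    }
                )
        return fits, pd.DataFrame(contrasts) if contrasts else None


@dataclass
class KinCohortResults:
    """Result bundle of a fitted :class:`KinCohortModel`."""

    model: KinCohortModel
    qc_tally: ExclusionTally | None
    clean_phenotypes: pd.DataFrame = field(repr=False)
    cox_fits: dict = field(repr=False)
    association: dict = field(repr=False)
    conditional: dict | None
    association_meta: pd.DataFrame | None
    verification: pd.DataFrame | None
    sex_contrasts: pd.DataFrame | None
    window_fits: pd.DataFrame | None
    window_contrasts: pd.DataFrame | None
    life_years: pd.DataFrame | None
    lambda_gc: dict
    calibrations: dict = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        lines = ["Kin-cohort survival association results", "=" * 42]
        if self.qc_tally is not None:
            t = self.qc_tally
            lines.append(
                f"QC: {t.subjects_in} subjects in; excluded {t.adopted} adopted, "
                f"{t.missing_parent_data} missing parental data, {t.invalid_age} invalid age, "
                f"{t.missing_covariate} missing covariate; {t.pre40_parent_records} pre-40 "
                f"parent records dropped; {t.records_remaining} records remain."
            )
        for sex, fit in self.cox_fits.items():
            lam = self.lambda_gc.get(sex)
            lam_txt = f", lambda_GC = {lam:.3f}" if lam is not None else ""
            lines.append(
                f"{sex}: {fit.n} records, {fit.n_events} deaths; Cox converged in "
                f"{fit.n_iter} iterations{lam_txt}"
            )
        if self.verification is not None:
            lines.append("\nVerification (full Cox, parental scale):")
            lines.append(
                self.verification[
                    ["parent_sex", "SNP", "window", "n", "deaths", "beta_parent", "se_parent", "HR_parent", "P"]
                ].to_string(index=False)
            )
        if self.sex_contrasts is not None:
            lines.append("\nSex contrasts (parental scale):")
            lines.append(self.sex_contrasts.to_string(index=False))
        if self.window_contrasts is not None:
            lines.append("\nAge-window contrasts:")
            lines.append(self.window_contrasts.to_string(index=False))
        if self.life_years is not None:
            lines.append("\nLife-years per allele (Kaplan-Meier restricted means):")
            lines.append(self.life_years.to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write every table of the bundle under ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.qc_tally is not None:
            kio.write_json(self.qc_tally.to_dict(), outdir / "qc_tally.json")
        for sex, fit in self.cox_fits.items():
            fit.to_json(outdir / f"cox_fit_{sex}.json")
        for sex, assoc in self.association.items():
            kio.write_table(assoc, outdir / f"association_{sex}.tsv")
            kio.write_table(qq_manhattan_table(assoc), outdir / f"manhattan_{sex}.tsv")
        if self.conditional:
            for sex, assoc in self.conditional.items():
                kio.write_table(assoc, outdir / f"conditional_{sex}.tsv")
        if self.association_meta is not None:
            kio.write_table(self.association_meta, outdir / "association_meta.tsv")
        if self.verification is not None:
            kio.write_table(self.verification, outdir / "verification.tsv")
        if self.sex_contrasts is not None:
            kio.write_table(self.sex_contrasts, outdir / "sex_contrasts.tsv")
        if self.window_fits is not None:
            kio.write_table(self.window_fits, outdir / "window_fits.tsv")
        if self.window_contrasts is not None:
            kio.write_table(self.window_contrasts, outdir / "window_contrasts.tsv")
        if self.life_years is not None:
            kio.write_table(self.life_years, outdir / "life_years.tsv")
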