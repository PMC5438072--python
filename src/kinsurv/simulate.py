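"""Synthetic trio-structured cohorts for the kin-cohort survival design.

The generator emulates the statistical structure the analysis assumes:

* parental genotypes drawn under Hardy-Weinberg equilibrium at configured
  allele frequencies, offspring dosages by Mendelian transmission;
* parental lifespans from age 40 under a Gompertz hazard
  ``h(t) = a * exp(b * (t - 40)) * exp(eta)``, where ``eta`` carries the
  parent's own genotype effect (log hazard ratio per *parental* allele,
  sex-specific and piecewise-constant across the 40-75 / 75+ age windows)
  plus confounder covariate effects;
* right-censoring of parents still alive when the offspring is interviewed
  (offspring interviewed at ages 40-69, parents older by a uniform offset);
* contamination records that the QC stage must catch: adopted offspring,
  missing covariates, implausible parental ages, parent deaths before 40.

Randomness is organised as independent child streams of one global seed
(genotypes, covariates, lifespans, interview timing, contamination), so each
sub-stream is reproducible on its own and the whole cohort is bit-identical
under a fixed :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ConfigurationError, InvalidParameterError

ENTRY_AGE = 40.0
AGE_SPLIT = 75.0
SEXES = ("father", "mother")
#: sub-stream order for SeedSequence.spawn
_STREAMS = ("genotypes", "covariates", "lifespans", "interview", "contamination")


@dataclass(frozen=True)
class GompertzParams:
    """Baseline mortality law from age 40: hazard ``a * exp(b * (t - 40))``.

    Defaults put mean death ages in the low-to-mid 70s, the ballpark of the
    parental generation the design targets (the split age 75 is approximately
    the mean age at death there).
    """

    a: float = 0.002  # hazard at age 40, 1/year
    b: float = 0.095  # log-hazard slope, 1/year


@dataclass(frozen=True)
class ContaminationRates:
    """Fractions of records carrying each QC-relevant defect."""

    adopted: float = 0.015            # per subject
    missing_covariate: float = 0.0012  # per subject (one covariate blanked)
    implausible_age: float = 0.0005    # per parent record (age set > 115)
    pre40_death: float = 0.002         # per parent record (death before 40)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``causal_effects`` has shape (n_variants, 2, 2): axis 1 is parent sex
    (father, mother), axis 2 is the age window (40-75, 75+); entries are log
    hazard ratios per *parental* allele. The downstream offspring-scale scan
    is expected to see half of each value.
    """

    n_subjects: int = 20_000
    n_variants: int = 1
    allele_freqs: np.ndarray = field(default_factory=lambda: np.array([0.3]))
    causal_effects: np.ndarray | None = None  # default: all zero
    gompertz: dict = field(
        default_factory=lambda: {"father": GompertzParams(), "mother": GompertzParams()}
    )
    covariate_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.05, 0.15, 0.10])
    )
    interview_age_range: tuple = (40.0, 69.0)
    parent_offset_range: tuple = (20.0, 35.0)
    contamination: ContaminationRates = field(default_factory=ContaminationRates)
    seed: int = 0

    def __post_init__(self) -> None:
        self.allele_freqs = np.atleast_1d(np.asarray(self.allele_freqs, dtype=float))
        if self.n_subjects < 1 or self.n_variants < 1:
            raise ConfigurationError("n_subjects and n_variants must be >= 1")
        if len(self.allele_freqs) != self.n_variants:
            raise ConfigurationError(
                f"{len(self.allele_freqs)} allele frequencies for {self.n_variants} variants"
            )
        if np.any(self.allele_freqs <= 0) or np.any(self.allele_freqs >= 1):
            raise ConfigurationError("allele frequencies must lie strictly inside (0, 1)")
        if self.causal_effects is None:
            self.causal_effects = np.zeros((self.n_variants, 2, 2))
        self.causal_effects = np.asarray(self.causal_effects, dtype=float)
        if self.causal_effects.shape != (self.n_variants, 2, 2):
            raise ConfigurationError(
                "causal_effects must have shape (n_variants, 2 sexes, 2 age windows); "
                f"got {self.causal_effects.shape}"
            )
        for sex in SEXES:
            if sex not in self.gompertz:
                raise ConfigurationError(f"gompertz parameters missing for {sex!r}")
            if self.gompertz[sex].a <= 0:
                raise ConfigurationError("gompertz a must be > 0")
        self.covariate_effects = np.atleast_1d(np.asarray(self.covariate_effects, dtype=float))

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_effects)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allele_freqs"] = self.allele_freqs.tolist()
        d["causal_effects"] = self.causal_effects.tolist()
        d["covariate_effects"] = self.covariate_effects.tolist()
        d["gompertz"] = {s: asdict(g) for s, g in self.gompertz.items()}
        d["contamination"] = asdict(self.contamination)
        return d


def constant_effects(betas: Sequence[float]) -> np.ndarray:
    """Effects array with one parental log-HR per variant, same in both sexes
    and both age windows."""
    b = np.asarray(betas, dtype=float)
    return np.broadcast_to(b[:, None, None], (len(b), 2, 2)).copy()


def sex_window_effects(
    n_variants: int,
    variant: int,
    father: tuple[float, float] = (0.0, 0.0),
    mother: tuple[float, float] = (0.0, 0.0),
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Set one variant's (sex x window) parental log-HRs in an effects array."""
    eff = np.zeros((n_variants, 2, 2)) if base is None else np.array(base, dtype=float)
    eff[variant, 0, :] = father
    eff[variant, 1, :] = mother
    return eff


def draw_parent_genotypes(n: int, p: float, rng: np.random.Generator):
    """HWE genotypes for ``n`` father/mother pairs at counted-allele frequency ``p``.

    Returns two integer arrays (fathers, mothers), each i.i.d. Binomial(2, p).
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"allele frequency must be in (0, 1); got {p}")
    fathers = rng.binomial(2, p, size=n)
    mothers = rng.binomial(2, p, size=n)
    return fathers, mothers


def transmit_offspring_dosage(father_genotype, mother_genotype, rng: np.random.Generator):
    """Mendelian transmission: one allele drawn uniformly from each parent, summed.

    Accepts scalars or arrays of genotypes in {0, 1, 2}.
    """
    fg = np.asarray(father_genotype)
    mg = np.asarray(mother_genotype)
    if np.any((fg < 0) | (fg > 2)) or np.any((mg < 0) | (mg > 2)):
        raise InvalidParameterError("parent genotypes must be in {0, 1, 2}")
    # P(transmit counted allele) = genotype / 2
    a1 = rng.random(fg.shape) < fg / 2.0
    a2 = rng.random(mg.shape) < mg / 2.0
    out = a1.astype(int) + a2.astype(int)
    return out if out.shape else int(out)


def sample_gompertz_lifespan(a: float, b: float, eta, u) -> np.ndarray:
    """Invert the Gompertz survival function at uniform draws ``u``.

    ``S(t) = exp(-(a e^eta / b) (e^{b (t-40)} - 1))``; the exponential limit is
    used at ``b == 0``. Exact inverse-CDF sampling, so analytic quantiles are
    reproduced without error.
    """
    if a <= 0:
        raise InvalidParameterError("gompertz a must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise InvalidParameterError("u must lie strictly inside (0, 1)")
    eta = np.asarray(eta, dtype=float)
    rate = a * np.exp(eta)
    if b == 0:
        return ENTRY_AGE - np.log(u) / rate
    return ENTRY_AGE + np.log1p(-b * np.log(u) / rate) / b


def _sample_piecewise_gompertz(a, b, eta_young, eta_old, u):
    """Lifespans under a Gompertz hazard whose log-HR switches at age 75."""
    e = -np.log(u)  # unit-exponential cumulative hazard target
    rate1 = a * np.exp(eta_young)
    rate2 = a * np.exp(eta_old)
    span = AGE_SPLIT - ENTRY_AGE
    if b == 0:
        h_split = rate1 * span
        t = np.where(
            e <= h_split,
            ENTRY_AGE + e / rate1,
            AGE_SPLIT + (e - h_split) / rate2,
        )
        return t
    g_split = np.exp(b * span)
    h_split = rate1 / b * (g_split - 1.0)
    first = e <= h_split
    t = np.empty_like(e)
    t[first] = ENTRY_AGE + np.log1p(b * e[first] / rate1[first]) / b
    rest = ~first
    t[rest] = ENTRY_AGE + np.log(g_split + b * (e[rest] - h_split[rest]) / rate2[rest]) / b
    return t


def apply_interview_censoring(true_death_age, parent_age_at_interview):
    """Observed (age, event) given the parent's age when the offspring was interviewed.

    A parent still alive at interview is censored at their interview age;
    otherwise the death is observed in full.
    """
    death = np.asarray(true_death_age, dtype=float)
    at_interview = np.asarray(parent_age_at_interview, dtype=float)
    alive = at_interview < death
    observed = np.where(alive, at_interview, death)
    event = (~alive).astype(int)
    if observed.shape:
        return observed, event
    return float(observed), int(event)


def generate_cohort(config: SimConfig):
    """Generate one cohort.

    Returns
    -------
    phenotypes : pandas.DataFrame
        One row per parent record (see :mod:`kinsurv.containers` schema).
    genotypes : GenotypeMatrix
        Offspring dosages, variants x subjects.
    truth : dict
        Configured effects, latent trio data (parental genotypes, true death
        ages) and contamination bookkeeping, for oracle checks.
    """
    n = config.n_subjects
    m = config.n_variants
    streams = dict(zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS))))
    rng_geno = np.random.default_rng(streams["genotypes"])
    rng_cov = np.random.default_rng(streams["covariates"])
    rng_life = np.random.default_rng(streams["lifespans"])
    rng_int = np.random.default_rng(streams["interview"])
    rng_cont = np.random.default_rng(streams["contamination"])

    father_g = np.empty((m, n), dtype=int)
    mother_g = np.empty((m, n), dtype=int)
    offspring = np.empty((m, n), dtype=int)
    for v in range(m):
        fg, mg = draw_parent_genotypes(n, config.allele_freqs[v], rng_geno)
        father_g[v], mother_g[v] = fg, mg
        offspring[v] = transmit_offspring_dosage(fg, mg, rng_geno)

    k = config.n_covariates
    covariates = rng_cov.standard_normal((n, k)) if k else np.empty((n, 0))
    cov_eta = covariates @ config.covariate_effects if k else np.zeros(n)

    lo, hi = config.interview_age_range
    interview_age = rng_int.uniform(lo, hi, size=n)

    subject_ids = np.array([f"S{i:07d}" for i in range(n)])
    parent_g = {"father": father_g, "mother": mother_g}
    rows = []
    true_death = {}
    for s, sex in enumerate(SEXES):
        gp = config.gompertz[sex]
        eta_young = config.causal_effects[:, s, 0] @ parent_g[sex] + cov_eta
        eta_old = config.causal_effects[:, s, 1] @ parent_g[sex] + cov_eta
        u = rng_life.uniform(np.finfo(float).tiny, 1.0, size=n)
        death_age = _sample_piecewise_gompertz(gp.a, gp.b, eta_young, eta_old, u)
        offset = rng_int.uniform(*config.parent_offset_range, size=n)
        observed, event = apply_interview_censoring(death_age, interview_age + offset)
        true_death[sex] = death_age
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "parent_sex": sex,
                    "observed_age": observed,
                    "event": event,
                }
            )
        )
    pheno = pd.concat(rows, ignore_index=True)
    pheno["adopted"] = False
    pheno["age_valid"] = True
    cov_frame = pd.DataFrame(
        np.vstack([covariates, covariates]),
        columns=[f"covariate_{j + 1}" for j in range(k)],
    )
    pheno = pd.concat([pheno, cov_frame], axis=1)

    # --- contamination ------------------------------------------------------
    rates = config.contamination
    adopted_mask = rng_cont.random(n) < rates.adopted
    missing_cov_mask = rng_cont.random(n) < rates.missing_covariate
    implaus_mask = rng_cont.random(2 * n) < rates.implausible_age
    pre40_mask = rng_cont.random(2 * n) < rates.pre40_death

    pheno.loc[pheno["subject_id"].isin(subject_ids[adopted_mask]), "adopted"] = True
    if k:
        blank_col = rng_cont.integers(0, k, size=n)
        for i in np.flatnonzero(missing_cov_mask):
            col = f"covariate_{blank_col[i] + 1}"
            pheno.loc[pheno["subject_id"] == subject_ids[i], col] = np.nan
    # record-level defects: rows are stacked fathers then mothers
    pheno.loc[implaus_mask, "observed_age"] = rng_cont.uniform(116.0, 125.0, int(implaus_mask.sum()))
    pheno.loc[implaus_mask, "age_valid"] = False
    pre40_ages = rng_cont.uniform(18.0, 39.9, int(pre40_mask.sum()))
    pheno.loc[pre40_mask, "observed_age"] = pre40_ages
    pheno.loc[pre40_mask, "event"] = 1

    variants = pd.DataFrame(
        {
            "snp": [f"rs{v + 1:06d}" for v in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 10_000,
            "effect_allele": ["A"] * m,
            "freq": config.allele_freqs,
        }
    )
    genotypes = GenotypeMatrix(offspring.astype(float), subject_ids, variants)

    truth = {
        "config": config.to_dict(),
        "parental_log_hr": config.causal_effects.tolist(),
        "father_genotypes": father_g,
        "mother_genotypes": mother_g,
        "true_death_age": true_death,
        "contamination_counts": {
            "adopted": int(adopted_mask.sum()),
            "missing_covariate": int(missing_cov_mask.sum()),
            "implausible_age": int(implaus_mask.sum()),
            "pre40_death": int(pre40_mask.sum()),
        },
    }
    return pheno, genotypes, truth


def correlated_proxy(
    gm: GenotypeMatrix, snp_id: str, r: float, rng: np.random.Generator, proxy_id: str = "proxy"
) -> GenotypeMatrix:
    """Append a proxy variant in linkage disequilibrium with ``snp_id``.

    Built by re-drawing each allele of the target variant independently with
    probability ``1 - r`` from the population frequency, which yields allelic
    correlation ~``r``. Used only to exercise the conditional scan; the
    generator itself keeps variants independent.
    """
    if not 0 <= r <= 1:
        raise InvalidParameterError("r must be in [0, 1]")
    target = gm.dosage_for(snp_id)
    row = gm.variants.loc[gm.variants["snp"] == snp_id].iloc[0]
    p = float(row["freq"]) if np.isfinite(row["freq"]) else float(np.mean(target) / 2)
    n = gm.n_subjects
    proxy = np.zeros(n)
    for _ in range(2):  # per haplotype
        allele = rng.random(n) < target / 2.0
        flip = rng.random(n) >= r
        fresh = rng.random(n) < p
        proxy += np.where(flip, fresh, allele)
    variants = pd.concat(
        [
            gm.variants,
            pd.DataFrame(
                {
                    "snp": [proxy_id],
                    "chrom": [row["chrom"]],
                    "pos": [int(row["pos"]) + 1],
                    "effect_allele": [row["effect_allele"]],
                    "freq": [p],
                }
            ),
        ],
        ignore_index=True,
    )
    dosages = np.vstack([gm.dosages, proxy[None, :]])
    return GenotypeMatrix(dosages, gm.subjects, variants)
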