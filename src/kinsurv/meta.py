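"""Fixed-effect meta-analysis and contrast tests on log hazard ratios.

Per-stratum Cox estimates (father/mother, discovery/replication, age windows)
are combined by inverse-variance weighting; sex and age-window differences
are tested by a normal contrast ``z = (b2 - b1) / sqrt(se1^2 + se2^2)``. With
tens of thousands of deaths per stratum the normal and t reference
distributions are indistinguishable, so the normal approximation is used
throughout (two-sided by default; a one-sided option exists for directional
replication). Cochran's Q is reported for information only — the combination
itself is always fixed-effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidParameterError


@dataclass(frozen=True)
class StudyEstimate:
    """One stratum's log-HR estimate on the parental scale."""

    label: str
    beta: float
    se: float
    n_lives: int | None = None
    n_deaths: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.beta) or not np.isfinite(self.se) or self.se <= 0:
            raise InvalidParameterError(f"invalid estimate {self.label!r}: se must be > 0")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance combination of several study estimates."""

    beta: float
    se: float
    hr: float
    z: float
    p: float
    weights: dict = field(default_factory=dict)  # label -> normalized weight
    q: float = np.nan       # Cochran's Q (information only)
    q_df: int = 0
    q_p: float = np.nan
    n_lives: int | None = None
    n_deaths: int | None = None


@dataclass(frozen=True)
class ContrastResult:
    """Difference between two stratum estimates with its normal test."""

    diff: float
    se: float
    z: float
    p: float


def hr_from_beta(beta: float) -> float:
    return float(np.exp(beta))


def beta_from_hr(hr: float) -> float:
    if hr <= 0:
        raise InvalidParameterError("hazard ratio must be > 0")
    return float(np.log(hr))


def ivw_meta(estimates, one_sided: bool = False) -> MetaResult:
    """Combine estimates with weights 1/se^2.

    ``one_sided=True`` halves the p-value in the direction of the combined
    effect (used only to mirror directional replication conventions).
    """
    estimates = list(estimates)
    if not estimates:
        raise InvalidParameterError("need at least one estimate")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(stats.norm.sf(abs(z)) * (1 if one_sided else 2))
    q = float(np.sum(w * (betas - beta) ** 2))
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    lives = [e.n_lives for e in estimates]
    deaths = [e.n_deaths for e in estimates]
    return MetaResult(
        beta=beta,
        se=se,
        hr=hr_from_beta(beta),
        z=float(z),
        p=p,
        weights={e.label: float(wi / np.sum(w)) for e, wi in zip(estimates, w)},
        q=q,
        q_df=q_df,
        q_p=q_p,
        n_lives=sum(lives) if all(v is not None for v in lives) else None,
        n_deaths=sum(deaths) if all(v is not None for v in deaths) else None,
    )


def contrast_test(beta1: float, se1: float, beta2: float, se2: float) -> ContrastResult:
    """Two-sided normal test of ``beta2 - beta1``."""
    if se1 <= 0 or se2 <= 0:
        raise InvalidParameterError("standard errors must be > 0")
    diff = beta2 - beta1
    se = float(np.sqrt(se1**2 + se2**2))
    z = diff / se
    return ContrastResult(diff=float(diff), se=se, z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def age_window_contrast(young: StudyEstimate, old: StudyEstimate) -> ContrastResult:
    """Frailty-vs-longevity contrast: late-window minus early-window log-HR."""
    return contrast_test(young.beta, young.se, old.beta, old.se)


def combined_homozygote_years(per_allele_years) -> float:
    """Predicted life-year gap between double-risk and double-protective
    homozygotes across loci, assuming additivity: ``2 * sum`` of the
    per-parental-allele reductions (one entry per locus for a given sex)."""
    vals = np.asarray(list(per_allele_years), dtype=float)
    return float(2.0 * vals.sum())
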