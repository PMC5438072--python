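"""Dosage-expectation arithmetic of the kin-cohort design.

The phenotyped individuals (parents) are not genotyped; the genotyped
offspring's dosage is a probabilistic proxy for each parent's. Under
Hardy-Weinberg equilibrium with counted-allele frequency ``p``:

* offspring dosage 0  -> expected parental dosage ``p`` (the non-inherited
  parental allele is the counted allele with probability ``p``);
* offspring dosage 2  -> expected parental dosage ``1 + p``;
* offspring dosage 1  -> the average, ``0.5 + p``.

The expected parental dosage is therefore *linear* in offspring dosage with
slope exactly 1/2 for every ``p``: effects measured per offspring allele are
half the effect per parental allele, and estimates are doubled at reporting
time to land on the natural (parental) scale. Doubling both the point
estimate and its standard error leaves z-statistics and p-values unchanged.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

#: regression slope of parental on offspring dosage under HWE — exactly 1/2
ATTENUATION = 0.5


def expected_parent_dosage(offspring_dose, p):
    """Expected parental dosage of the counted allele given offspring dosage.

    Accepts scalars or arrays for ``offspring_dose``.
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"allele frequency must be in (0, 1); got {p}")
    dose = np.asarray(offspring_dose)
    if np.any(~np.isin(dose, (0, 1, 2))):
        raise InvalidParameterError("offspring dosage must be in {0, 1, 2}")
    out = p + dose * ATTENUATION
    return float(out) if out.shape == () else out


def attenuation_slope(p: float) -> float:
    """Least-squares slope of expected parental dosage on offspring dosage
    under HWE offspring-dosage weights. Analytically 1/2 for every ``p``;
    computed explicitly so the identity is testable rather than asserted."""
    doses = np.array([0.0, 1.0, 2.0])
    weights = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    y = expected_parent_dosage(doses.astype(int), p)
    xbar = np.sum(weights * doses)
    ybar = np.sum(weights * y)
    cov = np.sum(weights * (doses - xbar) * (y - ybar))
    var = np.sum(weights * (doses - xbar) ** 2)
    return cov / var


def rescale_to_parent_scale(beta_offspring, se):
    """Double an offspring-scale estimate and its s.e. onto the parental scale."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InvalidParameterError("standard errors must be > 0")
    beta = np.asarray(beta_offspring, dtype=float) / ATTENUATION
    se2 = se / ATTENUATION
    if beta.shape == ():
        return float(beta), float(se2)
    return beta, se2


def rescale_to_offspring_scale(beta_parent, se_parent):
    """Inverse of :func:`rescale_to_parent_scale` (exact linear involution)."""
    se_parent = np.asarray(se_parent, dtype=float)
    if np.any(se_parent <= 0):
        raise InvalidParameterError("standard errors must be > 0")
    beta = np.asarray(beta_parent, dtype=float) * ATTENUATION
    se = se_parent * ATTENUATION
    if beta.shape == ():
        return float(beta), float(se)
    return beta, se
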