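"""Cox proportional-hazards engine on the age time-scale.

The model is ``h(t | Z) = h0(t) * exp(Z beta)`` with age as analysis time and
a common entry age (40 by default, 75 for the late age window). Because every
record enters at the same age, risk sets are the plain ``{tau_j >= t}`` sets
and no delayed-entry bookkeeping is needed.

Fitting is Newton-Raphson on the log partial likelihood with step-halving;
ties are handled by the Efron correction by default (Breslow available). The
baseline cumulative hazard always uses the Breslow estimator
``dH0(t_k) = d_k / sum_{j in R_k} exp(Z_j beta)``, under which the Martingale
residuals ``M_i = delta_i - H0(tau_i) exp(Z_i beta)`` sum to zero exactly for
*any* coefficient vector — the estimating-equation identity the residual scan
relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    ConvergenceError,
    DegenerateDataError,
    InvalidParameterError,
)

ENTRY_AGE = 40.0
AGE_SPLIT = 75.0

_TOL = 1e-9
_MAX_ITER = 50


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, covariance, Breslow baseline."""

    params: pd.Series
    cov_params: pd.DataFrame
    baseline: pd.DataFrame = field(repr=False)  # columns: age, cumhaz (step, right-cont.)
    entry_age: float
    ties: str
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    duration_col: str = "observed_age"
    event_col: str = "event"
    _zbar: pd.Series = field(default=None, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def summary(self) -> pd.DataFrame:
        from scipy import stats

        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": np.exp(self.params),
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def cumhaz_at(self, ages) -> np.ndarray:
        """Breslow baseline cumulative hazard evaluated at given ages."""
        ages = np.asarray(ages, dtype=float)
        grid = self.baseline["age"].to_numpy()
        ch = self.baseline["cumhaz"].to_numpy()
        idx = np.searchsorted(grid, ages, side="right")
        return np.where(idx > 0, ch[np.maximum(idx - 1, 0)], 0.0)

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor (as used in the baseline estimate)."""
        if len(self.params) == 0:
            return np.zeros(len(records))
        Z = records[list(self.params.index)].to_numpy(dtype=float)
        return (Z - self._zbar.to_numpy()) @ self.params.to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "covariates": list(self.params.index),
            "baseline": {
                "age": self.baseline["age"].tolist(),
                "cumhaz": self.baseline["cumhaz"].tolist(),
            },
            "entry_age": self.entry_age,
            "ties": self.ties,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n,
            "n_events": self.n_events,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "zbar": None if self._zbar is None else self._zbar.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoxFit":
        with open(path) as fh:
            payload = json.load(fh)
        covs = payload["covariates"]
        return cls(
            params=pd.Series(payload["params"], index=covs, dtype=float),
            cov_params=pd.DataFrame(payload["cov_params"], index=covs, columns=covs),
            baseline=pd.DataFrame(payload["baseline"]),
            entry_age=payload["entry_age"],
            ties=payload["ties"],
            loglik=payload["loglik"],
            loglik_null=payload["loglik_null"],
            n=payload["n"],
            n_events=payload["n_events"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            _zbar=None if payload["zbar"] is None else pd.Series(payload["zbar"], dtype=float),
        )


class _PartialLikelihood:
    """Grouped sufficient statistics for the Cox partial likelihood."""

    def __init__(self, t: np.ndarray, d: np.ndarray, Z: np.ndarray, ties: str):
        desc = np.argsort(-t, kind="stable")
        self.t = t[desc]
        self.d = d[desc]
        self.Z = Z[desc]
        self.ties = ties
        self.n, self.p = Z.shape
        event_times = np.unique(self.t[self.d == 1])[::-1]  # descending
        self.K = len(event_times)
        # index of last record (descending order) still at risk at each event time
        self.risk_end = np.searchsorted(-self.t, -event_times, side="right")
        self.death_mask = self.d == 1
        self.group = np.searchsorted(-event_times, -self.t[self.death_mask], side="left")
        self.d_k = np.bincount(self.group, minlength=self.K)
        # Efron expansion bookkeeping: one row per death, frac = l/d_k within group
        starts = np.concatenate([[0], np.cumsum(self.d_k)[:-1]])
        total = int(self.d_k.sum())
        self.gi = np.repeat(np.arange(self.K), self.d_k)
        order_within = np.arange(total) - np.repeat(starts, self.d_k)
        if ties == "efron":
            self.frac = order_within / np.repeat(self.d_k, self.d_k)
        elif ties == "breslow":
            self.frac = np.zeros(total)
        else:
            raise InvalidParameterError(f"unknown ties method {ties!r}")

    def _cumulants(self, w, wZ=None):
        S0 = np.cumsum(w)[self.risk_end - 1]
        S1 = None
        if wZ is not None:
            S1 = np.cumsum(wZ, axis=0)[self.risk_end - 1]
        return S0, S1

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.Z @ beta
        w = np.exp(eta)
        S0, _ = self._cumulants(w)
        wd = w[self.death_mask]
        s0 = np.bincount(self.group, weights=wd, minlength=self.K)
        phi0 = S0[self.gi] - self.frac * s0[self.gi]
        if np.any(phi0 <= 0) or not np.all(np.isfinite(phi0)):
            return -np.inf
        return float(eta[self.death_mask].sum() - np.log(phi0).sum())

    def loglik_grad_info(self, beta: np.ndarray):
        eta = self.Z @ beta
        w = np.exp(eta)
        wZ = w[:, None] * self.Z
        S0, S1 = self._cumulants(w, wZ)
        # pairwise second moments, cumulated then read at event times
        p = self.p
        S2 = np.empty((self.K, p, p))
        for i in range(p):
            for j in range(i + 1):
                c = np.cumsum(wZ[:, i] * self.Z[:, j])[self.risk_end - 1]
                S2[:, i, j] = c
                S2[:, j, i] = c
        wd = w[self.death_mask]
        Zd = self.Z[self.death_mask]
        s0 = np.bincount(self.group, weights=wd, minlength=self.K)
        s1 = np.stack(
            [np.bincount(self.group, weights=wd * Zd[:, j], minlength=self.K) for j in range(p)],
            axis=1,
        )
        s2 = np.empty((self.K, p, p))
        for i in range(p):
            for j in range(i + 1):
                c = np.bincount(self.group, weights=wd * Zd[:, i] * Zd[:, j], minlength=self.K)
                s2[:, i, j] = c
                s2[:, j, i] = c
        gi, frac = self.gi, self.frac
        phi0 = S0[gi] - frac * s0[gi]
        phi1 = S1[gi] - frac[:, None] * s1[gi]
        phi2 = S2[gi] - frac[:, None, None] * s2[gi]
        ll = float(eta[self.death_mask].sum() - np.log(phi0).sum())
        r = phi1 / phi0[:, None]
        grad = Zd.sum(axis=0) - r.sum(axis=0)
        info = (phi2 / phi0[:, None, None]).sum(axis=0) - r.T @ r
        return ll, grad, info

    def breslow_baseline(self, beta: np.ndarray):
        """(event_times ascending, dH0 increments) under the Breslow estimator."""
        w = np.exp(self.Z @ beta)
        S0, _ = self._cumulants(w)
        times_desc = self.t[self.death_mask][
            np.concatenate([[True], np.diff(self.group) > 0])
        ] if self.K else np.array([])
        # unique event times in descending order correspond to S0 order
        return times_desc[::-1], (self.d_k / S0)[::-1]


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    duration_col: str = "observed_age",
    event_col: str = "event",
    entry_age: float = ENTRY_AGE,
    ties: str = "efron",
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> CoxFit:
    """Fit the Cox model by maximum partial likelihood.

    ``covariates`` may be empty, giving the null model whose Breslow baseline
    is the Nelson-Aalen estimator. Covariates with zero variance carry no
    partial-likelihood information; their coefficients are fixed at 0 and
    their covariance entries set to NaN.
    """
    if covariates is None:
        covariates = [c for c in records.columns if c.startswith("covariate_")]
    t = records[duration_col].to_numpy(dtype=float)
    d = records[event_col].to_numpy(dtype=int)
    if np.any(t < entry_age):
        raise InvalidParameterError(
            f"{int((t < entry_age).sum())} records exit before the entry age {entry_age}"
        )
    if not np.isin(d, (0, 1)).all():
        raise InvalidParameterError("event indicator must be 0/1")
    n_events = int(d.sum())
    if n_events == 0:
        raise DegenerateDataError("no events in the data; the partial likelihood is flat")

    Z_full = records[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(t), 0))
    if np.isnan(Z_full).any():
        raise InvalidParameterError("covariates contain missing values; run QC first")
    zbar = Z_full.mean(axis=0) if covariates else np.array([])
    Zc = Z_full - zbar
    variances = Zc.var(axis=0) if covariates else np.array([])
    active = np.flatnonzero(variances > 0)

    pl = _PartialLikelihood(t, d, Zc[:, active], ties)
    beta_a = np.zeros(len(active))
    ll_null = pl.loglik(beta_a) if len(active) else _PartialLikelihood(t, d, Zc[:, :0], ties).loglik(
        np.zeros(0)
    )
    ll = ll_null
    n_iter = 0
    converged = len(active) == 0
    info = None
    for n_iter in range(1, max_iter + 1):
        if len(active) == 0:
            break
        ll_cur, grad, info = pl.loglik_grad_info(beta_a)
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _ in range(30):
            cand = beta_a + step * delta
            ll_new = pl.loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll_cur - 1e-14:
                break
            step /= 2.0
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter}; |grad| = {np.linalg.norm(grad):.3e}"
            )
        beta_a = cand
        if abs(ll_new - ll_cur) < tol * (abs(ll_cur) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged and len(active):
        _, grad, _ = pl.loglik_grad_info(beta_a)
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations; |grad| = {np.linalg.norm(grad):.3e}"
        )
    if len(active):
        ll, grad, info = pl.loglik_grad_info(beta_a)

    beta = np.zeros(len(covariates))
    cov = np.full((len(covariates), len(covariates)), np.nan)
    if len(active):
        beta[active] = beta_a
        cov_a = np.linalg.inv(info)
        cov[np.ix_(active, active)] = cov_a

    times, increments = pl.breslow_baseline(beta_a if len(active) else np.zeros(0))
    baseline = pd.DataFrame({"age": times, "cumhaz": np.cumsum(increments)})

    return CoxFit(
        params=pd.Series(beta, index=list(covariates)),
        cov_params=pd.DataFrame(cov, index=list(covariates), columns=list(covariates)),
        baseline=baseline,
        entry_age=entry_age,
        ties=ties,
        loglik=ll,
        loglik_null=ll_null,
        n=len(t),
        n_events=n_events,
        n_iter=n_iter,
        converged=converged,
        duration_col=duration_col,
        event_col=event_col,
        _zbar=pd.Series(zbar, index=list(covariates)),
    )


def martingale_residuals(fit: CoxFit, records: pd.DataFrame) -> np.ndarray:
    """``M_i = delta_i - H0(tau_i) * exp(eta_i)`` with the fit's Breslow baseline.

    Must be evaluated on the records the model was fitted to.
    """
    if len(records) != fit.n:
        raise ConsistencyError(
            f"fit has {fit.n} records but residuals requested for {len(records)}"
        )
    if not fit.converged:
        raise ConsistencyError("residuals requested from a non-converged fit")
    tau = records[fit.duration_col].to_numpy(dtype=float)
    delta = records[fit.event_col].to_numpy(dtype=int)
    eta = fit.linear_predictor(records)
    return delta - fit.cumhaz_at(tau) * np.exp(eta)


def km_life_years(
    records: pd.DataFrame,
    group: np.ndarray,
    horizon: float | None = None,
    entry_age: float = ENTRY_AGE,
    duration_col: str = "observed_age",
    event_col: str = "event",
) -> pd.DataFrame:
    """Restricted mean lifespan per genotype class from Kaplan-Meier curves.

    ``group`` assigns each record a genotype class (e.g. rounded dosage).
    Returns a table of class, n, deaths and expected age at death restricted
    to ``horizon`` (default: maximum observed age in the data). The between-
    class differences are per-offspring-allele life-years; doubling puts them
    on the parental scale.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    group = np.asarray(group)
    if len(group) != len(records):
        raise ConsistencyError("group labels must match records one-to-one")
    tau = records[duration_col].to_numpy(dtype=float)
    delta = records[event_col].to_numpy(dtype=int)
    if horizon is None:
        horizon = float(tau.max())
    rows = []
    for g in np.unique(group):
        mask = group == g
        t_g = tau[mask] - entry_age
        d_g = delta[mask]
        if len(t_g) == 0:
            continue
        if np.all(t_g <= 0):
            raise DegenerateDataError(f"genotype class {g!r} has no follow-up past entry")
        kmf = KaplanMeierFitter().fit(t_g, d_g)
        rmst = restricted_mean_survival_time(kmf, t=horizon - entry_age)
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "deaths": int(d_g.sum()),
                "expected_age": entry_age + float(rmst),
            }
        )
    if not rows:
        raise DegenerateDataError("no usable records in any genotype class")
    return pd.DataFrame(rows)


def per_allele_years(life_years: pd.DataFrame) -> float:
    """Mean difference in restricted mean lifespan between adjacent genotype
    classes (offspring scale; negative = counted allele shortens life)."""
    ly = life_years.sort_values("group")
    if len(ly) < 2:
        raise DegenerateDataError("need at least two genotype classes")
    diffs = np.diff(ly["expected_age"].to_numpy()) / np.diff(ly["group"].to_numpy())
    weights = (ly["n"].to_numpy()[1:] + ly["n"].to_numpy()[:-1]) / 2
    return float(np.average(diffs, weights=weights))


def truncate_age_window(
    records: pd.DataFrame,
    window: str,
    duration_col: str = "observed_age",
    event_col: str = "event",
) -> pd.DataFrame:
    """Transform records onto one of the frailty/longevity age windows.

    ``"40-75"``: exits capped at 75; deaths after 75 recoded as survivors.
    ``"75+"``: only records surviving past 75 are kept, with entry reset to
    75 (survival to 75 is complete by construction).
    """
    out = records.copy()
    if window in ("40-75", "40_75"):
        late = out[duration_col] > AGE_SPLIT
        out.loc[late, event_col] = 0
        out.loc[late, duration_col] = AGE_SPLIT
        return out
    if window in ("75+", "75plus"):
        return out.loc[out[duration_col] > AGE_SPLIT].copy()
    raise InvalidParameterError(f"unknown age window {window!r}; use '40-75' or '75+'")
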