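"""Gompertz hazard with sinusoidal seasonal modulation, and its estimation.

The daily mortality rate of a cohort member born on day-of-year ``b`` is

    lambda(t | b) = mu * exp(beta * (t + 365 - b)) * exp(alpha * cos(omega*t + theta))

with follow-up time ``t`` in days from January 1 of the year of the 60th
birthday, ``omega = 2*pi/365.25``, baseline scale ``mu > 0`` (per day),
exponential age slope ``beta > 0`` (per day), seasonal amplitude
``alpha >= 0`` on the log-hazard scale, and phase ``theta``.

Two estimators are provided:

* :func:`fit_poisson` — the working-horse piecewise-exponential
  approximation: daily death counts ``d_t`` among ``N_t`` at risk are treated
  as Poisson with ``log E(d_t) = log N_t + c + beta*t + a1*sin(omega*t) +
  a2*cos(omega*t)``, fit by Poisson regression.  The per-individual age
  offset ``365 - b`` is absorbed into the cohort-level intercept ``c``.
* :func:`fit_direct_ml` — exact maximization of the discrete-time survival
  likelihood with per-individual birth-day offsets; used to check that the
  Poisson aggregation loses essentially nothing.

The linear seasonal coefficients map to polar form by
``alpha = sqrt(a1^2 + a2^2)`` and ``theta = arctan(-a1/a2)``
(quadrant-aware), so that ``a1*sin + a2*cos = alpha*cos(omega*t + theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .cohort_data import Cohort, DailyCounts

#: Period of the seasonal modulation, days.
PERIOD = 365.25
#: Angular frequency of the seasonal modulation, radians per day.
OMEGA = 2.0 * np.pi / PERIOD

_PARAM_NAMES = ("log_mu", "beta", "a1", "a2")


def to_polar(a1: float, a2: float) -> tuple[float, float]:
    """Convert linear seasonal coefficients to (amplitude, phase).

    Returns ``alpha >= 0`` and ``theta`` in (-pi, pi] such that
    ``a1*sin(x) + a2*cos(x) == alpha*cos(x + theta)``; equivalently
    ``a2 = alpha*cos(theta)`` and ``a1 = -alpha*sin(theta)``.  The degenerate
    point ``a1 == a2 == 0`` returns ``(0.0, 0.0)`` (phase undefined).
    """
    alpha = float(np.hypot(a1, a2))
    if alpha == 0.0:
        return 0.0, 0.0
    theta = float(np.arctan2(-a1, a2))
    if theta == -np.pi:   # keep the phase in (-pi, pi]
        theta = np.pi
    return alpha, theta


def from_polar(alpha: float, theta: float) -> tuple[float, float]:
    """Inverse of :func:`to_polar`: (alpha, theta) -> (a1, a2)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return float(-alpha * np.sin(theta)), float(alpha * np.cos(theta))


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the seasonal Gompertz hazard.

    ``mu`` and ``beta`` are per-day rates; ``a1``/``a2`` are the sine/cosine
    coefficients on the log-hazard scale.  ``alpha`` and ``theta`` are the
    derived amplitude and phase.
    """

    mu: float
    beta: float
    a1: float = 0.0
    a2: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")

    @property
    def alpha(self) -> float:
        return to_polar(self.a1, self.a2)[0]

    @property
    def theta(self) -> float:
        return to_polar(self.a1, self.a2)[1]

    @classmethod
    def from_polar(cls, mu: float, beta: float, alpha: float, theta: float) -> "HazardParams":
        a1, a2 = from_polar(alpha, theta)
        return cls(mu=mu, beta=beta, a1=a1, a2=a2)


def hazard_rate(params: HazardParams, t, b=0.0) -> np.ndarray | float:
    """Evaluate the hazard ``lambda(t | b)`` (deaths per person-day).

    ``b`` is the birth day-of-year entering through the age offset
    ``365 - b``.  When ``params`` come from :func:`fit_poisson`, the cohort
    mean offset is already absorbed in ``mu`` and ``b=365`` (offset zero)
    gives the fitted cohort-level rate; :meth:`FitResult.cohort_hazard` does
    this for you.
    """
    t = np.asarray(t, dtype=float)
    age_offset = t + 365.0 - np.asarray(b, dtype=float)
    log_rate = (
        np.log(params.mu)
        + params.beta * age_offset
        + params.a1 * np.sin(OMEGA * t)
        + params.a2 * np.cos(OMEGA * t)
    )
    out = np.exp(log_rate)
    return float(out) if out.ndim == 0 else out


@dataclass
class FitResult:
    """Point estimates, covariance and bookkeeping from one cohort fit.

    ``covariance`` is 4x4 over ``(log mu, beta, a1, a2)`` — the estimation
    scale of the Poisson regression.  ``b_mean`` is the cohort mean birth
    day-of-year, needed to translate the cohort-level intercept back to
    individual age offsets.
    """

    params: HazardParams
    covariance: np.ndarray
    loglik: float
    n_days: int
    converged: bool
    b_mean: float = 365.0
    birth_year: int | None = None
    sex: str | None = None
    seasonality_pvalue: float | None = None
    method: str = "poisson"

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (4, 4):
            raise ValueError("covariance must be 4x4 over (log_mu, beta, a1, a2)")

    @property
    def se(self) -> np.ndarray:
        """Standard errors of ``(log mu, beta, a1, a2)``."""
        return np.sqrt(np.diag(self.covariance))

    @property
    def label(self) -> str:
        if self.birth_year is None:
            return "cohort"
        return f"{self.birth_year}-{self.sex}"

    def cohort_hazard(self, t) -> np.ndarray:
        """Fitted cohort-level hazard (mean age offset absorbed in ``mu``)."""
        return hazard_rate(self.params, t, b=365.0)

    def estimates(self) -> dict[str, float]:
        p = self.params
        return {
            "mu": p.mu,
            "beta": p.beta,
            "a1": p.a1,
            "a2": p.a2,
            "alpha": p.alpha,
            "theta": p.theta,
        }


def _design(t: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(t), t, np.sin(OMEGA * t), np.cos(OMEGA * t)]
    )


def fit_poisson(daily_counts: DailyCounts) -> FitResult:
    """Fit the seasonal Gompertz hazard by Poisson regression on daily counts.

    Days with ``N_t = 0`` (after cohort extinction) are dropped because the
    exposure offset ``log N_t`` is undefined.  The covariance is the inverse
    observed information at the optimum, as returned by the GLM fit.  The
    reported ``seasonality_pvalue`` is the likelihood-ratio test of
    ``a1 = a2 = 0`` against the full model (2 degrees of freedom).
    """
    mask = daily_counts.N > 0
    t = daily_counts.t_grid[mask].astype(float)
    y = daily_counts.d[mask].astype(float)
    if y.sum() == 0:
        raise ValueError(
            f"no deaths on the follow-up grid for {daily_counts.cohort_label}; "
            "the hazard is not identifiable"
        )
    offset = np.log(daily_counts.N[mask].astype(float))
    X = _design(t)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    null_res = sm.GLM(y, X[:, :2], family=sm.families.Poisson(), offset=offset).fit()
    lr = 2.0 * (res.llf - null_res.llf)
    p_seas = float(stats.chi2.sf(max(lr, 0.0), df=2))

    c, beta, a1, a2 = res.params
    return FitResult(
        params=HazardParams(mu=float(np.exp(c)), beta=float(beta), a1=float(a1), a2=float(a2)),
        covariance=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n_days=int(mask.sum()),
        converged=bool(res.converged),
        b_mean=daily_counts.b_mean,
        birth_year=daily_counts.birth_year,
        sex=daily_counts.sex,
        seasonality_pvalue=p_seas,
        method="poisson",
    )


# ---------------------------------------------------------------------------
# Direct maximum likelihood with per-individual birth-day offsets
# ---------------------------------------------------------------------------

@dataclass
class _DirectData:
    """Person-level data grouped by birth day-of-year for fast likelihood."""

    T: int                      # last grid day (inclusive)
    t: np.ndarray               # grid 0..T
    sin_t: np.ndarray
    cos_t: np.ndarray
    b_unique: np.ndarray        # distinct birth days-of-year
    n_cens: np.ndarray          # censored persons per distinct b
    ib: np.ndarray              # death cells: index into b_unique
    td: np.ndarray              # death cells: day of death
    cnt: np.ndarray             # death cells: number of deaths
    b_mean: float

    @classmethod
    def from_cohort(cls, cohort: Cohort, end_age_year: int) -> "_DirectData":
        import pandas as pd
        from datetime import date as _date

        t0 = pd.Timestamp(cohort.t0)
        grid_end = pd.Timestamp(_date(cohort.birth_year + end_age_year, 12, 31))
        T = (grid_end - t0).days
        death_t = (cohort.members["death_date"] - t0).dt.days.to_numpy()
        b = cohort.birth_days()
        b_unique, b_idx = np.unique(b, return_inverse=True)

        censored = death_t > T
        n_cens = np.bincount(b_idx[censored], minlength=len(b_unique))
        cells, cnt = np.unique(
            np.column_stack([b_idx[~censored], death_t[~censored]]), axis=0, return_counts=True
        )
        t = np.arange(T + 1, dtype=float)
        return cls(
            T=T,
            t=t,
            sin_t=np.sin(OMEGA * t),
            cos_t=np.cos(OMEGA * t),
            b_unique=b_unique.astype(float),
            n_cens=n_cens.astype(float),
            ib=cells[:, 0],
            td=cells[:, 1],
            cnt=cnt.astype(float),
            b_mean=float(b.mean()),
        )


def _direct_nll_grad(x: np.ndarray, data: _DirectData) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient for the exact discrete-day model.

    Parameters on the optimization scale: ``(c, beta*365.25, a1, a2)`` where
    ``log lambda_b(t) = c + beta*(t + 365 - b) + a1*sin + a2*cos``.
    """
    c, beta_y, a1, a2 = x
    beta = beta_y / PERIOD
    base = np.exp(c + beta * data.t + a1 * data.sin_t + a2 * data.cos_t)
    off = 365.0 - data.b_unique          # per-b age offset, days
    f = np.exp(beta * off)

    # exclusive cumulative sums: C[t] = sum_{s<t} base[s] etc.
    def excum(w):
        cs = np.concatenate([[0.0], np.cumsum(w)])
        return cs[:-1], cs[-1]

    C, C_end = excum(base)
    Ct, Ct_end = excum(data.t * base)
    Cs, Cs_end = excum(data.sin_t * base)
    Cc, Cc_end = excum(data.cos_t * base)

    fb = f[data.ib]
    lam = fb * base[data.td]
    em1 = np.expm1(lam)
    ll = (
        np.sum(data.cnt * (np.log(-np.expm1(-lam)) - fb * C[data.td]))
        - np.sum(data.n_cens * f * C_end)
    )

    # d/dp log(1 - e^{-lam}) = (lam / (e^lam - 1)) * dlog(lam)/dp
    g = data.cnt * lam / em1
    offb = off[data.ib]
    grad_c = np.sum(g) - np.sum(data.cnt * fb * C[data.td]) - np.sum(data.n_cens * f * C_end)
    grad_beta = (
        np.sum(g * (data.td + offb))
        - np.sum(data.cnt * fb * (offb * C[data.td] + Ct[data.td]))
        - np.sum(data.n_cens * f * (off * C_end + Ct_end))
    )
    grad_a1 = (
        np.sum(g * data.sin_t[data.td])
        - np.sum(data.cnt * fb * Cs[data.td])
        - np.sum(data.n_cens * f * Cs_end)
    )
    grad_a2 = (
        np.sum(g * data.cos_t[data.td])
        - np.sum(data.cnt * fb * Cc[data.td])
        - np.sum(data.n_cens * f * Cc_end)
    )
    grad = np.array([grad_c, grad_beta / PERIOD, grad_a1, grad_a2])
    return -ll, -grad


def fit_direct_ml(
    cohort: Cohort,
    end_age_year: int = 95,
    fix: dict[str, float] | None = None,
) -> FitResult:
    """Maximize the exact discrete-day survival likelihood for a cohort.

    Each person contributes survival factors ``exp(-lambda_b(t))`` for every
    day alive on the grid and ``1 - exp(-lambda_b(t))`` for the day of death;
    deaths after the grid end are right-censored.  Unlike
    :func:`fit_poisson`, the per-individual age offset ``365 - b_i`` is kept
    exact rather than absorbed into the intercept.  The reported ``mu`` is
    translated to the cohort scale ``exp(c + beta*(365 - b_mean))`` so the
    two estimators are directly comparable.

    ``fix`` pins parameters by name (``mu``, ``beta``, ``a1``, ``a2``) at
    given values, e.g. ``fix={"beta": 0, "a1": 0, "a2": 0}`` fits a constant
    hazard.
    """
    if cohort.is_empty:
        raise ValueError("cannot fit an empty cohort")
    data = _DirectData.from_cohort(cohort, end_age_year)
    if data.cnt.sum() == 0:
        raise ValueError("no deaths on the follow-up grid; hazard not identifiable")

    # crude init: overall rate; mild age slope
    exposure = np.sum(np.minimum(data.td.repeat(data.cnt.astype(int)), data.T) + 1.0) + np.sum(
        data.n_cens * (data.T + 1.0)
    )
    x0 = np.array([np.log(data.cnt.sum() / exposure), 0.05, 0.0, 0.0])

    fix = dict(fix or {})
    fixed_idx: dict[int, float] = {}
    for name, val in fix.items():
        i = _PARAM_NAMES.index("log_mu" if name == "mu" else name)
        fixed_idx[i] = np.log(val) if name == "mu" else (val * PERIOD if name == "beta" else val)
    free = np.array([i for i in range(4) if i not in fixed_idx])
    if len(free) == 0:
        raise ValueError("at least one parameter must be free")

    def embed(xf):
        x = np.empty(4)
        x[free] = xf
        for i, v in fixed_idx.items():
            x[i] = v
        return x

    def fun(xf):
        val, grad = _direct_nll_grad(embed(xf), data)
        return val, grad[free]

    res = optimize.minimize(
        fun, x0[free], jac=True, method="L-BFGS-B",
        options={"ftol": 1e-14, "gtol": 1e-8, "maxiter": 500},
    )
    x = embed(res.x)
    c, beta_y, a1, a2 = x
    beta = beta_y / PERIOD

    # observed information over free params by central differences of the gradient
    h = 1e-5 * np.maximum(np.abs(res.x), 1.0)
    k = len(free)
    H = np.zeros((k, k))
    for j in range(k):
        xp = res.x.copy(); xp[j] += h[j]
        xm = res.x.copy(); xm[j] -= h[j]
        H[:, j] = (fun(xp)[1] - fun(xm)[1]) / (2 * h[j])
    H = 0.5 * (H + H.T)
    cov_free = np.linalg.inv(H)
    cov_opt = np.zeros((4, 4))
    cov_opt[np.ix_(free, free)] = cov_free

    # to reporting scale: (log mu_cohort, beta, a1, a2) with
    # log mu_cohort = c + beta*(365 - b_mean) and beta = beta_y / 365.25
    A = np.eye(4)
    A[0, 1] = (365.0 - data.b_mean) / PERIOD
    A[1, 1] = 1.0 / PERIOD
    cov = A @ cov_opt @ A.T

    mu_cohort = float(np.exp(c + beta * (365.0 - data.b_mean)))
    return FitResult(
        params=HazardParams(mu=mu_cohort, beta=float(beta), a1=float(a1), a2=float(a2)),
        covariance=cov,
        loglik=float(-res.fun),
        n_days=data.T + 1,
        converged=bool(res.success),
        b_mean=data.b_mean,
        birth_year=cohort.birth_year,
        sex=cohort.sex,
        method="direct_ml",
    )


def direct_loglik(cohort: Cohort, params: HazardParams, end_age_year: int = 95) -> float:
    """Exact discrete-day survival log-likelihood at given parameters.

    ``params.mu`` is interpreted on the individual scale of the hazard
    formula (offset ``365 - b_i`` applied per person, not absorbed).
    """
    data = _DirectData.from_cohort(cohort, end_age_year)
    x = np.array([np.log(params.mu), params.beta * PERIOD, params.a1, params.a2])
    nll, _ = _direct_nll_grad(x, data)
    return -nll
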