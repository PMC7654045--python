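"""Within-year magnitude and timing of seasonal mortality.

The magnitude of seasonality in a cohort is summarized by the ratio of the
highest to the lowest mortality rate within a year.  Because the hazard is
``mu * exp(beta*(t + offset)) * exp(alpha*cos(omega*t + theta))``, the peak
and trough of the modulation are half a period (182.625 days) apart and the
exponential age trend drifts between them, giving the closed form

    h = exp(2*alpha - 182.625*beta)

Confidence intervals are parametric-bootstrap: ``(beta, a1, a2)`` are drawn
from a multivariate normal with the fit's mean and covariance (the intercept
is marginalized out — it cancels from the ratio), pushed through the polar
transform and the formula above, and the empirical percentiles are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hazard_model import OMEGA, PERIOD, FitResult, HazardParams, to_polar

#: Half a seasonal period, days: the peak-to-trough lag.
HALF_PERIOD = PERIOD / 2.0


@dataclass
class SeasonalitySummary:
    """Peak-to-trough mortality rate ratio for one cohort, with its CI."""

    cohort_label: str
    h: float
    ci_low: float
    ci_high: float
    peak_day: float
    level: float
    n_samples: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.h <= self.ci_high):
            raise ValueError(
                f"point estimate {self.h} outside CI [{self.ci_low}, {self.ci_high}]"
            )


def rate_ratio(params: HazardParams) -> float:
    """Within-year peak/trough hazard ratio, ``exp(2*alpha - 182.625*beta)``.

    The ``-182.625*beta`` term accounts for the exponential age drift over
    the half year separating the seasonal peak from the following trough.
    Invariant to ``mu`` and ``theta``.
    """
    return float(np.exp(2.0 * params.alpha - HALF_PERIOD * params.beta))


def rate_ratio_ci(
    fit: FitResult,
    level: float = 0.95,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the rate ratio.

    Draws ``(beta, a1, a2)`` from the asymptotic multivariate normal of the
    fit, maps each draw through the polar transform and :func:`rate_ratio`,
    and returns the ``(1-level)/2`` and ``1-(1-level)/2`` empirical
    percentiles.  Reproducible given ``seed``.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    mean = np.array([fit.params.beta, fit.params.a1, fit.params.a2])
    cov = fit.covariance[1:4, 1:4]
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance not symmetric")
    eigvals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eigvals.min() < -1e-12 * max(eigvals.max(), 1.0):
        raise ValueError("covariance not positive semi-definite")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_samples, method="eigh")
    beta_s, a1_s, a2_s = draws.T
    alpha_s = np.hypot(a1_s, a2_s)
    h_s = np.exp(2.0 * alpha_s - HALF_PERIOD * beta_s)
    lo, hi = np.quantile(h_s, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def peak_day(theta: float, alpha: float | None = None) -> float:
    """Day of year (from January 1) at which the seasonal modulation peaks.

    The cosine ``cos(omega*t + theta)`` attains +1 at
    ``t* = (-theta/omega) mod 365.25``.  With ``alpha = 0`` the modulation is
    flat and the peak undefined.
    """
    if alpha is not None and alpha == 0.0:
        raise ValueError("peak day undefined for alpha = 0 (no seasonal modulation)")
    day = float((-theta / OMEGA) % PERIOD)
    return 0.0 if day >= PERIOD else day   # (-eps) % PERIOD can round to PERIOD


def summarize_seasonality(
    fit: FitResult,
    level: float = 0.95,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> SeasonalitySummary:
    """Rate ratio, CI and peak timing for one fitted cohort."""
    h = rate_ratio(fit.params)
    lo, hi = rate_ratio_ci(fit, level=level, n_samples=n_samples, seed=seed)
    alpha, theta = to_polar(fit.params.a1, fit.params.a2)
    pk = peak_day(theta) if alpha > 0 else float("nan")
    return SeasonalitySummary(
        cohort_label=fit.label,
        h=h,
        ci_low=min(lo, h),
        ci_high=max(hi, h),
        peak_day=pk,
        level=level,
        n_samples=n_samples,
        seed=seed,
    )
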