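"""End-to-end cohort analysis: records -> cohorts -> fits -> summaries.

Runs the full chain for every sex-specific birth cohort in range: build the
daily risk-set/death series, fit the seasonal Gompertz hazard by Poisson
regression, summarize the winter/summer rate ratio with bootstrap CIs, and
compute actual and counterfactual (lower-bound) life expectancy at 60.
Cohorts whose fit fails are logged and skipped; they never abort the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_data, hazard_model, life_expectancy, seasonality

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    out_dir: str
    sexes: tuple[str, ...] = ("male", "female")
    birth_year_start: int = 1800
    birth_year_end: int = 1900
    end_age: int = 95
    ci_level: float = 0.95
    ci_samples: int = 10_000
    seed: int = 0
    b_policy: str = "mean"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.birth_year_start > self.birth_year_end:
            raise ValueError("birth_year_start must not exceed birth_year_end")
        if not 60 < self.end_age:
            raise ValueError("end_age must exceed the follow-up start age of 60")


def running_mean(series, width: int = 60) -> np.ndarray:
    """Centered moving average of fixed width, truncated at the edges.

    Each point is replaced by the mean of the ``width`` surrounding points
    (fewer near the series ends).  Used only for visualization of daily
    rates, never in estimation.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        raise ValueError("cannot smooth an empty series")
    return s.rolling(window=width, center=True, min_periods=1).mean().to_numpy()


def _cohort_seed(master: int, index: int) -> int:
    """Deterministic per-cohort bootstrap seed below 2**31."""
    return int(np.random.SeedSequence(master, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def analyze_cohort(
    records: pd.DataFrame,
    birth_year: int,
    sex: str,
    *,
    end_age: int = 95,
    ci_level: float = 0.95,
    ci_samples: int = 10_000,
    seed: int | None = None,
    b_policy: str = "mean",
):
    """Fit and summarize a single cohort; returns (counts, fit, seas, le).

    Raises on empty cohorts or non-identifiable fits; ``run_pipeline``
    catches these per cohort.
    """
    cohort = cohort_data.build_cohort(records, birth_year, sex)
    counts = cohort_data.build_daily_counts(cohort, end_age_year=end_age)
    fit = hazard_model.fit_poisson(counts)
    seas = seasonality.summarize_seasonality(
        fit, level=ci_level, n_samples=ci_samples, seed=seed
    )
    le = life_expectancy.cohort_e60(fit, cohort=cohort, b_policy=b_policy)
    return counts, fit, seas, le


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write per-cohort tables plus a manifest.

    Outputs in ``config.out_dir``: ``fits.csv``, ``seasonality.csv``,
    ``life_expectancy.csv``, ``summary.csv`` and ``manifest.json``.  Returns
    the tables as DataFrames keyed by the same names.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = cohort_data.read_persons(config.input_path)

    fit_rows, seas_rows, le_rows, failures = [], [], [], []
    keep_counts = {}
    idx = 0
    for sex in config.sexes:
        for year in range(config.birth_year_start, config.birth_year_end + 1):
            idx += 1
            try:
                counts, fit, seas, le = analyze_cohort(
                    records, year, sex,
                    end_age=config.end_age,
                    ci_level=config.ci_level,
                    ci_samples=config.ci_samples,
                    seed=_cohort_seed(config.seed, idx),
                    b_policy=config.b_policy,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("cohort %d-%s skipped: %s", year, sex, exc)
                failures.append({"birth_year": year, "sex": sex, "error": str(exc)})
                continue
            se = fit.se
            fit_rows.append(
                {
                    "birth_year": year, "sex": sex,
                    **fit.estimates(),
                    "se_log_mu": se[0], "se_beta": se[1], "se_a1": se[2], "se_a2": se[3],
                    "loglik": fit.loglik, "n_days": fit.n_days,
                    "converged": fit.converged,
                    "seasonality_pvalue": fit.seasonality_pvalue,
                    "b_mean": fit.b_mean,
                }
            )
            seas_rows.append(
                {
                    "birth_year": year, "sex": sex,
                    "h": seas.h, "ci_low": seas.ci_low, "ci_high": seas.ci_high,
                    "peak_day": seas.peak_day, "level": seas.level,
                    "n_samples": seas.n_samples, "seed": seas.seed,
                }
            )
            le_rows.append(
                {
                    "birth_year": year, "sex": sex,
                    "e_observed": le.e_observed, "e_model": le.e_model,
                    "e_lower_bound": le.e_lower_bound,
                    "contribution": le.contribution, "b_policy": le.b_policy,
                }
            )
            keep_counts[(year, sex)] = {
                "n_included": int(counts.N[0]),
                "n_deaths_on_grid": int(counts.d.sum()),
                "n_censored": counts.n_censored,
            }

    tables = {
        "fits": pd.DataFrame(fit_rows),
        "seasonality": pd.DataFrame(seas_rows),
        "life_expectancy": pd.DataFrame(le_rows),
    }
    if not tables["fits"].empty:
        summary = tables["fits"][["birth_year", "sex", "alpha", "theta", "beta"]].merge(
            tables["seasonality"][["birth_year", "sex", "h", "ci_low", "ci_high", "peak_day"]],
            on=["birth_year", "sex"],
        ).merge(
            tables["life_expectancy"].drop(columns="b_policy"), on=["birth_year", "sex"]
        )
    else:
        summary = pd.DataFrame()
    tables["summary"] = summary

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    import seasonmort

    manifest = {
        "config": asdict(config),
        "package_version": seasonmort.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_records_read": int(len(records)),
        "n_cohorts_fit": len(fit_rows),
        "n_cohorts_failed": len(failures),
        "failures": failures,
        "cohort_counts": {f"{y}-{s}": v for (y, s), v in keep_counts.items()},
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    tables["manifest"] = manifest

    if config.make_plots and not summary.empty:
        make_plots(tables, out)
    return tables


def make_plots(tables: dict, out_dir) -> None:
    """Rate-ratio trajectories with CI bands and life-expectancy curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    seas = tables["seasonality"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sex, grp in seas.groupby("sex"):
        ax.plot(grp["birth_year"], grp["h"], label=sex)
        ax.fill_between(grp["birth_year"], grp["ci_low"], grp["ci_high"], alpha=0.3)
    ax.set_xlabel("birth year")
    ax.set_ylabel("winter/summer mortality rate ratio h")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "rate_ratio.png", dpi=150)
    plt.close(fig)

    le = tables["life_expectancy"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=False)
    for ax, sex in zip(axes, ("male", "female")):
        grp = le[le["sex"] == sex]
        if grp.empty:
            continue
        ax.plot(grp["birth_year"], grp["e_observed"], ".", color="k", label="observed")
        ax.plot(grp["birth_year"], grp["e_model"], color="m", label="model")
        ax.plot(grp["birth_year"], grp["e_lower_bound"], color="g", label="lower bound")
        ax.set_title(sex)
        ax.set_xlabel("birth year")
        ax.set_ylabel("life expectancy at 60 (years of age)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "life_expectancy.png", dpi=150)
    plt.close(fig)


def plot_daily_rates(counts, fit, out_path, smooth_width: int = 60) -> None:
    """Observed daily mortality rates (smoothed) with the model overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = counts.N > 0
    rate = np.full(counts.n_days, np.nan)
    rate[mask] = counts.d[mask] / counts.N[mask]
    smoothed = running_mean(np.nan_to_num(rate), width=smooth_width)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(counts.dates(), smoothed, color="0.3", lw=0.8, label="observed (smoothed)")
    ax.plot(counts.dates(), fit.cohort_hazard(counts.t_grid.astype(float)), color="m",
            lw=1.2, label="model")
    ax.set_yscale("log")
    ax.set_ylabel("deaths per person-day")
    ax.set_title(counts.cohort_label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
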