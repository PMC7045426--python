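"""Replication-level performance metrics and the replicated benchmark.

A benchmark run fixes one complete dataset, then for every missingness rate
and replication draws a fresh MAR (or MCAR) mask, applies each handling
strategy and computes three summary statistics of the completed data —
the total-score mean, its sample SD, and the Pearson correlation between
total score and a configured covariate (age by default).  Writing y_ij for
the statistic after method j in replication i and y_i0 for its value on the
complete data, the per-cell error summaries are

    absolute deviation   |y_ij - y_i0|        (reported as mean +/- SD over reps)
    RMSE                 sqrt(sum_i (y_ij - y_i0)^2 / n)
    average relative     sum_i ((y_i0 - y_ij) / y_i0) / n    (signed)

For MI the summary statistic of a replication is the mean of the statistic
over the m completed datasets; for deletion it is computed on the
complete-case subset.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amputation import AmputedDataset, MissingnessPlan, ampute
from .datasets import SurveyDataset
from .imputation import (
    CompletedData,
    complete_case,
    impute_hotdeck,
    impute_mi,
    impute_mode,
)
from .specs import CovariateSpec, find_covariate

__all__ = [
    "summary_statistics",
    "completed_summary",
    "absolute_deviation",
    "rmse",
    "average_relative_error",
    "apply_method",
    "run_benchmark",
    "evaluation_table",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("deletion", "mode", "hotdeck", "mi")
STATISTICS = ("mean", "sd", "corr")


def summary_statistics(
    dataset: SurveyDataset,
    corr_var: str = "age",
    covariate_specs: Sequence[CovariateSpec] | None = None,
) -> dict[str, float]:
    """(mean, sample SD, Pearson corr) of total scores on complete data.

    ``corr_var`` names the covariate paired with the total score; categorical
    covariates are trend-coded through their spec before correlating.
    """
    totals = dataset.total_scores().to_numpy(dtype=float)
    if totals.size < 2:
        raise ValueError("need at least 2 respondents for SD and correlation")
    if corr_var not in dataset.covariates.columns:
        raise ValueError(f"correlation covariate {corr_var!r} not in dataset")
    col = dataset.covariates[corr_var]
    if covariate_specs is not None:
        x = find_covariate(covariate_specs, corr_var).numeric(col)
    else:
        x = np.asarray(col, dtype=float)
    return {
        "mean": float(totals.mean()),
        "sd": float(totals.std(ddof=1)),
        "corr": float(np.corrcoef(totals, x)[0, 1]),
    }


def completed_summary(
    completed: CompletedData,
    corr_var: str = "age",
    covariate_specs: Sequence[CovariateSpec] | None = None,
) -> dict[str, float]:
    """Summary statistics of a strategy's output; MI averages over its m sets."""
    per_set = [
        summary_statistics(ds, corr_var=corr_var, covariate_specs=covariate_specs)
        for ds in completed.datasets
    ]
    return {s: float(np.mean([p[s] for p in per_set])) for s in STATISTICS}


# ------------------------------------------------------------------- metrics


def absolute_deviation(y_ij: float, y_i0: float) -> float:
    return abs(y_ij - y_i0)


def rmse(pairs: Iterable[tuple[float, float]]) -> float:
    """sqrt( sum_i (y_ij - y_i0)^2 / n )."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("rmse needs at least one (y_ij, y_i0) pair")
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def average_relative_error(pairs: Iterable[tuple[float, float]]) -> float:
    """Signed mean of (y_i0 - y_ij) / y_i0; errors of opposite sign cancel."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("average_relative_error needs at least one pair")
    y_ij, y_i0 = arr[:, 0], arr[:, 1]
    if np.any(y_i0 == 0):
        raise ValueError("average relative error undefined when a reference value is 0")
    return float(np.mean((y_i0 - y_ij) / y_i0))


# ----------------------------------------------------------------- benchmark


def apply_method(
    method: str,
    amputed: AmputedDataset,
    covariate_specs: Sequence[CovariateSpec],
    donor_class_vars: Sequence[str] = (),
    mi_m: int = 20,
    mi_iter: int = 10,
    k_pmm: int = 5,
    seed: int = 0,
) -> CompletedData:
    """Dispatch one handling strategy by name."""
    if method == "deletion":
        return complete_case(amputed)
    if method == "mode":
        return impute_mode(amputed)
    if method == "hotdeck":
        return impute_hotdeck(amputed, donor_class_vars, seed=seed)
    if method == "mi":
        return impute_mi(
            amputed, covariate_specs, m=mi_m, n_iter=mi_iter, k_pmm=k_pmm, seed=seed
        )
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_benchmark(
    dataset: SurveyDataset,
    covariate_specs: Sequence[CovariateSpec],
    rates: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
    methods: Sequence[str] = METHODS,
    n_reps: int = 50,
    master_seed: int = 0,
    mechanism: str = "MAR",
    driver_slopes: Mapping[str, float] | None = None,
    donor_class_vars: Sequence[str] = (),
    corr_var: str = "age",
    mi_m: int = 20,
    mi_iter: int = 10,
    k_pmm: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full (rate x replication x method) factorial on one dataset.

    Returns ``(records, table)``: the long-format per-replication records
    (columns rate, method, replication, statistic, y0, y) and the aggregated
    evaluation table from :func:`evaluation_table`.  Fully deterministic
    given ``master_seed``; replication r at rate index q uses replication
    index ``q * n_reps + r`` of the amputation plan and a matching
    imputation sub-seed.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    baseline = summary_statistics(dataset, corr_var=corr_var, covariate_specs=covariate_specs)

    rows: list[dict] = []
    for q, rate in enumerate(rates):
        plan0 = MissingnessPlan(
            mechanism=mechanism,
            target_rate=rate,
            driver_slopes=dict(driver_slopes or {}),
            seed=master_seed,
        )
        # calibrate the MAR intercept once per rate; the dataset is fixed
        if mechanism == "MAR":
            probe = ampute(dataset, plan0, covariate_specs)
            plan0 = probe.plan
        for r in range(n_reps):
            rep_index = q * n_reps + r
            amputed = ampute(
                dataset, plan0.with_replication(rep_index), covariate_specs
            )
            for method in methods:
                try:
                    completed = apply_method(
                        method,
                        amputed,
                        covariate_specs,
                        donor_class_vars=donor_class_vars,
                        mi_m=mi_m,
                        mi_iter=mi_iter,
                        k_pmm=k_pmm,
                        seed=master_seed * 100003 + rep_index,
                    )
                except Exception:
                    logger.exception(
                        "benchmark cell failed: rate=%s replication=%d method=%s",
                        rate, r, method,
                    )
                    raise
                stats = completed_summary(
                    completed, corr_var=corr_var, covariate_specs=covariate_specs
                )
                for stat_name in STATISTICS:
                    rows.append(
                        {
                            "rate": rate,
                            "method": method,
                            "replication": r,
                            "statistic": stat_name,
                            "y0": baseline[stat_name],
                            "y": stats[stat_name],
                        }
                    )
    records = pd.DataFrame(rows)
    return records, evaluation_table(records)


def evaluation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replication records into the per-cell evaluation table.

    One row per (method, rate, statistic) with the mean and SD of the
    absolute deviation across replications, the RMSE, the signed average
    relative error and the replication count.
    """
    required = {"rate", "method", "replication", "statistic", "y0", "y"}
    if not required.issubset(records.columns):
        raise ValueError(f"records lack columns {sorted(required - set(records.columns))}")
    out = []
    for (method, rate, stat), grp in records.groupby(
        ["method", "rate", "statistic"], sort=True
    ):
        dev = (grp["y"] - grp["y0"]).abs()
        pairs = list(zip(grp["y"], grp["y0"]))
        out.append(
            {
                "method": method,
                "rate": rate,
                "statistic": stat,
                "abs_dev_mean": float(dev.mean()),
                "abs_dev_sd": float(dev.std(ddof=1)) if len(dev) > 1 else np.nan,
                "rmse": rmse(pairs),
                "avg_rel_error": average_relative_error(pairs),
                "n_replications": int(len(grp)),
            }
        )
    return pd.DataFrame(out)
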