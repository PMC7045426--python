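"""Validation battery run identically on complete and imputed data.

Mirrors how a cross-sectional mental-health survey is actually analysed:
per-covariate group comparisons of the total score (pooled two-sample t for
binary covariates, one-way ANOVA F otherwise) and a multiple logistic
regression of the dichotomized total score (1 = total >= cutoff) on
trend-coded covariates, reported as odds ratios with Wald 95% CIs.

For multiple imputation, descriptive statistics and test statistics are the
average of the per-imputation values, while logistic coefficients are pooled
by Rubin's rules with t-based confidence intervals on the Rubin degrees of
freedom.  ``compare_analyses`` lines the imputed arms up against the
complete-data arm and tabulates the deltas.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import SurveyDataset
from .imputation import CompletedData, rubins_pool
from .specs import CovariateSpec, find_covariate

__all__ = [
    "dichotomize_score",
    "group_tests",
    "group_tests_completed",
    "fit_logistic",
    "logistic_on_dataset",
    "pooled_logistic_mi",
    "compare_analyses",
]

ALPHA = 0.05
_Z975 = 1.959963984540054


def dichotomize_score(totals: Sequence[float] | pd.Series, cutoff: int) -> np.ndarray:
    """1 where total >= cutoff, else 0 (e.g. high vs low self-esteem at 30)."""
    return (np.asarray(totals, dtype=float) >= cutoff).astype(int)


# ------------------------------------------------------------- group tests


def group_tests(
    dataset: SurveyDataset,
    group_vars: Sequence[str],
) -> pd.DataFrame:
    """Per-covariate group means/SDs of the total score plus a t or F test.

    Two-level covariates get the pooled-variance two-sample t statistic;
    covariates with more levels get the one-way ANOVA F.  Returns one row
    per (variable, level) carrying the shared test statistic.
    """
    totals = dataset.total_scores().to_numpy(dtype=float)
    rows = []
    for var in group_vars:
        if var not in dataset.covariates.columns:
            raise ValueError(f"grouping covariate {var!r} not in dataset")
        col = dataset.covariates[var]
        levels = (
            [lv for lv in col.cat.categories if (col == lv).any()]
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(pd.unique(col.dropna()))
        )
        groups = [totals[(col == lv).to_numpy()] for lv in levels]
        for lv, g in zip(levels, groups):
            if g.size < 2:
                raise ValueError(f"group {var}={lv!r} has fewer than 2 observations")
        if len(groups) < 2:
            raise ValueError(f"covariate {var!r} has a single observed level")
        if len(groups) == 2:
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
            test = "t"
        else:
            stat, p = stats.f_oneway(*groups)
            test = "F"
        for lv, g in zip(levels, groups):
            rows.append(
                {
                    "variable": var,
                    "level": str(lv),
                    "n": int(g.size),
                    "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)),
                    "test": test,
                    "statistic": float(stat),
                    "p_value": float(p),
                    "significant": bool(p < ALPHA),
                }
            )
    return pd.DataFrame(rows)


def group_tests_completed(
    completed: CompletedData,
    group_vars: Sequence[str],
    stacked: bool = False,
) -> pd.DataFrame:
    """Group tests on a strategy's output.

    MI default: run the battery in each completed dataset and average the
    means, SDs and test statistics across the m sets (p-values and the
    significance flag come from the averaged statistic's per-set votes:
    significant iff the majority of sets reject).  ``stacked=True`` instead
    concatenates the m sets and tests once — kept behind a flag because it
    overstates the effective sample size.
    """
    if completed.m == 1:
        return group_tests(completed.datasets[0], group_vars)
    if stacked:
        big_items = pd.concat([d.items for d in completed.datasets], ignore_index=True)
        big_cov = pd.concat([d.covariates for d in completed.datasets], ignore_index=True)
        stacked_ds = SurveyDataset(
            ids=np.arange(1, len(big_items) + 1),
            items=big_items,
            covariates=big_cov,
            scale=completed.datasets[0].scale,
        )
        return group_tests(stacked_ds, group_vars)
    per_set = [group_tests(d, group_vars) for d in completed.datasets]
    out = per_set[0].copy()
    for col in ("mean", "sd", "statistic", "p_value"):
        out[col] = np.mean([t[col].to_numpy() for t in per_set], axis=0)
    votes = np.mean([t["significant"].to_numpy(float) for t in per_set], axis=0)
    out["significant"] = votes > 0.5
    return out


# --------------------------------------------------------------- logistic


def _predictor_matrix(
    covariates: pd.DataFrame,
    predictor_names: Sequence[str],
    covariate_specs: Sequence[CovariateSpec],
) -> pd.DataFrame:
    """Trend-coded numeric predictors: level index for categoricals (a single
    score per multi-level variable, matching one-OR-per-variable reporting),
    raw values for continuous covariates."""
    cols = {}
    for name in predictor_names:
        spec = find_covariate(covariate_specs, name)
        cols[name] = spec.numeric(covariates[name])
    return pd.DataFrame(cols, index=covariates.index)


def fit_logistic(outcome: np.ndarray, predictors: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; ORs with Wald 95% CIs.

    Raises on a one-class outcome, non-convergence within 100 Newton
    iterations, or (perfect) separation — never returns a silently bad fit.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size != len(predictors):
        raise ValueError("outcome and predictors disagree on n")
    if y.min() == y.max():
        raise ValueError("outcome is single-class; logistic model undefined")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", maxiter=100, disp=False)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge in 100 iterations")
    rows = []
    for name in predictors.columns:
        coef = float(res.params[name])
        se = float(res.bse[name])
        lo, hi = coef - _Z975 * se, coef + _Z975 * se
        rows.append(
            {
                "predictor": name,
                "coef": coef,
                "se": se,
                "or": float(np.exp(coef)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def logistic_on_dataset(
    dataset: SurveyDataset,
    predictor_names: Sequence[str],
    covariate_specs: Sequence[CovariateSpec],
    cutoff: int | None = None,
) -> pd.DataFrame:
    """Dichotomize the total score and fit the multiple logistic model."""
    cutoff = cutoff if cutoff is not None else dataset.scale.dichotomization_cutoff
    if cutoff is None:
        raise ValueError("scale declares no dichotomization cutoff")
    y = dichotomize_score(dataset.total_scores(), cutoff)
    X = _predictor_matrix(dataset.covariates, predictor_names, covariate_specs)
    return fit_logistic(y, X)


def pooled_logistic_mi(
    completed: CompletedData,
    predictor_names: Sequence[str],
    covariate_specs: Sequence[CovariateSpec],
    cutoff: int | None = None,
) -> pd.DataFrame:
    """Fit the logistic model per completed dataset and pool by Rubin's rules.

    The pooled CI uses the t quantile on Rubin's degrees of freedom (normal
    quantile when the between-imputation variance is zero).
    """
    if completed.m < 2:
        raise ValueError("pooled_logistic_mi needs m >= 2 completed datasets")
    fits = []
    for idx, ds in enumerate(completed.datasets):
        try:
            fits.append(
                logistic_on_dataset(ds, predictor_names, covariate_specs, cutoff=cutoff)
            )
        except Exception as exc:
            raise RuntimeError(f"logistic fit failed in imputation {idx}: {exc}") from exc
    rows = []
    for name in predictor_names:
        coefs = [float(f.loc[f["predictor"] == name, "coef"].iloc[0]) for f in fits]
        ses = [float(f.loc[f["predictor"] == name, "se"].iloc[0]) for f in fits]
        pooled = rubins_pool(coefs, [s**2 for s in ses])
        tq = _Z975 if np.isinf(pooled.df) else float(stats.t.ppf(0.975, pooled.df))
        lo = pooled.point - tq * pooled.se
        hi = pooled.point + tq * pooled.se
        rows.append(
            {
                "predictor": name,
                "coef": pooled.point,
                "se": pooled.se,
                "df": pooled.df,
                "or": float(np.exp(pooled.point)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- comparison


def compare_analyses(
    complete_groups: pd.DataFrame,
    complete_logistic: pd.DataFrame,
    arm_groups: Mapping[tuple[str, float], pd.DataFrame],
    arm_logistic: Mapping[tuple[str, float], pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta tables of the imputed arms against the complete-data arm.

    ``arm_groups`` / ``arm_logistic`` map (method, rate) to the arm's group
    tests and logistic fits.  Returns long-format analogues of the group-test
    and odds-ratio tables with ``delta_*`` columns versus complete data and,
    for ORs, a log-odds sign-agreement flag.
    """
    g_rows, l_rows = [], []
    for (method, rate), tbl in arm_groups.items():
        merged = tbl.merge(
            complete_groups[["variable", "level", "mean", "sd", "statistic"]],
            on=["variable", "level"],
            suffixes=("", "_complete"),
            validate="one_to_one",
        )
        if len(merged) != len(complete_groups):
            raise ValueError(f"arm ({method}, {rate}) covariate set mismatch")
        merged["method"] = method
        merged["rate"] = rate
        merged["delta_mean"] = merged["mean"] - merged["mean_complete"]
        merged["delta_sd"] = merged["sd"] - merged["sd_complete"]
        merged["delta_statistic"] = merged["statistic"] - merged["statistic_complete"]
        g_rows.append(merged)
    for (method, rate), tbl in arm_logistic.items():
        merged = tbl.merge(
            complete_logistic[["predictor", "coef", "or"]],
            on="predictor",
            suffixes=("", "_complete"),
            validate="one_to_one",
        )
        if len(merged) != len(complete_logistic):
            raise ValueError(f"arm ({method}, {rate}) predictor set mismatch")
        merged["method"] = method
        merged["rate"] = rate
        merged["delta_or"] = merged["or"] - merged["or_complete"]
        merged["sign_agrees"] = np.sign(merged["coef"]) == np.sign(merged["coef_complete"])
        l_rows.append(merged)
    groups_out = pd.concat(g_rows, ignore_index=True) if g_rows else pd.DataFrame()
    logistic_out = pd.concat(l_rows, ignore_index=True) if l_rows else pd.DataFrame()
    return groups_out, logistic_out
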