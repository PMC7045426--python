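"""The four missing-item handling strategies and Rubin's-rules pooling.

* complete-case deletion — drop every respondent with any missing item;
* mode imputation — fill each cell with its column's most frequent observed
  value (ties broken toward the smallest value, so the method is a pure
  function of its input);
* random hot-deck — fill each cell with the value of a donor drawn uniformly
  (with replacement) among respondents in the same donor class, i.e. the
  same joint levels of the configured covariates, observed on that item;
* multiple imputation — a chained-equations engine with predictive-mean
  matching (PMM): initialise missing cells with random observed draws, then
  sweep the items, regressing each incomplete item on all other items plus
  the covariates and refilling its missing cells with the observed value
  whose prediction is among the k_pmm closest; m independent chains give m
  completed datasets.  PMM only ever copies observed donor values, so the
  ordinal response range is preserved without rounding.

All methods leave observed cells bit-identical to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf
from typing import Sequence

import numpy as np
import pandas as pd

from .amputation import AmputedDataset
from .datasets import SurveyDataset
from .specs import CovariateSpec, find_covariate

__all__ = [
    "CompletedData",
    "PooledEstimate",
    "complete_case",
    "impute_mode",
    "impute_hotdeck",
    "impute_mi",
    "rubins_pool",
]

logger = logging.getLogger(__name__)

_HOTDECK_STREAM = 0xB4
_MI_STREAM = 0xC5


@dataclass
class CompletedData:
    """Analysis-ready output of one handling strategy.

    ``datasets`` has length 1 for deletion/mode/hot-deck and length m for MI.
    Every member is a complete :class:`SurveyDataset`.
    """

    method: str
    datasets: list[SurveyDataset]
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def single(self) -> SurveyDataset:
        if self.m != 1:
            raise ValueError(f"{self.method} produced {self.m} datasets, not 1")
        return self.datasets[0]


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation estimates."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


# ---------------------------------------------------------------- strategies


def complete_case(amputed: AmputedDataset) -> CompletedData:
    """Retain exactly the respondents whose mask row is all-observed."""
    keep = ~amputed.mask.any(axis=1)
    if not keep.any():
        raise ValueError("no complete respondents left after deletion")
    ds = amputed.base.subset(keep)
    return CompletedData(
        method="deletion",
        datasets=[ds],
        provenance={"plan": amputed.plan, "n_retained": int(keep.sum())},
    )


def impute_mode(amputed: AmputedDataset) -> CompletedData:
    """Column-wise mode fill; deterministic (smallest value wins ties)."""
    items = amputed.base.items.to_numpy().copy()
    mask = amputed.mask
    for j in range(items.shape[1]):
        col_missing = mask[:, j]
        if not col_missing.any():
            continue
        observed = items[~col_missing, j]
        if observed.size == 0:
            raise ValueError(
                f"column {amputed.base.items.columns[j]!r} is fully missing; mode undefined"
            )
        values, counts = np.unique(observed, return_counts=True)
        items[col_missing, j] = values[np.argmax(counts)]  # np.unique sorts, so
        # argmax lands on the smallest value among tied counts
    completed = amputed.base.replace_items(
        pd.DataFrame(items, columns=amputed.base.items.columns)
    )
    return CompletedData(method="mode", datasets=[completed], provenance={"plan": amputed.plan})


def impute_hotdeck(
    amputed: AmputedDataset,
    donor_class_vars: Sequence[str],
    seed: int,
) -> CompletedData:
    """Random hot-deck within donor classes defined by covariate levels.

    A donor class with no observed value for some item falls back to the
    pool of all respondents observed on that item (logged at INFO).
    """
    base = amputed.base
    mask = amputed.mask
    items = base.items.to_numpy().copy()
    n, k = items.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, _HOTDECK_STREAM]))

    for var in donor_class_vars:
        if var not in base.covariates.columns:
            raise ValueError(f"donor-class variable {var!r} not in covariates")
        if base.covariates[var].isna().any():
            raise ValueError(f"donor-class variable {var!r} contains missing values")

    if donor_class_vars:
        class_index = pd.MultiIndex.from_frame(
            base.covariates[list(donor_class_vars)].astype(str)
        )
        class_codes, class_labels = class_index.factorize()
    else:
        class_codes, class_labels = np.zeros(n, dtype=int), [()]

    for code in range(len(class_labels)):
        key = class_labels[code]
        in_class = class_codes == code
        for j in range(k):
            need = in_class & mask[:, j]
            if not need.any():
                continue
            pool = items[in_class & ~mask[:, j], j]
            if pool.size == 0:
                pool = items[~mask[:, j], j]
                logger.info(
                    "hot-deck fallback: class %r has no donor for item %s; "
                    "using the full observed pool", key, base.items.columns[j],
                )
                if pool.size == 0:
                    raise ValueError(
                        f"item {base.items.columns[j]!r} has no observed value anywhere"
                    )
            items[need, j] = rng.choice(pool, size=int(need.sum()), replace=True)

    completed = base.replace_items(pd.DataFrame(items, columns=base.items.columns))
    return CompletedData(
        method="hotdeck",
        datasets=[completed],
        provenance={
            "plan": amputed.plan,
            "donor_class_vars": list(donor_class_vars),
            "seed": seed,
        },
    )


# ----------------------------------------------------------------------- MI


def _covariate_design(
    covariates: pd.DataFrame, covariate_specs: Sequence[CovariateSpec]
) -> np.ndarray:
    """Numeric covariate block for the conditional models (centred coding)."""
    if not len(covariate_specs):
        return np.empty((len(covariates), 0))
    cols = [
        find_covariate(covariate_specs, name).code(covariates[name])
        for name in covariates.columns
        if any(s.name == name for s in covariate_specs)
    ]
    return np.column_stack(cols) if cols else np.empty((len(covariates), 0))


def _ridge_lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS via jittered normal equations; SVD fallback if the solve fails.

    The jitter (1e-8 of the mean diagonal) only matters for degenerate,
    near-collinear designs, where it shrinks the offending direction instead
    of failing.
    """
    xtx = X.T @ X
    jitter = 1e-8 * max(np.trace(xtx) / max(X.shape[1], 1), 1.0)
    xtx.flat[:: X.shape[1] + 1] += jitter
    try:
        return np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate input
        return np.linalg.lstsq(X, y, rcond=None)[0]


def _pmm_draw(
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    pred_mis: np.ndarray,
    k_pmm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each missing prediction, copy the observed value of one of the
    k_pmm donors with the closest predictions (vectorised over cells)."""
    k = min(k_pmm, pred_obs.size)
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k neighbours around the insertion point
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, pred_obs.size - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    return sorted_y[cand[np.arange(len(pred_mis)), pick]]


def impute_mi(
    amputed: AmputedDataset,
    covariate_specs: Sequence[CovariateSpec],
    m: int = 20,
    n_iter: int = 10,
    k_pmm: int = 5,
    seed: int = 0,
) -> CompletedData:
    """Chained-equations multiple imputation with predictive-mean matching.

    Each of the ``m`` chains runs independently from its own sub-seed:
    missing cells start as random observed-value draws, then ``n_iter``
    sweeps refit each incomplete item on all other items (current values)
    plus the covariates and refill its missing cells by PMM against the
    ``k_pmm`` nearest observed predictions.
    """
    if m < 2:
        raise ValueError(f"multiple imputation needs m >= 2, got {m}")
    base = amputed.base
    mask = amputed.mask
    n, k = base.items.shape
    cov_block = _covariate_design(base.covariates, covariate_specs)
    items0 = base.items.to_numpy().astype(float)
    incomplete = [j for j in range(k) if mask[:, j].any()]
    for j in incomplete:
        if mask[:, j].all():
            raise ValueError(
                f"column {base.items.columns[j]!r} is fully missing; MI needs observed donors"
            )

    completed_sets: list[SurveyDataset] = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain, _MI_STREAM]))
        X = items0.copy()
        for j in incomplete:  # random observed-value starts
            pool = items0[~mask[:, j], j]
            X[mask[:, j], j] = rng.choice(pool, size=int(mask[:, j].sum()), replace=True)
        for _ in range(n_iter):
            for j in incomplete:
                mis = mask[:, j]
                others = np.delete(X, j, axis=1)
                design = np.column_stack([np.ones(n), others, cov_block])
                beta = _ridge_lstsq(design[~mis], X[~mis, j])
                pred = design @ beta
                X[mis, j] = _pmm_draw(
                    pred[~mis], X[~mis, j], pred[mis], k_pmm, rng
                )
        out = base.replace_items(
            pd.DataFrame(X.astype(int), columns=base.items.columns)
        )
        completed_sets.append(out)

    return CompletedData(
        method="mi",
        datasets=completed_sets,
        provenance={
            "plan": amputed.plan,
            "m": m,
            "n_iter": n_iter,
            "k_pmm": k_pmm,
            "seed": seed,
        },
    )


# ------------------------------------------------------------------ pooling


def rubins_pool(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Combine m per-imputation estimates by Rubin's rules.

    point = mean(q_l); within = mean(u_l); between B = sample variance of the
    q_l; total T = within + (1 + 1/m) B; df = (m - 1)(1 + within /
    ((1 + 1/m) B))^2, with df = inf when B = 0.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-D and equally long")
    m = q.size
    if m < 2:
        raise ValueError(f"Rubin's rules need m >= 2 imputations, got {m}")
    if (u < 0).any():
        raise ValueError("variances must be nonnegative")
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    else:
        df = inf
    return PooledEstimate(
        point=point, within_var=within, between_var=between, total_var=total, df=df, m=m
    )
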