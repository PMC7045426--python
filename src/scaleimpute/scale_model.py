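"""Synthetic questionnaire populations from a latent-trait ordinal model.

The generator draws covariates from their declared marginals, forms a
unidimensional latent trait as a linear combination of (centred) covariate
codings plus standard-normal noise, and produces each ordinal item through a
probit-style graded threshold model:

    z_ij = lambda_j * theta_i + eps_ij,   eps_ij ~ N(0, 1)
    x_ij = response_min + #{t : z_ij > tau_jt}

with strictly increasing thresholds tau_j1 < ... < tau_j,c-1 per item.  The
shared trait makes items positively inter-correlated; nonzero covariate
loadings give the covariate-score associations a validation analysis needs.

``calibrate_scale_params`` tunes a common threshold shift (bisection; the
population total-score mean is monotone in the shift under common random
numbers) and a threshold spread factor (coarse grid) so that the synthetic
total score hits a target mean/SD — e.g. an RSES-like 28.22 +/- 4.63.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import SurveyDataset
from .specs import CovariateSpec, ScaleSpec

__all__ = [
    "ItemParams",
    "generate_covariates",
    "latent_trait",
    "generate_item_responses",
    "compute_total_score",
    "calibrate_scale_params",
]


@dataclass(frozen=True)
class ItemParams:
    """Graded-model parameters: one loading and c-1 thresholds per item."""

    loadings: tuple[float, ...]
    thresholds: tuple[tuple[float, ...], ...]  # shape (k, n_categories - 1)

    def __post_init__(self) -> None:
        if len(self.loadings) != len(self.thresholds):
            raise ValueError("loadings and thresholds must have one entry per item")
        for j, taus in enumerate(self.thresholds):
            diffs = np.diff(taus)
            if len(taus) and not np.all(diffs > 0):
                raise ValueError(f"item {j}: thresholds must be strictly increasing")
        object.__setattr__(self, "loadings", tuple(float(v) for v in self.loadings))
        object.__setattr__(
            self, "thresholds", tuple(tuple(float(t) for t in row) for row in self.thresholds)
        )

    @property
    def n_items(self) -> int:
        return len(self.loadings)

    def shifted(self, delta: float) -> "ItemParams":
        """All thresholds shifted by ``delta`` (larger delta -> lower scores)."""
        return ItemParams(
            loadings=self.loadings,
            thresholds=tuple(tuple(t + delta for t in row) for row in self.thresholds),
        )

    @classmethod
    def homogeneous(
        cls, n_items: int, loading: float, thresholds: Sequence[float]
    ) -> "ItemParams":
        return cls(
            loadings=(loading,) * n_items,
            thresholds=(tuple(thresholds),) * n_items,
        )


def generate_covariates(
    specs: Sequence[CovariateSpec], n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` respondents' covariates i.i.d. from the declared marginals.

    Categorical columns come back as ordered ``pd.Categorical`` with the
    spec's level order; continuous columns as float.  Covariates are mutually
    independent — only the latent trait links them to the items.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols: dict[str, object] = {}
    for spec in specs:
        if spec.kind == "categorical":
            draws = rng.choice(len(spec.levels), size=n, p=spec.probabilities)
            cols[spec.name] = pd.Categorical.from_codes(
                draws, categories=list(spec.levels)
            )
        else:
            cols[spec.name] = rng.normal(spec.mean, spec.sd, size=n)
    return pd.DataFrame(cols, columns=[s.name for s in specs])


def latent_trait(
    covariates: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """theta_i = sum_c effect_c * code_c(x_ic) + N(0, 1) noise."""
    n = len(covariates)
    theta = rng.standard_normal(n)
    for spec in specs:
        if spec.effect_on_trait != 0.0:
            theta += spec.effect_on_trait * spec.code(covariates[spec.name])
    return theta


def generate_item_responses(
    covariates: pd.DataFrame,
    scale: ScaleSpec,
    item_params: ItemParams,
    covariate_specs: Sequence[CovariateSpec],
    seed: int,
    ids: Optional[np.ndarray] = None,
) -> SurveyDataset:
    """Generate a complete :class:`SurveyDataset` from the graded model."""
    if item_params.n_items != scale.n_items:
        raise ValueError(
            f"item_params has {item_params.n_items} items, scale declares {scale.n_items}"
        )
    n = len(covariates)
    rng = np.random.default_rng(seed)
    theta = latent_trait(covariates, covariate_specs, rng)
    loadings = np.asarray(item_params.loadings)
    taus = np.asarray(item_params.thresholds)  # (k, c-1)
    z = theta[:, None] * loadings[None, :] + rng.standard_normal((n, scale.n_items))
    values = scale.response_min + (z[:, :, None] > taus[None, :, :]).sum(axis=2)
    items = pd.DataFrame(values.astype(int), columns=scale.item_columns)
    if ids is None:
        ids = np.arange(1, n + 1)
    return SurveyDataset(
        ids=np.asarray(ids), items=items, covariates=covariates.reset_index(drop=True), scale=scale
    )


def compute_total_score(data: SurveyDataset | pd.DataFrame) -> pd.Series:
    """Per-respondent total = sum of item values; refuses incomplete input."""
    items = data.items if isinstance(data, SurveyDataset) else data
    if items.isna().any().any():
        raise ValueError(
            "item matrix has missing cells; impute or delete before computing total scores"
        )
    return items.sum(axis=1)


def _mc_total_moments(
    scale: ScaleSpec,
    covariate_specs: Sequence[CovariateSpec],
    params: ItemParams,
    n: int,
    seed: int,
) -> tuple[float, float]:
    covs = generate_covariates(covariate_specs, n, seed)
    ds = generate_item_responses(covs, scale, params, covariate_specs, seed + 1)
    totals = ds.total_scores()
    return float(totals.mean()), float(totals.std(ddof=1))


def calibrate_scale_params(
    scale: ScaleSpec,
    covariate_specs: Sequence[CovariateSpec],
    loading: float,
    base_thresholds: Sequence[float],
    target_mean: float,
    target_sd: Optional[float] = None,
    spread_grid: Sequence[float] = (0.7, 0.85, 1.0, 1.15, 1.3),
    n: int = 60000,
    seed: int = 20200227,
    tol: float = 1e-3,
) -> ItemParams:
    """Tune item parameters so the synthetic total score hits its targets.

    For each candidate spread ``s`` (thresholds scaled about their centre),
    bisect on a common threshold shift until the Monte-Carlo total-score mean
    (common random numbers, so the map shift -> mean is exactly monotone)
    matches ``target_mean``; keep the spread whose resulting SD is closest to
    ``target_sd``.  Returns homogeneous :class:`ItemParams`.
    """
    base = np.asarray(base_thresholds, dtype=float)
    centre = base.mean()

    def solve_shift(params: ItemParams) -> ItemParams:
        lo, hi = -6.0, 6.0  # mean is decreasing in shift
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            mean_mid, _ = _mc_total_moments(scale, covariate_specs, params.shifted(mid), n, seed)
            if mean_mid > target_mean:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return params.shifted(0.5 * (lo + hi))

    best: tuple[float, ItemParams] | None = None
    spreads = [1.0] if target_sd is None else list(spread_grid)
    for s in spreads:
        taus = centre + s * (base - centre)
        cand = solve_shift(ItemParams.homogeneous(scale.n_items, loading, taus))
        _, sd = _mc_total_moments(scale, covariate_specs, cand, n, seed)
        gap = 0.0 if target_sd is None else abs(sd - target_sd)
        if best is None or gap < best[0]:
            best = (gap, cand)
    assert best is not None
    return best[1]
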