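"""Controlled amputation: imposing MCAR/MAR missingness on complete data.

The mechanism works at respondent level: each respondent i gets one
missingness probability

    p_i = expit(alpha + sum_d beta_d * code_d(x_id))        (MAR)
    p_i = target_rate                                       (MCAR)

and every item cell of respondent i is then set missing independently with
probability p_i.  Drivers are always fully observed covariates, never item
values, which is what makes the mechanism MAR rather than MNAR.  The
intercept alpha is not user-set: it is solved by bisection so that the mean
of p_i over the sample equals the target marginal cell rate (5/10/15/20%
in the default study design) to 1e-6.

Replication seeding: the mask for replication r of a plan with master seed s
is drawn from ``numpy.random.SeedSequence([s, r, _MASK_STREAM])`` — each
replication is independently reproducible and masks differ across r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datasets import SurveyDataset
from .specs import CovariateSpec, find_covariate

__all__ = [
    "MissingnessPlan",
    "AmputedDataset",
    "calibrate_intercept",
    "ampute",
    "realized_missing_rate",
    "complete_case_fraction",
]

logger = logging.getLogger(__name__)

_MASK_STREAM = 0xA3  # stream tag separating mask draws from other RNG uses
_CAL_TOL = 1e-6


@dataclass(frozen=True)
class MissingnessPlan:
    """Recipe for one amputation: mechanism, target rate, drivers, seeds."""

    mechanism: str  # "MCAR" | "MAR"
    target_rate: float
    driver_slopes: Mapping[str, float] = field(default_factory=dict)
    intercept: float | None = None
    seed: int = 0
    replication_index: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"mechanism must be MCAR or MAR, got {self.mechanism!r}")
        if not (0.0 < self.target_rate < 1.0):
            raise ValueError(f"target_rate must lie in (0, 1), got {self.target_rate}")
        if self.mechanism == "MAR" and not self.driver_slopes:
            raise ValueError("MAR plan needs at least one driver covariate")
        object.__setattr__(self, "driver_slopes", dict(self.driver_slopes))

    def with_replication(self, r: int) -> "MissingnessPlan":
        return replace(self, replication_index=r)


@dataclass
class AmputedDataset:
    """A complete dataset plus the boolean mask (True = missing) that hides it."""

    base: SurveyDataset
    mask: np.ndarray  # (n, k) bool
    plan: MissingnessPlan

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.base.items.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != items shape {self.base.items.shape}"
            )

    def items_with_missing(self) -> pd.DataFrame:
        """Item matrix as floats with NaN in masked cells."""
        out = self.base.items.astype(float).copy()
        out.values[self.mask] = np.nan
        return out

    def to_csv(self, path: str | Path) -> None:
        frame = self.base.to_frame().copy()
        items = self.items_with_missing()
        for col in items.columns:
            frame[col] = items[col].astype(object).where(items[col].notna(), "")
        frame.to_csv(path, index=False)

    def mask_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.mask.astype(int), columns=self.base.items.columns
        ).assign(id=self.base.ids)[["id", *self.base.items.columns]].to_csv(path, index=False)


def _driver_score(
    plan: MissingnessPlan,
    covariates: pd.DataFrame,
    covariate_specs: Sequence[CovariateSpec],
) -> np.ndarray:
    score = np.zeros(len(covariates))
    for name, slope in plan.driver_slopes.items():
        spec = find_covariate(covariate_specs, name)
        col = covariates[name]
        if col.isna().any():
            raise ValueError(f"driver covariate {name!r} contains missing values")
        score += slope * spec.code(col)
    return score


def calibrate_intercept(
    plan: MissingnessPlan,
    covariates: pd.DataFrame,
    covariate_specs: Sequence[CovariateSpec],
) -> float:
    """Solve alpha so that mean_i expit(alpha + score_i) = target_rate.

    The mean is strictly increasing in alpha, so plain bisection converges;
    with all slopes zero this reduces to the closed form logit(target_rate).
    """
    score = _driver_score(plan, covariates, covariate_specs)
    if not np.any(score):
        return float(logit(plan.target_rate))

    def mean_rate(alpha: float) -> float:
        return float(np.mean(expit(alpha + score)))

    lo, hi = -40.0, 40.0
    if not (mean_rate(lo) <= plan.target_rate <= mean_rate(hi)):
        raise ValueError(
            f"target rate {plan.target_rate} unattainable with the given drivers"
        )
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < plan.target_rate:
            lo = mid
        else:
            hi = mid
        if abs(mean_rate(0.5 * (lo + hi)) - plan.target_rate) < _CAL_TOL:
            break
    return 0.5 * (lo + hi)


def ampute(
    dataset: SurveyDataset,
    plan: MissingnessPlan,
    covariate_specs: Sequence[CovariateSpec] = (),
) -> AmputedDataset:
    """Draw the missingness mask and return the amputed dataset.

    MAR plans with ``intercept=None`` are calibrated on the fly against the
    dataset's own covariates; the solved intercept is recorded in the
    returned plan for provenance.
    """
    n, k = dataset.items.shape
    if plan.mechanism == "MCAR":
        p = np.full(n, plan.target_rate)
        plan_used = plan
    else:
        alpha = (
            plan.intercept
            if plan.intercept is not None
            else calibrate_intercept(plan, dataset.covariates, covariate_specs)
        )
        p = expit(alpha + _driver_score(plan, dataset.covariates, covariate_specs))
        plan_used = replace(plan, intercept=float(alpha))
    rng = np.random.default_rng(
        np.random.SeedSequence([plan.seed, plan.replication_index, _MASK_STREAM])
    )
    mask = rng.random((n, k)) < p[:, None]
    logger.debug(
        "amputed %s: mechanism=%s rate=%.3f rep=%d realized=%.4f",
        dataset.scale.name, plan.mechanism, plan.target_rate,
        plan.replication_index, mask.mean() if mask.size else 0.0,
    )
    return AmputedDataset(base=dataset, mask=mask, plan=plan_used)


def realized_missing_rate(amputed: AmputedDataset) -> float:
    """Fraction of item cells that are missing."""
    return float(amputed.mask.mean()) if amputed.mask.size else 0.0


def complete_case_fraction(amputed: AmputedDataset) -> float:
    """Fraction of respondents with no missing item at all."""
    if amputed.mask.shape[0] == 0:
        return 1.0
    return float((~amputed.mask.any(axis=1)).mean())
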