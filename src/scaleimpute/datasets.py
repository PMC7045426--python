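"""The in-memory container for a complete questionnaire dataset and its CSV dialect.

A :class:`SurveyDataset` bundles respondent ids, the n x k integer item
matrix, the covariate table and the :class:`~scaleimpute.specs.ScaleSpec`.
It is complete by construction — every item cell holds a value inside the
declared response range.  Incomplete data live in
:class:`~scaleimpute.amputation.AmputedDataset` instead.

CSV layout: one row per respondent; ``id``, then ``item_01..item_k``, then
covariate columns; UTF-8 with a header row.  Missing cells (only ever present
after amputation) are written as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .specs import CovariateSpec, ScaleSpec

__all__ = ["SurveyDataset"]


@dataclass
class SurveyDataset:
    ids: np.ndarray
    items: pd.DataFrame
    covariates: pd.DataFrame
    scale: ScaleSpec

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.items) != n or len(self.covariates) != n:
            raise ValueError(
                f"row mismatch: {n} ids, {len(self.items)} item rows, "
                f"{len(self.covariates)} covariate rows"
            )
        if list(self.items.columns) != self.scale.item_columns:
            raise ValueError("item columns do not match the scale spec")
        if self.items.isna().any().any():
            raise ValueError("SurveyDataset must be complete; item matrix has missing cells")
        vals = self.items.to_numpy()
        if vals.size and (
            vals.min() < self.scale.response_min or vals.max() > self.scale.response_max
        ):
            raise ValueError(
                f"item values outside [{self.scale.response_min}, {self.scale.response_max}]"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def total_scores(self) -> pd.Series:
        from .scale_model import compute_total_score

        return compute_total_score(self.items)

    def subset(self, row_mask: np.ndarray) -> "SurveyDataset":
        """Row subset (boolean mask or integer positions), order preserved."""
        return SurveyDataset(
            ids=np.asarray(self.ids)[row_mask],
            items=self.items.iloc[np.flatnonzero(row_mask)]
            if np.asarray(row_mask).dtype == bool
            else self.items.iloc[row_mask],
            covariates=self.covariates.iloc[np.flatnonzero(row_mask)]
            if np.asarray(row_mask).dtype == bool
            else self.covariates.iloc[row_mask],
            scale=self.scale,
        )

    def replace_items(self, items: pd.DataFrame) -> "SurveyDataset":
        return SurveyDataset(
            ids=self.ids, items=items, covariates=self.covariates, scale=self.scale
        )

    # --------------------------------------------------------------------- io

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                pd.DataFrame({"id": self.ids}),
                self.items.reset_index(drop=True),
                self.covariates.reset_index(drop=True),
            ],
            axis=1,
        )
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        scale: ScaleSpec,
        covariate_specs: Optional[Sequence[CovariateSpec]] = None,
    ) -> "SurveyDataset":
        df = pd.read_csv(path)
        item_cols = scale.item_columns
        missing_cols = [c for c in ["id", *item_cols] if c not in df.columns]
        if missing_cols:
            raise ValueError(f"CSV lacks required columns: {missing_cols}")
        cov_cols = [c for c in df.columns if c != "id" and c not in item_cols]
        covariates = df[cov_cols].copy()
        if covariate_specs is not None:
            for spec in covariate_specs:
                if spec.kind == "categorical" and spec.name in covariates:
                    covariates[spec.name] = pd.Categorical(
                        covariates[spec.name], categories=list(spec.levels)
                    )
        return cls(
            ids=df["id"].to_numpy(),
            items=df[item_cols].astype(int),
            covariates=covariates,
            scale=scale,
        )
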