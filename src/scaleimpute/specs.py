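"""Schemas describing a questionnaire scale and its respondent covariates.

A :class:`ScaleSpec` declares the ordinal item structure of an instrument
(number of items, response range, total-score rule, optional dichotomization
cutoff).  A :class:`CovariateSpec` declares one respondent-level variable —
categorical with level probabilities or continuous with mean/sd — together
with its loading on the latent trait that drives item responses.

Both are plain frozen dataclasses, round-trippable through ``to_dict`` /
``from_dict`` so they can live inside a YAML/JSON run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScaleSpec", "CovariateSpec"]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ScaleSpec:
    """Ordinal-item questionnaire schema.

    Parameters
    ----------
    name
        Instrument label (e.g. ``"rses"``).
    n_items
        Number of items; total score is the plain sum of item values.
    response_min, response_max
        Inclusive ordinal response range shared by all items (e.g. 1..4).
    dichotomization_cutoff
        Optional integer threshold splitting the total score into a binary
        outcome (``total >= cutoff`` codes 1).
    target_total_mean, target_total_sd
        Calibration targets for the synthetic generator; purely advisory.
    """

    name: str
    n_items: int
    response_min: int
    response_max: int
    dichotomization_cutoff: Optional[int] = None
    target_total_mean: Optional[float] = None
    target_total_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError(f"n_items must be >= 2, got {self.n_items}")
        if self.response_min >= self.response_max:
            raise ValueError(
                f"response_min ({self.response_min}) must be < "
                f"response_max ({self.response_max})"
            )
        if self.dichotomization_cutoff is not None and not (
            self.total_min <= self.dichotomization_cutoff <= self.total_max
        ):
            raise ValueError(
                f"cutoff {self.dichotomization_cutoff} outside total-score "
                f"range [{self.total_min}, {self.total_max}]"
            )

    @property
    def n_categories(self) -> int:
        return self.response_max - self.response_min + 1

    @property
    def total_min(self) -> int:
        return self.n_items * self.response_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.response_max

    @property
    def item_columns(self) -> list[str]:
        width = max(2, len(str(self.n_items)))
        return [f"item_{i + 1:0{width}d}" for i in range(self.n_items)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_items": self.n_items,
            "response_min": self.response_min,
            "response_max": self.response_max,
            "dichotomization_cutoff": self.dichotomization_cutoff,
            "target_total_mean": self.target_total_mean,
            "target_total_sd": self.target_total_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        return cls(**d)


@dataclass(frozen=True)
class CovariateSpec:
    """One respondent covariate and its loading on the latent trait.

    Categorical covariates carry ordered ``levels`` (first level is the
    reference) with sampling ``probabilities``; continuous covariates carry
    ``mean`` and ``sd``.  ``effect_on_trait`` is the trait shift per coded
    unit: per level step for categoricals, per standard deviation for
    continuous variables (see :meth:`code`).
    """

    name: str
    kind: str  # "categorical" | "continuous"
    levels: Optional[tuple[str, ...]] = None
    probabilities: Optional[tuple[float, ...]] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    effect_on_trait: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels or self.probabilities is None:
                raise ValueError(f"{self.name}: categorical spec needs levels + probabilities")
            if len(self.levels) != len(self.probabilities):
                raise ValueError(f"{self.name}: levels/probabilities length mismatch")
            if abs(sum(self.probabilities) - 1.0) > _PROB_TOL:
                raise ValueError(
                    f"{self.name}: probabilities sum to {sum(self.probabilities)!r}, not 1"
                )
            if any(p < 0 for p in self.probabilities):
                raise ValueError(f"{self.name}: negative probability")
        elif self.kind == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous spec needs mean + sd")
            if self.sd <= 0:
                raise ValueError(f"{self.name}: sd must be > 0, got {self.sd}")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        # tuples, so frozen dataclass hashing works even when built from lists
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))
        if self.probabilities is not None:
            object.__setattr__(self, "probabilities", tuple(float(p) for p in self.probabilities))

    # ------------------------------------------------------------------ coding

    def numeric(self, values: pd.Series) -> np.ndarray:
        """Raw numeric coding: level index (0-based, trend-coded) for
        categoricals, the raw value for continuous covariates."""
        if self.kind == "categorical":
            idx = pd.Categorical(values, categories=list(self.levels)).codes
            if (idx < 0).any():
                raise ValueError(f"{self.name}: value outside declared levels")
            return idx.astype(float)
        return np.asarray(values, dtype=float)

    def code(self, values: pd.Series) -> np.ndarray:
        """Centred coding used by the trait model and the MAR mechanism.

        Categorical: level index minus its expectation under the declared
        probabilities (so the coding does not depend on the sample drawn).
        Continuous: (x - mean) / sd.
        """
        x = self.numeric(values)
        if self.kind == "categorical":
            expected = float(np.dot(np.arange(len(self.levels)), self.probabilities))
            return x - expected
        return (x - self.mean) / self.sd

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind, "effect_on_trait": self.effect_on_trait}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
            d["probabilities"] = list(self.probabilities)
        else:
            d["mean"] = self.mean
            d["sd"] = self.sd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        d = dict(d)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        if "probabilities" in d:
            d["probabilities"] = tuple(d["probabilities"])
        return cls(**d)


def find_covariate(specs: Sequence[CovariateSpec], name: str) -> CovariateSpec:
    for s in specs:
        if s.name == name:
            return s
    raise KeyError(f"no covariate spec named {name!r}")
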