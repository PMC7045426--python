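"""Run configuration: a validated, YAML/JSON round-trippable experiment recipe.

A :class:`RunConfig` either names a built-in preset (``preset: saq``) or
carries inline ``scale`` / ``covariates`` / ``item_params`` sections; every
knob of the benchmark (rates, replications, methods, MI settings, donor
classes, correlation pair, MAR drivers, master seed) lives here so a run is
reproducible from the file plus nothing else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .evaluation import METHODS
from .presets import get_preset
from .scale_model import ItemParams
from .specs import CovariateSpec, ScaleSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    preset: Optional[str] = None
    scale: Optional[ScaleSpec] = None
    covariates: tuple[CovariateSpec, ...] = ()
    item_params: Optional[ItemParams] = None
    n: Optional[int] = None
    rates: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    n_reps: int = 50
    methods: tuple[str, ...] = METHODS
    mechanism: str = "MAR"
    driver_slopes: dict[str, float] = field(default_factory=dict)
    donor_class_vars: tuple[str, ...] = ()
    corr_var: str = "age"
    cutoff: Optional[int] = None
    mi_m: int = 20
    mi_iter: int = 10
    k_pmm: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.preset is None and (self.scale is None or self.item_params is None):
            raise ValueError("config needs either a preset name or inline scale + item_params")
        if not self.rates:
            raise ValueError("rates must be non-empty")
        if len(set(self.rates)) != len(self.rates):
            raise ValueError("rates must be unique")
        for r in self.rates:
            if not (0.0 < r < 1.0):
                raise ValueError(f"rate {r} outside (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"mechanism must be MCAR or MAR, got {self.mechanism!r}")
        if self.mi_m < 2:
            raise ValueError("mi_m must be >= 2")

    # ------------------------------------------------------------ resolution

    def resolve(self):
        """Fill scale/covariates/params/defaults from the preset if named.

        Returns (scale, covariate_specs, item_params, n, driver_slopes,
        donor_class_vars, corr_var, cutoff).
        """
        if self.preset is not None:
            p = get_preset(self.preset)
            scale = self.scale or p.scale
            covs = self.covariates or p.covariates
            params = self.item_params or p.item_params
            n = self.n or p.default_n
            drivers = self.driver_slopes or dict(p.mar_driver_slopes)
            donors = self.donor_class_vars or p.donor_class_vars
            corr_var = self.corr_var or p.corr_var
        else:
            scale, covs, params = self.scale, self.covariates, self.item_params
            if self.n is None:
                raise ValueError("inline config needs n")
            n, drivers, donors, corr_var = (
                self.n, self.driver_slopes, self.donor_class_vars, self.corr_var,
            )
        cutoff = self.cutoff if self.cutoff is not None else scale.dichotomization_cutoff
        if self.mechanism == "MAR" and not drivers:
            raise ValueError("MAR mechanism needs driver_slopes")
        return scale, tuple(covs), params, n, dict(drivers), tuple(donors), corr_var, cutoff

    # --------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        d: dict = {
            "preset": self.preset,
            "n": self.n,
            "rates": list(self.rates),
            "n_reps": self.n_reps,
            "methods": list(self.methods),
            "mechanism": self.mechanism,
            "driver_slopes": dict(self.driver_slopes),
            "donor_class_vars": list(self.donor_class_vars),
            "corr_var": self.corr_var,
            "cutoff": self.cutoff,
            "mi_m": self.mi_m,
            "mi_iter": self.mi_iter,
            "k_pmm": self.k_pmm,
            "master_seed": self.master_seed,
        }
        if self.scale is not None:
            d["scale"] = self.scale.to_dict()
        if self.covariates:
            d["covariates"] = [c.to_dict() for c in self.covariates]
        if self.item_params is not None:
            d["item_params"] = {
                "loadings": list(self.item_params.loadings),
                "thresholds": [list(r) for r in self.item_params.thresholds],
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "scale" in d and d["scale"] is not None:
            d["scale"] = ScaleSpec.from_dict(d["scale"])
        if "covariates" in d and d["covariates"]:
            d["covariates"] = tuple(CovariateSpec.from_dict(c) for c in d["covariates"])
        if "item_params" in d and d["item_params"] is not None:
            ip = d["item_params"]
            d["item_params"] = ItemParams(
                loadings=tuple(ip["loadings"]),
                thresholds=tuple(tuple(r) for r in ip["thresholds"]),
            )
        for key in ("rates", "methods", "donor_class_vars"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load YAML (JSON is a YAML subset, so .json files work too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
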