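"""Built-in study populations: RSES-like, SAQ-like and ADL-like presets.

Each preset bundles a :class:`ScaleSpec`, covariate specs, frozen
:class:`ItemParams` and default MAR driver slopes, emulating the three
cross-sectional questionnaire populations the benchmark is designed around:

* ``rses`` — a 10-item self-esteem scale (responses 1-4, cutoff 30) for
  middle-school students (n = 3513 by default), calibrated so the synthetic
  total score sits near mean 28.2, SD 4.6;
* ``saq`` — a 16-item self-acceptance questionnaire (1-4) for college
  students (n = 742);
* ``adl`` — a 14-item activities-of-daily-living scale (1-4) for elders
  (n = 1242), right-skewed because most elders are independent.

Item counts and response ranges for the SAQ- and ADL-like scales follow the
published instruments' conventional forms.  Item thresholds were frozen once
with :func:`~scaleimpute.scale_model.calibrate_scale_params` against each
preset's target moments.  Covariate effects are in latent-trait SD units per
coded step; MAR driver slopes are on the same coded scale and deliberately
load on score-relevant covariates so that complete-case deletion is biased
under MAR, the regime the benchmark studies.  The default correlation
operand (age) is intentionally not a driver — when the two roles coincide,
constant-fill imputation corrupts the correlation statistic more than
deletion does, which is not the regime of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .datasets import SurveyDataset
from .scale_model import ItemParams, generate_covariates, generate_item_responses
from .specs import CovariateSpec, ScaleSpec

__all__ = ["Preset", "get_preset", "PRESETS"]


@dataclass(frozen=True)
class Preset:
    scale: ScaleSpec
    covariates: tuple[CovariateSpec, ...]
    item_params: ItemParams
    default_n: int
    mar_driver_slopes: Mapping[str, float]
    donor_class_vars: tuple[str, ...]
    corr_var: str = "age"

    def generate(self, n: int | None = None, seed: int = 0) -> SurveyDataset:
        """Draw a complete synthetic population of this preset."""
        n = self.default_n if n is None else n
        covs = generate_covariates(self.covariates, n, seed)
        return generate_item_responses(
            covs, self.scale, self.item_params, self.covariates, seed + 1
        )


# --------------------------------------------------------------- RSES-like

_RSES_SCALE = ScaleSpec(
    name="rses",
    n_items=10,
    response_min=1,
    response_max=4,
    dichotomization_cutoff=30,
    target_total_mean=28.22,
    target_total_sd=4.63,
)

_RSES_COVARIATES = (
    CovariateSpec(name="age", kind="continuous", mean=16.3, sd=1.2, effect_on_trait=-0.10),
    CovariateSpec(
        name="gender", kind="categorical",
        levels=("female", "male"), probabilities=(0.485, 0.515),
        effect_on_trait=0.22,
    ),
    CovariateSpec(
        name="grade", kind="categorical",
        levels=("junior", "senior"), probabilities=(0.60, 0.40),
        effect_on_trait=-0.06,
    ),
    CovariateSpec(
        name="record", kind="categorical",
        levels=("excellent", "good", "average", "poor"),
        probabilities=(0.12, 0.28, 0.42, 0.18),
        effect_on_trait=-0.38,
    ),
    CovariateSpec(
        name="residence", kind="categorical",
        levels=("rural", "urban"), probabilities=(0.957, 0.043),
        effect_on_trait=0.09,
    ),
    CovariateSpec(
        name="communication", kind="categorical",
        levels=("usually", "sometimes", "scarcely", "never", "unclear"),
        probabilities=(0.46, 0.34, 0.09, 0.05, 0.06),
        effect_on_trait=-0.24,
    ),
)

# frozen by calibrate_scale_params against mean 28.22, SD 4.63 (n=60000 MC)
_RSES_PARAMS = ItemParams.homogeneous(
    10, loading=0.55, thresholds=(-1.95809, -0.46309, 0.91691)
)

# ---------------------------------------------------------------- SAQ-like

_SAQ_SCALE = ScaleSpec(
    name="saq",
    n_items=16,
    response_min=1,
    response_max=4,
    target_total_mean=44.0,
    target_total_sd=7.0,
)

_SAQ_COVARIATES = (
    CovariateSpec(name="age", kind="continuous", mean=19.8, sd=1.3, effect_on_trait=-0.30),
    CovariateSpec(
        name="gender", kind="categorical",
        levels=("female", "male"), probabilities=(0.50, 0.50),
        effect_on_trait=0.35,
    ),
    CovariateSpec(
        name="parent_edu", kind="categorical",
        levels=("low", "middle", "high"), probabilities=(0.40, 0.40, 0.20),
        effect_on_trait=0.30,
    ),
)

# frozen by calibrate_scale_params against mean 44.0, SD 7.0 (n=60000 MC)
_SAQ_PARAMS = ItemParams.homogeneous(
    16, loading=0.55, thresholds=(-1.84383, -0.34883, 1.03117)
)

# ---------------------------------------------------------------- ADL-like

_ADL_SCALE = ScaleSpec(
    name="adl",
    n_items=14,
    response_min=1,
    response_max=4,
    target_total_mean=20.0,
    target_total_sd=5.5,
)

_ADL_COVARIATES = (
    CovariateSpec(name="age", kind="continuous", mean=71.0, sd=7.0, effect_on_trait=0.45),
    CovariateSpec(
        name="gender", kind="categorical",
        levels=("male", "female"), probabilities=(0.45, 0.55),
        effect_on_trait=0.10,
    ),
    CovariateSpec(
        name="living", kind="categorical",
        levels=("with_family", "alone"), probabilities=(0.80, 0.20),
        effect_on_trait=0.20,
    ),
)

# frozen by calibrate_scale_params against mean 20.0, SD 5.5 (n=60000 MC)
_ADL_PARAMS = ItemParams.homogeneous(
    14, loading=0.70, thresholds=(0.55525, 1.75525, 2.75525)
)

PRESETS: dict[str, Preset] = {
    "rses": Preset(
        scale=_RSES_SCALE,
        covariates=_RSES_COVARIATES,
        item_params=_RSES_PARAMS,
        default_n=3513,
        mar_driver_slopes={"record": 0.5, "communication": 0.4},
        donor_class_vars=("gender", "grade"),
    ),
    "saq": Preset(
        scale=_SAQ_SCALE,
        covariates=_SAQ_COVARIATES,
        item_params=_SAQ_PARAMS,
        default_n=742,
        mar_driver_slopes={"gender": 0.8, "parent_edu": 0.6},
        donor_class_vars=("gender",),
    ),
    "adl": Preset(
        scale=_ADL_SCALE,
        covariates=_ADL_COVARIATES,
        item_params=_ADL_PARAMS,
        default_n=1242,
        mar_driver_slopes={"living": 0.8, "gender": 0.6},
        donor_class_vars=("gender",),
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
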