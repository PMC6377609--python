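"""Domain types for larval pharmacokinetic modelling.

The unit conventions are fixed package-wide: amounts in pmole per larva,
time in minutes, larval volumes in nL, clearance in nL/h.  Ages are integer
days post fertilisation (dpf) and are treated as discrete levels, not as a
continuous covariate to interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

ARMS = ("constant", "washout")
COVARIATE_FORMS = ("none", "linear", "power", "discrete")
ERROR_MODELS = ("additive", "proportional", "combined")
ELIMINATION_LAWS = ("first_order", "michaelis_menten")

#: columns of the on-disk dataset format (one row per pooled-larvae sample)
DATASET_COLUMNS = (
    "sample_id",
    "age_dpf",
    "arm",
    "time_min",
    "amount_pmole",
    "pool_size",
)


@dataclass(frozen=True)
class Observation:
    """One measured pooled-larvae sample.

    ``amount_pmole`` is the total paracetamol amount per larva derived from a
    pooled lysate; ``pool_size`` is the number of larvae pooled (metadata, not
    a variance divisor — pooling yields a single observation).
    """

    sample_id: str
    age_dpf: int
    arm: str
    time_min: float
    amount_pmole: float
    pool_size: int = 5

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.time_min < 0:
            raise ValueError("time_min must be non-negative")
        if not self.amount_pmole >= 0:
            raise ValueError("amount_pmole must be a non-negative finite number")


@dataclass
class CovariateSpec:
    """Functional relationship between a PK parameter and larval age.

    form:
        "none"      P = base
        "linear"    P = base * (1 + slope * (age - ref))
        "power"     P = base * (1 + slope) ** (age - ref)
        "discrete"  scalar coefficient: P = base at the reference age and
                    base * (1 + factor) for older ages (a single step); or a
                    mapping {age: multiplier} giving one level per age.
    """

    form: str = "none"
    base_value: Optional[float] = None
    slope_or_factor: Union[float, Mapping[int, float], None] = None
    reference_age_dpf: int = 3

    def __post_init__(self) -> None:
        if self.form not in COVARIATE_FORMS:
            raise ValueError(
                f"unknown covariate form {self.form!r}; expected one of {COVARIATE_FORMS}"
            )


@dataclass
class ModelSpec:
    """Structural variant + covariate functions + residual-error form.

    A two-compartment spec is fitted against the *sum* of compartment amounts,
    with elimination from the central compartment only.
    """

    n_compartments: int = 1
    elimination: str = "first_order"
    ka_covariate: CovariateSpec = field(default_factory=CovariateSpec)
    ke_covariate: CovariateSpec = field(default_factory=CovariateSpec)
    error_model: str = "combined"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.elimination not in ELIMINATION_LAWS:
            raise ValueError(
                f"unknown elimination law {self.elimination!r}; "
                f"expected one of {ELIMINATION_LAWS}"
            )
        if self.error_model not in ERROR_MODELS:
            raise ValueError(
                f"unknown error model {self.error_model!r}; "
                f"expected one of {ERROR_MODELS}"
            )
        if self.elimination == "michaelis_menten" and self.ke_covariate.form != "none":
            raise ValueError(
                "covariates on the elimination parameters are not supported for "
                "Michaelis-Menten elimination"
            )


@dataclass
class PKParameters:
    """Structural, covariate and residual-error parameters.

    ``ka_coef``/``ke_coef`` are the covariate coefficients whose meaning is set
    by the matching :class:`CovariateSpec` form (slope, step factor, or per-age
    multiplier map).  ``factor_a`` and ``slope_e`` are provided as aliases for
    the final-model parameterisation (discrete ka step, power ke).
    """

    ka_base: float = 0.289
    ka_coef: Union[float, Mapping[int, float], None] = None
    ke_base: float = 0.0193
    ke_coef: Union[float, Mapping[int, float], None] = None
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0
    vmax: Optional[float] = None
    km: Optional[float] = None
    k12: Optional[float] = None
    k21: Optional[float] = None

    @property
    def factor_a(self) -> Union[float, Mapping[int, float], None]:
        return self.ka_coef

    @property
    def slope_e(self) -> Union[float, Mapping[int, float], None]:
        return self.ke_coef

    def replace(self, **kw) -> "PKParameters":
        return replace(self, **kw)


@dataclass
class DesignSpec:
    """Sampling design of the waterborne-treatment study.

    Two arms: constant treatment sampled inside ``treatment_window`` and a
    washout arm exposed for ``treatment_duration_min`` then sampled in
    drug-free medium up to ``washout_end_min``.
    """

    ages: Sequence[int] = (3, 4, 5)
    treatment_duration_min: float = 60.0
    washout_end_min: float = 240.0
    treatment_window: Sequence[float] = (0.0, 180.0)
    treatment_times: Sequence[float] = (10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)
    washout_times: Sequence[float] = (75.0, 90.0, 105.0, 120.0, 150.0, 180.0, 210.0, 240.0)
    replicates: int = 3
    pool_size: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.treatment_window
        if any(t < lo or t > hi for t in self.treatment_times):
            raise ValueError("treatment sampling times fall outside the declared window")
        if any(
            t < self.treatment_duration_min or t > self.washout_end_min
            for t in self.washout_times
        ):
            raise ValueError("washout sampling times fall outside the declared window")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def spec_to_dict(spec: ModelSpec) -> dict:
    """Plain-dict form of a ModelSpec (YAML/JSON friendly)."""

    def cov(c: CovariateSpec) -> dict:
        coef = c.slope_or_factor
        if isinstance(coef, Mapping):
            coef = {int(k): float(v) for k, v in coef.items()}
        return {
            "form": c.form,
            "base_value": c.base_value,
            "slope_or_factor": coef,
            "reference_age_dpf": c.reference_age_dpf,
        }

    return {
        "n_compartments": spec.n_compartments,
        "elimination": spec.elimination,
        "ka_covariate": cov(spec.ka_covariate),
        "ke_covariate": cov(spec.ke_covariate),
        "error_model": spec.error_model,
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    def cov(c) -> CovariateSpec:
        if c is None:
            return CovariateSpec()
        coef = c.get("slope_or_factor")
        if isinstance(coef, Mapping):
            coef = {int(k): float(v) for k, v in coef.items()}
        return CovariateSpec(
            form=c.get("form", "none"),
            base_value=c.get("base_value"),
            slope_or_factor=coef,
            reference_age_dpf=int(c.get("reference_age_dpf", 3)),
        )

    return ModelSpec(
        n_compartments=int(d.get("n_compartments", 1)),
        elimination=d.get("elimination", "first_order"),
        ka_covariate=cov(d.get("ka_covariate")),
        ke_covariate=cov(d.get("ke_covariate")),
        error_model=d.get("error_model", "combined"),
    )


def final_model_spec() -> ModelSpec:
    """The selected model: one compartment, zero-order absorption, first-order
    elimination, discrete-step age effect on ka, power age effect on ke,
    combined residual error."""
    return ModelSpec(
        n_compartments=1,
        elimination="first_order",
        ka_covariate=CovariateSpec(form="discrete", reference_age_dpf=3),
        ke_covariate=CovariateSpec(form="power", reference_age_dpf=3),
        error_model="combined",
    )


def reported_parameters() -> PKParameters:
    """Published final-model estimates (3 dpf reference): ka 0.289 pmole/min,
    +106% step after 3 dpf; ke 0.0193 min^-1, +17.5%/day; combined error with
    proportional variance 0.109 and additive variance 0.00844."""
    return PKParameters(
        ka_base=0.289,
        ka_coef=1.06,
        ke_base=0.0193,
        ke_coef=0.175,
        sigma2_prop=0.109,
        sigma2_add=0.00844,
    )
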