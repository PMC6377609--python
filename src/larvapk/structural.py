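"""Structural model predictions: paracetamol amount per larva over time.

The core model is zero-order absorption (constant uptake rate while the larva
sits in treatment medium, since the medium concentration stays effectively
constant) with first-order elimination:

    dA/dt = ka - ke * A

whose closed form under constant treatment is A(t) = (ka/ke)(1 - exp(-ke t))
and, after transfer to drug-free medium at T_d, a mono-exponential decline
A(T_d) exp(-ke (t - T_d)).  Candidate variants — a peripheral compartment and
saturable Michaelis-Menten elimination — are integrated numerically.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import CovariateSpec, DesignSpec, ModelSpec, PKParameters

__all__ = [
    "covariate_value",
    "predict_amount",
    "predict_amounts",
    "time_to_fraction_of_steady_state",
    "clearance",
]

# adaptive stiff-capable integration; tight enough that solver error is
# negligible relative to model differences
_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


def covariate_value(spec: CovariateSpec, age: int) -> float:
    """Resolve a parameter value at a given larval age.

    Raises ValueError for a discrete form asked about an age level it does not
    define.
    """
    base = spec.base_value
    if base is None:
        raise ValueError("CovariateSpec.base_value is not set")
    coef = spec.slope_or_factor
    ref = spec.reference_age_dpf
    if spec.form == "none":
        return float(base)
    if coef is None:
        raise ValueError(f"covariate form {spec.form!r} needs slope_or_factor")
    if spec.form == "linear":
        return float(base * (1.0 + coef * (age - ref)))
    if spec.form == "power":
        return float(base * (1.0 + coef) ** (age - ref))
    # discrete
    if isinstance(coef, Mapping):
        if age == ref:
            return float(base * coef.get(age, 1.0))
        if age not in coef:
            raise ValueError(
                f"discrete covariate has no level for age {age} dpf "
                f"(levels: {sorted(coef)})"
            )
        return float(base * coef[age])
    if age == ref:
        return float(base)
    if age < ref:
        raise ValueError(
            f"discrete step covariate has no level for age {age} dpf "
            f"below the reference age {ref} dpf"
        )
    return float(base * (1.0 + coef))


def _resolve(base: float, cov: CovariateSpec, coef, age: int) -> float:
    spec = CovariateSpec(
        form=cov.form,
        base_value=base,
        slope_or_factor=coef,
        reference_age_dpf=cov.reference_age_dpf,
    )
    return covariate_value(spec, age)


def resolve_rates(params: PKParameters, spec: ModelSpec, age: int) -> tuple[float, float]:
    """ka and ke at a given age after applying the covariate functions.

    For Michaelis-Menten elimination the returned ke is NaN (vmax/km are used
    instead).
    """
    ka = _resolve(params.ka_base, spec.ka_covariate, params.ka_coef, age)
    if spec.elimination == "michaelis_menten":
        return ka, float("nan")
    ke = _resolve(params.ke_base, spec.ke_covariate, params.ke_coef, age)
    return ka, ke


def _linear_amount(ka: float, ke: float, t: np.ndarray, arm: str, t_d: float) -> np.ndarray:
    """Closed form for the linear one-compartment model, both arms."""
    t = np.asarray(t, dtype=float)
    ss = ka / ke
    uptake = ss * -np.expm1(-ke * t)
    if arm == "constant":
        return uptake
    a_td = ss * -np.expm1(-ke * t_d)
    out = np.where(t <= t_d, uptake, a_td * np.exp(-ke * np.minimum(t - t_d, np.inf)))
    return out


def _ode_amounts(
    params: PKParameters,
    spec: ModelSpec,
    age: int,
    arm: str,
    times: np.ndarray,
    design: DesignSpec,
) -> np.ndarray:
    """Numerically integrated prediction for MM and/or two-compartment variants.

    Absorption is switched off at the treatment end for the washout arm; the
    integration is split at that discontinuity.
    """
    ka, ke = resolve_rates(params, spec, age)
    two = spec.n_compartments == 2
    mm = spec.elimination == "michaelis_menten"
    if mm and (params.vmax is None or params.km is None):
        raise ValueError("Michaelis-Menten elimination needs vmax and km")
    if mm and not params.km > 0:
        raise ValueError("km must be > 0 for Michaelis-Menten elimination")
    if two and (params.k12 is None or params.k21 is None):
        raise ValueError("two-compartment model needs k12 and k21")

    def rhs(absorbing: bool):
        def f(t, y):
            a1 = y[0]
            elim = params.vmax * a1 / (params.km + a1) if mm else ke * a1
            da1 = (ka if absorbing else 0.0) - elim
            if two:
                da1 += params.k21 * y[1] - params.k12 * a1
                return [da1, params.k12 * a1 - params.k21 * y[1]]
            return [da1]

        return f

    times = np.asarray(times, dtype=float)
    order = np.argsort(times)
    t_sorted = times[order]
    y0 = [0.0, 0.0] if two else [0.0]
    t_d = design.treatment_duration_min if arm == "washout" else np.inf
    pred_sorted = np.empty_like(t_sorted)

    pre_mask = t_sorted <= t_d
    t_pre = t_sorted[pre_mask]
    t_end_pre = t_d if arm == "washout" else (t_sorted[-1] if len(t_sorted) else 0.0)
    t_end_pre = max(t_end_pre, t_pre[-1] if len(t_pre) else 0.0)
    sol = solve_ivp(
        rhs(True),
        (0.0, max(t_end_pre, 1e-9)),
        y0,
        t_eval=t_pre,
        method="LSODA",
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed (treatment phase): {sol.message}")
    pred_sorted[pre_mask] = sol.y.sum(axis=0) if len(t_pre) else []
    if arm == "washout":
        sol_td = solve_ivp(
            rhs(True),
            (0.0, t_d),
            y0,
            method="LSODA",
            rtol=_ODE_RTOL,
            atol=_ODE_ATOL,
        )
        if not sol_td.success:
            raise RuntimeError(f"ODE integration failed (treatment phase): {sol_td.message}")
        y_td = sol_td.y[:, -1]
        t_post = t_sorted[~pre_mask]
        if len(t_post):
            sol2 = solve_ivp(
                rhs(False),
                (t_d, t_post[-1]),
                y_td,
                t_eval=t_post,
                method="LSODA",
                rtol=_ODE_RTOL,
                atol=_ODE_ATOL,
            )
            if not sol2.success:
                raise RuntimeError(f"ODE integration failed (washout phase): {sol2.message}")
            pred_sorted[~pre_mask] = sol2.y.sum(axis=0)
    out = np.empty_like(pred_sorted)
    out[order] = pred_sorted
    return out


def predict_amount(
    params: PKParameters,
    spec: ModelSpec,
    age: int,
    arm: str,
    t: float,
    design: DesignSpec,
) -> float:
    """Predicted paracetamol amount (pmole/larva) at a single time point."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return float(
        predict_amounts(
            params,
            spec,
            pd.DataFrame({"age_dpf": [age], "arm": [arm], "time_min": [float(t)]}),
            design,
        )[0]
    )


def predict_amounts(
    params: PKParameters,
    spec: ModelSpec,
    data: pd.DataFrame,
    design: DesignSpec,
) -> np.ndarray:
    """Vectorised predictions for a dataset (columns age_dpf, arm, time_min)."""
    t_all = np.asarray(data["time_min"], dtype=float)
    if np.any(t_all < 0):
        raise ValueError("time must be non-negative")
    pred = np.empty(len(data), dtype=float)
    linear = spec.n_compartments == 1 and spec.elimination == "first_order"
    ages = np.asarray(data["age_dpf"])
    arms = np.asarray(data["arm"])
    for age in np.unique(ages):
        for arm in ("constant", "washout"):
            mask = (ages == age) & (arms == arm)
            if not mask.any():
                continue
            t = t_all[mask]
            if linear:
                ka, ke = resolve_rates(params, spec, int(age))
                pred[mask] = _linear_amount(ka, ke, t, arm, design.treatment_duration_min)
            else:
                pred[mask] = _ode_amounts(params, spec, int(age), arm, t, design)
    return pred


class CompiledPredictor:
    """Pre-grouped prediction kernel for repeated evaluation over one dataset.

    Splitting the rows by (age, arm) once removes the per-call DataFrame
    overhead from the optimiser's inner loop; predictions are identical to
    :func:`predict_amounts`.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, design: DesignSpec):
        self.spec = spec
        self.design = design
        self.n = len(data)
        self.linear = spec.n_compartments == 1 and spec.elimination == "first_order"
        t_all = np.asarray(data["time_min"], dtype=float)
        if np.any(t_all < 0):
            raise ValueError("time must be non-negative")
        ages = np.asarray(data["age_dpf"])
        arms = np.asarray(data["arm"])
        self.groups = []
        for age in np.unique(ages):
            for arm in ("constant", "washout"):
                mask = (ages == age) & (arms == arm)
                if mask.any():
                    self.groups.append((int(age), arm, np.where(mask)[0], t_all[mask]))

    def __call__(self, params: PKParameters) -> np.ndarray:
        pred = np.empty(self.n, dtype=float)
        td = self.design.treatment_duration_min
        for age, arm, idx, t in self.groups:
            if self.linear:
                ka, ke = resolve_rates(params, self.spec, age)
                pred[idx] = _linear_amount(ka, ke, t, arm, td)
            else:
                pred[idx] = _ode_amounts(params, self.spec, age, arm, t, self.design)
        return pred


def time_to_fraction_of_steady_state(ke: float, fraction: float) -> float:
    """Minutes until the constant-treatment amount reaches a given fraction of
    its plateau ka/ke; closed form -ln(1 - f)/ke for the linear model (the
    approach rate depends on ke only)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if not ke > 0:
        raise ValueError("ke must be > 0")
    return float(-np.log1p(-fraction) / ke)


def clearance(ke: float, total_volume_nL: float) -> float:
    """Clearance in nL/h from the elimination rate constant (min^-1) and the
    total larval volume (nL), assuming homogeneous whole-body distribution."""
    if ke < 0:
        raise ValueError("ke must be non-negative")
    if not total_volume_nL > 0:
        raise ValueError("volume must be > 0")
    return float(ke * total_volume_nL * 60.0)
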