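"""scikit-learn-style estimators wrapping the PK fit and the allometric fit.

`PKModelFit` follows the sklearn estimator contract (get_params/set_params,
fitted attributes with trailing underscores, ValueError on bad input), so it
composes with sklearn tooling; `X` is the longitudinal dataset as a DataFrame
(one row per pooled sample) and `y` is unused — the response column
``amount_pmole`` travels inside `X`, as the observations are a single table
in this field's workflows.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import estimation
from .allometry import fit_allometric, fraction_of_lower_bound
from .models import DesignSpec, ModelSpec, PKParameters, final_model_spec
from .simulate import default_study_design
from .structural import predict_amounts

__all__ = ["PKModelFit", "AllometricScaling"]

_REQUIRED_COLS = ("age_dpf", "arm", "time_min", "amount_pmole")


class PKModelFit(BaseEstimator):
    """Maximum-likelihood fit of a structural PK model to pooled-sample data.

    Parameters
    ----------
    model_spec : ModelSpec, optional
        Structural/covariate/error specification; defaults to the selected
        final model (discrete-step ka, power ke, combined error).
    design : DesignSpec, optional
        Study design (treatment duration, windows); defaults to the study's.
    init : PKParameters, optional
        Starting values; data-driven defaults when omitted.
    n_restarts : int
        Multi-start count with jittered initial values.
    seed : int
        Seed for the jitter.

    Attributes
    ----------
    result_ : estimation.FitResult
    params_ : PKParameters
    ofv_ : float        -2 log-likelihood at the optimum
    rse_percent_ : dict or None
    converged_ : bool
    """

    def __init__(
        self,
        model_spec: Optional[ModelSpec] = None,
        design: Optional[DesignSpec] = None,
        init: Optional[PKParameters] = None,
        n_restarts: int = 10,
        seed: int = 0,
    ):
        self.model_spec = model_spec
        self.design = design
        self.init = init
        self.n_restarts = n_restarts
        self.seed = seed

    def _spec(self) -> ModelSpec:
        return self.model_spec if self.model_spec is not None else final_model_spec()

    def _design(self) -> DesignSpec:
        return self.design if self.design is not None else default_study_design()

    @staticmethod
    def _validate(X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValueError("X must be a DataFrame of pooled-sample observations")
        missing = [c for c in _REQUIRED_COLS if c not in X.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(X) == 0:
            raise ValueError("empty dataset")
        return X.reset_index(drop=True)

    def fit(self, X: pd.DataFrame, y=None) -> "PKModelFit":
        X = self._validate(X)
        res = estimation.fit(
            X,
            self._spec(),
            self._design(),
            init=self.init,
            n_restarts=self.n_restarts,
            seed=self.seed,
        )
        self.result_ = res
        self.params_ = res.estimates
        self.ofv_ = res.ofv
        self.rse_percent_ = res.rse_percent
        self.converged_ = res.converged
        self.n_obs_ = res.n_obs
        self.n_params_ = res.n_params
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise ValueError("estimator is not fitted yet")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("X must be a DataFrame")
        return predict_amounts(self.params_, self._spec(), X, self._design())

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per observation (higher is better)."""
        X = self._validate(X)
        return -0.5 * estimation.neg2_loglik(
            self.params_, self._spec(), X, self._design()
        ) / len(X)


class AllometricScaling(BaseEstimator, RegressorMixin):
    """Interspecies log10-log10 regression of clearance on bodyweight.

    Fitted on mature records only; immature rows are ignored by `fit` and can
    be compared against the band afterwards.

    Attributes
    ----------
    slope_, intercept_ : float   on log10 axes
    fit_ : allometry.AllometricFit
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, X: pd.DataFrame, y=None) -> "AllometricScaling":
        self.fit_ = fit_allometric(X, level=self.level)
        self.slope_ = self.fit_.slope
        self.intercept_ = self.fit_.intercept
        return self

    def predict(self, bodyweight_g) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ValueError("estimator is not fitted yet")
        bw = np.asarray(bodyweight_g, dtype=float)
        if bw.ndim == 2:  # sklearn-style column vector
            bw = bw.ravel()
        return self.fit_.predict(bw)

    def confidence_band(self, bodyweight_g):
        if not hasattr(self, "fit_"):
            raise ValueError("estimator is not fitted yet")
        return self.fit_.conf_band(bodyweight_g)

    def fraction_of_lower_bound(self, clearance: float, bodyweight_g: float) -> float:
        if not hasattr(self, "fit_"):
            raise ValueError("estimator is not fitted yet")
        return fraction_of_lower_bound(clearance, bodyweight_g, self.fit_)
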