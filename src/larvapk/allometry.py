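"""Allometric scaling of clearance across species.

Clearance follows an approximate power law in bodyweight, CL = a * BW^b,
linear on log-log axes.  The interspecies line and its 95% confidence band
are fitted on mature individuals only (immature records are kept for
comparison, never for fitting); a larva's clearance is then expressed as a
percentage of the band's lower bound at its bodyweight — extrapolation far
below the fitted range is the point of the exercise, and is flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SpeciesClearanceRecord",
    "AllometricFit",
    "bodyweight_from_volume",
    "fit_allometric",
    "fraction_of_lower_bound",
]

LARVAL_DENSITY_G_PER_ML = 0.997


@dataclass(frozen=True)
class SpeciesClearanceRecord:
    species: str
    bodyweight_g: float
    clearance: float  # in the table's declared units, harmonised on read
    mature: bool

    def __post_init__(self):
        if not self.bodyweight_g > 0:
            raise ValueError("bodyweight must be > 0")
        if not self.clearance > 0:
            raise ValueError("clearance must be > 0")


@dataclass
class AllometricFit:
    """OLS fit of log10(CL) on log10(BW) over mature records.

    ``conf_band`` maps bodyweight (g) to the (lower, upper) 95% mean-prediction
    confidence bounds of clearance on the linear scale.
    """

    intercept: float
    slope: float
    residual_variance: float
    n_mature: int
    bw_range_g: tuple[float, float]
    conf_band: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    result: object = None  # statsmodels results, for downstream inspection

    def predict(self, bodyweight_g) -> np.ndarray:
        bw = np.asarray(bodyweight_g, dtype=float)
        return 10.0 ** (self.intercept + self.slope * np.log10(bw))


def bodyweight_from_volume(
    volume_nL: float, density_g_per_mL: float = LARVAL_DENSITY_G_PER_ML
) -> float:
    """Larval bodyweight (g) from total volume (nL) at near-water density."""
    if not volume_nL > 0:
        raise ValueError("volume must be > 0")
    return float(volume_nL * 1e-6 * density_g_per_mL)


def fit_allometric(records: pd.DataFrame, level: float = 0.95) -> AllometricFit:
    """Least-squares log-log regression on the mature records.

    ``records`` needs columns bodyweight_g, clearance, mature (all clearances
    already in one consistent unit).  At least 3 mature records with distinct
    bodyweights are required for a meaningful band.
    """
    req = {"bodyweight_g", "clearance", "mature"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    mature = records.loc[records["mature"].astype(bool)]
    if len(mature) < 3:
        raise ValueError(f"need >= 3 mature records to fit, got {len(mature)}")
    bw = np.asarray(mature["bodyweight_g"], dtype=float)
    cl = np.asarray(mature["clearance"], dtype=float)
    if np.any(bw <= 0) or np.any(cl <= 0):
        raise ValueError("bodyweights and clearances must be > 0")
    if len(np.unique(bw)) < 2:
        raise ValueError("mature bodyweights must not all coincide")
    x = np.log10(bw)
    y = np.log10(cl)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()

    def conf_band(bodyweight_g):
        bwq = np.atleast_1d(np.asarray(bodyweight_g, dtype=float))
        Xq = sm.add_constant(np.log10(bwq), has_constant="add")
        pred = ols.get_prediction(Xq)
        lo, hi = pred.conf_int(alpha=1.0 - level).T  # mean-prediction interval
        return 10.0**lo, 10.0**hi

    return AllometricFit(
        intercept=float(ols.params[0]),
        slope=float(ols.params[1]),
        residual_variance=float(ols.mse_resid),
        n_mature=len(mature),
        bw_range_g=(float(bw.min()), float(bw.max())),
        conf_band=conf_band,
        result=ols,
    )


def fraction_of_lower_bound(
    larval_cl: float, larval_bw_g: float, fit: AllometricFit
) -> float:
    """Larval clearance as % of the lower 95% confidence bound of the mature
    interspecies regression extrapolated to the larval bodyweight."""
    if not larval_bw_g > 0:
        raise ValueError("bodyweight must be > 0")
    lo, _ = fit.conf_band(larval_bw_g)
    if not (fit.bw_range_g[0] <= larval_bw_g <= fit.bw_range_g[1]):
        warnings.warn(
            f"bodyweight {larval_bw_g:g} g lies outside the fitted range "
            f"{fit.bw_range_g}; the bound is an extrapolation"
        )
    return float(100.0 * larval_cl / lo[0])
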