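"""Goodness-of-fit quantities: predictions, residuals, weighted residuals.

With no random effects in the model, conditional weighted residuals reduce to
ordinary variance-weighted residuals, wres_i = (obs_i - pred_i)/sqrt(v_i) with
v_i from the fitted error model; we report them as "weighted residuals
(CWRES-equivalent)".  A well-specified model shows wres with mean ~0 and
variance ~1 and no trend over time or over predicted amounts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import FitResult, _variances
from .models import DesignSpec, ModelSpec
from .structural import predict_amounts

__all__ = ["weighted_residuals", "gof_table", "plot_gof"]

GOF_COLUMNS = (
    "sample_id",
    "age_dpf",
    "arm",
    "time_min",
    "observed",
    "predicted",
    "residual",
    "variance",
    "wres",
)


def weighted_residuals(
    fit_result: FitResult,
    data: pd.DataFrame,
    spec: ModelSpec,
    design: DesignSpec,
) -> pd.DataFrame:
    """One GOF record per observation, in input order."""
    if not fit_result.converged:
        raise ValueError("weighted residuals require a converged fit")
    data = data.reset_index(drop=True)
    pred = predict_amounts(fit_result.estimates, spec, data, design)
    obs = np.asarray(data["amount_pmole"], dtype=float)
    v = _variances(pred, fit_result.estimates, spec.error_model)
    if np.any(v <= 0):
        raise ValueError("zero residual variance; weighted residuals undefined")
    res = obs - pred
    out = pd.DataFrame(
        {
            "sample_id": data.get("sample_id", pd.RangeIndex(len(data)).astype(str)),
            "age_dpf": data["age_dpf"],
            "arm": data["arm"],
            "time_min": data["time_min"],
            "observed": obs,
            "predicted": pred,
            "residual": res,
            "variance": v,
            "wres": res / np.sqrt(v),
        }
    )
    return out


def gof_table(records: pd.DataFrame, out_path=None) -> pd.DataFrame:
    """Validate and optionally write the GOF table (CSV).

    The one table carries both views used for assessment: observed vs
    predicted, and weighted residuals vs time / vs predicted.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty GOF records")
    missing = [c for c in GOF_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"GOF records missing columns: {missing}")
    table = records.loc[:, list(GOF_COLUMNS)]
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table


def plot_gof(records: pd.DataFrame, out_path) -> Path:
    """Optional thin plotting layer: obs-vs-pred, wres-vs-time, wres-vs-pred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(records) == 0:
        raise ValueError("empty GOF records")
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].scatter(records["predicted"], records["observed"], s=12)
    lim = [0, float(max(records["predicted"].max(), records["observed"].max())) * 1.05]
    axes[0].plot(lim, lim, "k--", lw=1)
    axes[0].set_xlabel("predicted (pmole/larva)")
    axes[0].set_ylabel("observed (pmole/larva)")
    for ax, xcol, xlab in (
        (axes[1], "time_min", "time (min)"),
        (axes[2], "predicted", "predicted (pmole/larva)"),
    ):
        ax.scatter(records[xcol], records["wres"], s=12)
        ax.axhline(0.0, color="k", ls="--", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("weighted residual")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
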