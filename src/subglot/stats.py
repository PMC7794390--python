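"""Threshold-pressure statistics and condition comparisons.

The reference model for the onset/offset threshold pressures is ordinary
least squares on the log-transformed pressure with categorical fixed
effects for condition (anechoic vs. resonant), larynx, sweep and
repetition.  The condition coefficient beta is reported as a percent
change (1 - exp(beta)) * 100, positive when the resonant condition
lowers the threshold, with its 95 % confidence interval and two-sided
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .source import THRESHOLD_TABLE_COLUMNS

__all__ = ["EffectEstimate", "fit_threshold_model", "percent_effect",
           "spl_difference_by_pressure"]

_FORMULA = (
    "np.log({col}) ~ C(condition, Treatment('anechoic')) "
    "+ C(larynx_id) + C(sweep_index) + C(repetition)"
)
_COND_TERM = "C(condition, Treatment('anechoic'))[T.resonant]"


@dataclass
class EffectEstimate:
    """Condition effect on a threshold pressure, on the percent scale."""

    percent_change: float
    ci_low: float
    ci_high: float
    p_value: float
    response: str
    n_rows: int
    beta: float = float("nan")
    formula: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.percent_change <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "percent_change": self.percent_change,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_rows": self.n_rows,
            "beta": self.beta,
            "model": self.formula,
        }


def percent_effect(beta: float) -> float:
    """Log-scale condition coefficient -> percent reduction.

    Coded so that a resonant-condition lowering (beta < 0) gives a
    positive percent: (1 - exp(beta)) * 100.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return (1.0 - np.exp(beta)) * 100.0


def fit_threshold_model(table: pd.DataFrame, response: str) -> EffectEstimate:
    """OLS on log threshold pressure with categorical predictors.

    ``response`` selects ``"onset"`` or ``"offset"``.  Requires a table
    with both conditions present and strictly positive pressures.
    """
    if response not in ("onset", "offset"):
        raise ValueError("response must be 'onset' or 'offset'")
    missing = set(THRESHOLD_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if table["condition"].nunique() < 2:
        raise ValueError("both conditions are required to estimate the effect")
    col = f"{response}_pressure"
    if not (table[col] > 0).all():
        raise ValueError("threshold pressures must be positive")

    fit = smf.ols(_FORMULA.format(col=col), data=table).fit()
    beta = float(fit.params[_COND_TERM])
    lo_b, hi_b = (float(v) for v in fit.conf_int().loc[_COND_TERM])
    # percent_effect is decreasing in beta: the CI endpoints swap
    ci = sorted((percent_effect(lo_b), percent_effect(hi_b)))
    p = float(fit.pvalues[_COND_TERM])
    if not np.isfinite(p):  # perfect (noise-free) fit
        p = 0.0 if beta != 0 else 1.0
    return EffectEstimate(
        percent_change=percent_effect(beta),
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        response=response,
        n_rows=len(table),
        beta=beta,
        formula=_FORMULA.format(col=col),
    )


def spl_difference_by_pressure(
    anechoic, resonant, p_min: float = 8.0, n_grid: int = 50
) -> dict:
    """Resonant-minus-anechoic SPL difference at matched mean pressures.

    ``anechoic`` and ``resonant`` are sequences of (pressure hPa, SPL dB)
    pairs.  Both curves are interpolated onto a common pressure grid
    above ``p_min``; the mean and range of the difference are returned.
    """
    def prep(series):
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("series must be (pressure, spl) pairs")
        arr = arr[arr[:, 0] >= p_min]
        if arr.size == 0:
            raise ValueError(f"no points above p_min = {p_min} hPa")
        order = np.argsort(arr[:, 0])
        return arr[order]

    a = prep(anechoic)
    r = prep(resonant)
    lo = max(a[0, 0], r[0, 0])
    hi = min(a[-1, 0], r[-1, 0])
    if not hi > lo:
        raise ValueError("pressure ranges do not overlap above p_min")
    grid = np.linspace(lo, hi, n_grid)
    diff = np.interp(grid, r[:, 0], r[:, 1]) - np.interp(grid, a[:, 0], a[:, 1])
    return {
        "mean_db": float(diff.mean()),
        "min_db": float(diff.min()),
        "max_db": float(diff.max()),
        "p_low": float(lo),
        "p_high": float(hi),
        "n_grid": n_grid,
    }
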