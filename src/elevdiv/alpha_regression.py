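"""Elevational alpha-diversity regressions and strategy comparison.

Per strategy and Hill order q, the rarefied diversity of each sample is
regressed on elevation by OLS; the replicate and transect strategies are
compared with an ANCOVA (diversity ~ elevation * strategy), whose
elevation x strategy interaction term tests for a difference in slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import SampleMeta

__all__ = ["SlopeResult", "fit_elevation_trend", "compare_slopes_ancova"]


@dataclass(frozen=True)
class SlopeResult:
    """OLS fit of a diversity estimate on elevation."""

    q: float
    strategy: str
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int
    r_squared: float


def _check_xy(elev: np.ndarray, y: np.ndarray) -> None:
    if len(elev) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(elev) == 0:
        raise ValueError("elevation is constant; slope undefined")


def fit_elevation_trend(
    estimates: pd.Series,
    meta: SampleMeta,
    q: float = 0.0,
    strategy: str = "",
) -> SlopeResult:
    """OLS of per-sample Hill estimates (indexed by sample id) on elevation."""
    elev = meta.frame.loc[estimates.index, "elevation_m"].to_numpy(dtype=float)
    y = estimates.to_numpy(dtype=float)
    _check_xy(elev, y)
    X = sm.add_constant(elev)
    fit = sm.OLS(y, X).fit()
    return SlopeResult(
        q=q,
        strategy=strategy,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=len(y),
        r_squared=float(fit.rsquared),
    )


def compare_slopes_ancova(
    replicate: tuple[np.ndarray, np.ndarray],
    transect: tuple[np.ndarray, np.ndarray],
) -> float:
    """p-value of the elevation x strategy interaction.

    Each argument is (elevation, estimate).  The two datasets are stacked
    with a strategy indicator; the model estimate ~ elevation + strategy +
    elevation:strategy is fitted by OLS and the two-sided t-test p of the
    interaction coefficient returned.  Samples shared between strategies
    legitimately appear in both groups (a feature of the sampling design).
    """
    (e1, y1), (e2, y2) = replicate, transect
    e1, y1 = np.asarray(e1, float), np.asarray(y1, float)
    e2, y2 = np.asarray(e2, float), np.asarray(y2, float)
    _check_xy(e1, y1)
    _check_xy(e2, y2)
    elev = np.concatenate([e1, e2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(e1)), np.ones(len(e2))])
    X = np.column_stack([np.ones_like(elev), elev, g, elev * g])
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[3])
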