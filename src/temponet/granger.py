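"""Pooled Granger causality F-test for lag-1 bivariate models.

X Granger-causes Y when X's past improves prediction of Y beyond Y's own
past. The test compares two nested least-squares fits on stacked lagged
rows:

    reduced:  y_t ~ 1 + y_{t-1}
    full:     y_t ~ 1 + y_{t-1} + x_{t-1}

and refers F = (RSS_r - RSS_f) / (RSS_f / (n - k_full)) to the
F(1, n - k_full) upper tail. With an intercept, k_full = 3. Only
first-order, stationary dynamics are modelled: a single shared
coefficient set is fitted across all pooled individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import LaggedDesign

logger = logging.getLogger(__name__)

__all__ = ["GrangerResult", "ols_fit", "granger_test"]

# below this share of the reduced-model RSS the full fit is treated as exact
_DEGENERATE_REL = 1e-12


class InsufficientDataError(ValueError):
    """Raised when a design has too few rows for the requested fit."""


@dataclass
class GrangerResult:
    """Outcome of one ordered-pair Granger causality test."""

    rss_full: float
    rss_reduced: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    coef_full: np.ndarray
    coef_reduced: np.ndarray
    n_rows: int
    degenerate: bool = False
    collinear: bool = False


def ols_fit(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit; returns (coefficients, residual sum of squares).

    Rank-deficient designs are solved by the minimum-norm solution with a
    logged warning. Fewer rows than columns raises
    :class:`InsufficientDataError`.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    n, k = design.shape
    if n < k:
        raise InsufficientDataError(f"{n} rows < {k} columns")
    if not (np.isfinite(design).all() and np.isfinite(response).all()):
        raise ValueError("non-finite values in design or response")
    coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < k:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "minimum-norm solution used", rank, k)
    resid = response - design @ coef
    return coef, float(resid @ resid)


def granger_test(design: LaggedDesign, intercept: bool = True) -> GrangerResult:
    """Run the nested F-test on a stacked lagged design.

    A constant x_lag column carries no information and would make the
    full design singular; such tests are skipped with ``collinear=True``
    and p = 1. An exactly collinear response (RSS_full = 0, the noiseless
    case) is reported with p = 0 and ``degenerate=True``.
    """
    k_full = 3 if intercept else 2
    n = design.n_rows
    if n < k_full + 1:
        raise InsufficientDataError(
            f"need at least {k_full + 1} rows for df2 >= 1, got {n}")

    if intercept:
        x_red = np.column_stack([np.ones(n), design.y_lag])
        x_full = np.column_stack([np.ones(n), design.y_lag, design.x_lag])
    else:
        x_red = design.y_lag[:, None]
        x_full = np.column_stack([design.y_lag, design.x_lag])

    coef_red, rss_red = ols_fit(x_red, design.y)

    if np.ptp(design.x_lag) == 0.0:
        return GrangerResult(
            rss_full=rss_red, rss_reduced=rss_red, f_stat=0.0,
            df1=1, df2=n - k_full, p_value=1.0,
            coef_full=np.append(coef_red, 0.0), coef_reduced=coef_red,
            n_rows=n, collinear=True,
        )

    coef_full, rss_full = ols_fit(x_full, design.y)
    df2 = n - k_full
    if rss_full <= _DEGENERATE_REL * max(rss_red, 1.0):
        return GrangerResult(
            rss_full=rss_full, rss_reduced=rss_red, f_stat=np.inf,
            df1=1, df2=df2, p_value=0.0,
            coef_full=coef_full, coef_reduced=coef_red,
            n_rows=n, degenerate=True,
        )
    f_stat = (rss_red - rss_full) / (rss_full / df2)
    f_stat = max(f_stat, 0.0)  # guard against roundoff on nested fits
    p = float(stats.f.sf(f_stat, 1, df2))
    return GrangerResult(
        rss_full=rss_full, rss_reduced=rss_red, f_stat=float(f_stat),
        df1=1, df2=df2, p_value=p,
        coef_full=coef_full, coef_reduced=coef_red, n_rows=n,
    )
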