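"""Statistical layer: through-origin quadratic dP-Q fits, RMSE, ordinary
least squares with R^2, and FFR-vs-angle difference tables.

The stenosis pressure drop as a function of flow is decomposed as

    dP = A*Q + B*Q^2

with no intercept (dP(0) = 0 physically): A captures viscous (Poiseuille)
friction losses, B the convective (Bernoulli) acceleration losses through the
narrowing.  Goodness of fit is summarized by a degrees-of-freedom corrected
RMSE, sqrt(sum(residuals^2) / (n - m)) with m fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal

import numpy as np
import pandas as pd

from .errors import FitError, InvalidParameterError


@dataclass(frozen=True)
class DpQPoint:
    """One (side-branch flow, pressure drop) observation."""

    q: float        # mL/min
    dp: float       # mmHg
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise InvalidParameterError("flow must be positive")
        if not np.isfinite(self.dp):
            raise InvalidParameterError("pressure drop must be finite")


@dataclass(frozen=True)
class QuadraticFit:
    """Through-origin quadratic fit dP = A*Q + B*Q^2.

    ``a`` in mmHg.min/mL, ``b`` in mmHg.min^2/mL^2; ``rmse`` is None when the
    fit has zero residual degrees of freedom (n = m = 2).
    """

    a: float
    b: float
    rmse: float | None
    n_points: int

    def predict(self, q):
        q = np.asarray(q, dtype=float)
        return self.a * q + self.b * q * q

    def rounded(self) -> tuple[float, float, float | None]:
        """(A, B, RMSE) at reporting precision: 3, 3 and 2 decimals."""
        r = None if self.rmse is None else round(self.rmse, 2)
        return round(self.a, 3), round(self.b, 3), r


def fit_dp_q(points: list[DpQPoint]) -> QuadraticFit:
    """Least-squares through-origin quadratic fit of dP against Q.

    Requires at least two points with distinct flows; with exactly two the
    system is solved exactly and the RMSE is undefined (flagged as None).
    """
    if len(points) < 2:
        raise FitError("need at least 2 points for a 2-coefficient fit")
    q = np.array([p.q for p in points], dtype=float)
    dp = np.array([p.dp for p in points], dtype=float)
    if len(np.unique(q)) < 2:
        raise FitError("points have fewer than 2 distinct flow values")
    X = np.column_stack([q, q * q])
    coef, _, rank, _ = np.linalg.lstsq(X, dp, rcond=None)
    if rank < 2:
        raise FitError("singular design matrix in dP-Q fit")
    n, m = len(points), 2
    r = None if n == m else rmse(dp, X @ coef, m)
    return QuadraticFit(a=float(coef[0]), b=float(coef[1]), rmse=r, n_points=n)


def rmse(observed, predicted, m: int) -> float:
    """Degrees-of-freedom corrected root mean squared error.

    sqrt( sum((y - yhat)^2) / (n - m) ) with ``m`` fitted coefficients.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise InvalidParameterError("observed and predicted lengths differ")
    n = len(y)
    if n <= m:
        raise FitError(f"RMSE undefined: n={n} response values, m={m} coefficients")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / (n - m)))


def linear_fit_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns (slope,
    intercept, r^2) with r^2 = 1 - SS_res/SS_tot."""
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise FitError("need at least 3 points for a linear regression")
    if np.var(x) == 0:
        raise FitError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _round_half_down(x: float, decimals: int = 2) -> float:
    """Round with exact halves going toward zero (the convention that
    reproduces the printed FFR angle-difference table, including its one
    half-way entry)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.6f}").quantize(q, rounding=ROUND_HALF_DOWN))


def angle_difference_table(results: pd.DataFrame,
                           angle_low: float = 40.0, angle_high: float = 70.0) -> pd.DataFrame:
    """FFR_SB difference between the smallest and largest distal angles.

    ``results`` must contain columns ``sb_stenosis_pct``, ``alpha_deg``,
    ``split_sb_pct`` and ``ffr_sb`` (the per-case results table).  Returns one
    row per (SB stenosis, flow split) with FFR_SB(angle_low) -
    FFR_SB(angle_high), rounded to 2 decimals (exact halves toward zero).
    """
    required = {"sb_stenosis_pct", "alpha_deg", "split_sb_pct", "ffr_sb"}
    missing = required - set(results.columns)
    if missing:
        raise InvalidParameterError(f"results table missing columns {sorted(missing)}")
    rows = []
    for (sb, split), grp in results.groupby(["sb_stenosis_pct", "split_sb_pct"], sort=True):
        lo = grp.loc[grp.alpha_deg == angle_low, "ffr_sb"]
        hi = grp.loc[grp.alpha_deg == angle_high, "ffr_sb"]
        if len(lo) != 1 or len(hi) != 1:
            raise InvalidParameterError(
                f"missing {angle_low} or {angle_high} deg case for SB {sb}%, split {split}%")
        rows.append({"sb_stenosis_pct": sb, "split_sb_pct": split,
                     "ffr_sb_diff": _round_half_down(float(lo.iloc[0]) - float(hi.iloc[0]))})
    return pd.DataFrame(rows)
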