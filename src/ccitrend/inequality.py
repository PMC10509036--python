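"""Within-country inequality in coverage.

Two absolute measures, matching the stratifier's measurement scale:

* urban-rural gap — residence is nominal, so absolute inequality is the
  signed percentage-point difference urban minus rural;
* slope index of inequality (SII) — wealth quintiles and education levels
  are ordinal, so inequality is the slope of a weighted regression of
  coverage on the cumulative population ranking (ridit scores), i.e. the
  modelled difference in coverage between the very top and very bottom of
  the distribution, in percentage points.

The SII regression can run on the natural scale (default; the coefficient
is directly in percentage points) or on the log of the coverage proportion,
in which case the predicted end-points are back-transformed before
differencing.  Uncertainty propagates by applying either measure per
posterior draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "OrderedStratumSeries",
    "SiiResult",
    "ridit_scores",
    "sii",
    "sii_draws",
    "urban_rural_gap",
    "inequality_trend",
]


@dataclass
class OrderedStratumSeries:
    """Per-level coverage for one ordered stratifier in one country-year.

    ``levels`` are ordered from most to least disadvantaged (Q1 -> Q5,
    none -> secondary+); ``cci`` is on the percent scale (0-100);
    ``shares`` are population shares summing to 1 (equal by default —
    wealth quintiles are fifths by construction).
    """

    levels: list[str]
    cci: np.ndarray
    shares: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cci = np.asarray(self.cci, dtype=float)
        if len(self.levels) != self.cci.shape[-1]:
            raise ValueError("levels and cci lengths differ")
        if len(self.levels) < 2:
            raise ValueError("need at least 2 ordered levels")
        if self.shares is None:
            self.shares = np.full(len(self.levels), 1.0 / len(self.levels))
        else:
            self.shares = np.asarray(self.shares, dtype=float)
            if self.shares.shape != (len(self.levels),):
                raise ValueError("shares length differs from levels")
        if np.any(self.shares <= 0):
            raise ValueError("population shares must be positive")
        if abs(self.shares.sum() - 1.0) > 1e-8:
            raise ValueError("population shares must sum to 1")
        if np.any(~np.isfinite(self.cci)) or np.any(self.cci < 0) or np.any(self.cci > 100):
            raise ValueError("CCI values must be percentages in [0, 100]")


@dataclass
class SiiResult:
    sii: float                     # percentage points (top minus bottom)
    scale: str                     # "natural" | "log"
    intercept: float               # fitted value at ridit 0 (model scale)
    slope: float                   # regression slope (model scale)
    ridits: np.ndarray = field(default=None)


def ridit_scores(shares) -> np.ndarray:
    """Midpoint of each level's cumulative population interval.

    score_g = (cumulative share below g) + share_g / 2; strictly increasing
    and inside (0, 1) whenever all shares are positive.
    """
    s = np.asarray(shares, dtype=float)
    if np.any(s <= 0):
        raise ValueError("shares must be strictly positive")
    if abs(s.sum() - 1.0) > 1e-8:
        raise ValueError("shares must sum to 1")
    cum = np.concatenate([[0.0], np.cumsum(s)])[:-1]
    return cum + s / 2.0


def sii(series: OrderedStratumSeries, scale: str = "natural") -> SiiResult:
    """Slope index of inequality by weighted least squares on ridit scores.

    natural scale: SII is the WLS slope itself (fit at ridit 1 minus fit at
    ridit 0), in percentage points.  log scale: the regression runs on
    ln(CCI proportion) and SII = 100 * (exp(fit at 1) - exp(fit at 0)),
    back on the percentage-point scale.  Weights are population shares.
    """
    x = ridit_scores(series.shares)
    if scale == "natural":
        yv = series.cci
    elif scale == "log":
        if np.any(series.cci <= 0):
            raise ValueError("log scale requires strictly positive CCI")
        yv = np.log(series.cci / 100.0)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    X = sm.add_constant(x)
    res = sm.WLS(yv, X, weights=series.shares).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    if scale == "natural":
        value = slope
    else:
        value = 100.0 * (np.exp(intercept + slope) - np.exp(intercept))
    return SiiResult(sii=float(value), scale=scale, intercept=intercept,
                     slope=slope, ridits=x)


def sii_draws(level_cci_draws: np.ndarray, shares=None) -> np.ndarray:
    """Natural-scale SII applied to a (draws, levels) matrix at once.

    The natural-scale SII is linear in the level coverages, so the WLS
    slope reduces to a fixed coefficient vector c with SII = c @ cci; this
    evaluates that functional per posterior draw (percent scale in, percentage
    points out).  Agrees with :func:`sii` column-wise.
    """
    d = np.atleast_2d(np.asarray(level_cci_draws, dtype=float))
    g = d.shape[1]
    if shares is None:
        shares = np.full(g, 1.0 / g)
    shares = np.asarray(shares, dtype=float)
    x = ridit_scores(shares)
    X = np.column_stack([np.ones(g), x])
    W = np.diag(shares)
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W)  # (2, g); row 1 = slope functional
    return d @ coef[1]


def urban_rural_gap(urban_cci: float, rural_cci: float) -> float:
    """Signed urban minus rural coverage difference in percentage points."""
    for v in (urban_cci, rural_cci):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"CCI percentage out of range: {v}")
    return float(urban_cci) - float(rural_cci)


def inequality_trend(values: pd.Series | dict, *,
                     narrowing_threshold: float = 0.0,
                     large_reduction: float = 10.0) -> dict:
    """Start-to-end change of a yearly inequality series.

    ``values`` maps year -> SII or gap (percentage points).  The flag is
    "narrowing" when |inequality| falls by more than ``narrowing_threshold``
    points, "widening" when it grows, "stable" otherwise;
    ``large_reduction_met`` marks reductions of at least ``large_reduction``
    points (10 by default).
    """
    s = pd.Series(dict(values)).sort_index()
    if len(s) < 2:
        raise ValueError("need at least 2 time points")
    start, end = float(s.iloc[0]), float(s.iloc[-1])
    change = end - start
    abs_change = abs(end) - abs(start)
    if abs_change < -narrowing_threshold and abs_change != 0.0:
        flag = "narrowing"
    elif abs_change > narrowing_threshold and abs_change != 0.0:
        flag = "widening"
    else:
        flag = "stable"
    return {"start_year": int(s.index[0]), "end_year": int(s.index[-1]),
            "start": start, "end": end, "change": change,
            "flag": flag, "large_reduction_met": abs_change <= -large_reduction}
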