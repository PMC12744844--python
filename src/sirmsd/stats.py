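"""Correlation and regression machinery linking siRMSD (or ΔTm) to SOA.

Pearson r with the exact t-based two-sided p value and a Fisher-z 95%
confidence interval; ordinary least-squares fits with a mean-response
confidence band; grouped correlation reports over the seed region (per
position, positions 2–8, 2–5, 6–8).  Welch's t test and one-way ANOVA are
provided as thin from-definition auxiliaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import SirmsdError


@dataclass
class CorrelationReport:
    r: float
    n: int
    p: float
    ci95: tuple[float, float]
    defined: bool = True

    @classmethod
    def undefined(cls, n: int) -> "CorrelationReport":
        nan = float("nan")
        return cls(r=nan, n=n, p=nan, ci95=(nan, nan), defined=False)


@dataclass
class RegressionBand:
    slope: float
    intercept: float
    x: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def pearson(x: Sequence[float], y: Sequence[float],
            level: float = 0.95) -> CorrelationReport:
    """Sample Pearson correlation with t-based p and Fisher-z CI.

    Zero variance in either series yields an undefined-correlation sentinel
    (``defined=False``) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SirmsdError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise SirmsdError("need at least 3 points for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SirmsdError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport.undefined(n)

    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))

    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))

    if n >= 4 and abs(r) < 1.0:
        z = math.atanh(r)
        half = float(sps.norm.ppf(0.5 + level / 2.0)) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (float("nan"), float("nan")) if abs(r) < 1.0 else (r, r)
    return CorrelationReport(r=r, n=n, p=p, ci95=ci)


def fit_with_band(x: Sequence[float], y: Sequence[float],
                  level: float = 0.95,
                  grid: Optional[Sequence[float]] = None) -> RegressionBand:
    """OLS line with the mean-response confidence band (t, n−2 df).

    The band is for the conditional mean (the shaded region around a
    regression line), not a prediction interval for new observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise SirmsdError("need at least 3 points")
    if np.ptp(x) == 0:
        raise SirmsdError("degenerate x: zero variance")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    grid_x = x if grid is None else np.asarray(grid, dtype=float)
    pred = fit.get_prediction(sm.add_constant(grid_x))
    ci = pred.conf_int(alpha=1.0 - level)
    return RegressionBand(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        x=grid_x,
        fitted=np.asarray(pred.predicted_mean, dtype=float),
        lower=ci[:, 0],
        upper=ci[:, 1],
        level=level,
    )


GROUPINGS = ("per-position", "2-8", "2-5", "6-8")


def _group_mask(positions: pd.Series, group: str) -> pd.Series:
    lo, hi = (int(p) for p in group.split("-"))
    return positions.between(lo, hi)


def grouped_correlations(
    table: pd.DataFrame,
    value_column: str = "sirmsd_A",
    response_column: str = "soa_pct",
    combinations: Optional[Iterable[str]] = None,
    groups: Iterable[str] = ("2-8", "2-5", "6-8"),
) -> pd.DataFrame:
    """One correlation report per (window combination, grouping).

    ``table`` is tidy with columns ``position``, ``combination``,
    ``value_column`` and ``response_column`` (one point per modification ×
    position, matching a dot on a correlation panel).  ``groups`` may
    contain ``"per-position"`` which expands to every position present.
    Groups with fewer than 3 points yield a sentinel row
    (``defined=False``), never silence.
    """
    required = {"position", "combination", value_column, response_column}
    missing = required - set(table.columns)
    if missing:
        raise SirmsdError(f"table missing columns {sorted(missing)}")
    if combinations is None:
        combinations = sorted(table["combination"].unique())

    expanded: list[str] = []
    for g in groups:
        if g == "per-position":
            expanded.extend(f"{p}-{p}" for p in sorted(table["position"].unique()))
        else:
            expanded.append(g)

    rows = []
    for combo in combinations:
        sub = table[table["combination"] == combo]
        for group in expanded:
            pts = sub[_group_mask(sub["position"], group)]
            n = len(pts)
            if n < 3:
                rep = CorrelationReport.undefined(n)
            else:
                rep = pearson(pts[value_column], pts[response_column])
            rows.append({
                "combination": combo, "group": group, "n": rep.n,
                "r": rep.r, "p": rep.p,
                "ci_low": rep.ci95[0], "ci_high": rep.ci95[1],
                "defined": rep.defined,
            })
    return pd.DataFrame(rows, columns=["combination", "group", "n", "r", "p",
                                       "ci_low", "ci_high", "defined"])


# ---------------------------------------------------------------------------
# Thin from-definition auxiliaries
# ---------------------------------------------------------------------------

def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t test (unequal variances); returns (t, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df=df))
    return float(t), p


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from sums of squares; returns (F, p)."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise SirmsdError("need at least two groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = sum(g.size for g in arrays) - len(arrays)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p
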