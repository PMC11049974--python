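"""Metabolic control analysis: the flux control coefficient of DXS.

The flux control coefficient (FCC) of an enzyme is the fractional change in
pathway flux per fractional change in that enzyme's activity,

    C^J_v = (dJ/J) / (dv/v) = d log J / d log v,

estimated here as the ordinary-least-squares slope of log flux on log DXS
activity over samples that span a range of activities (empty-vector controls
pooled with RNAi-silenced and overexpressing lines), computed separately for
each light x temperature condition.  In a linear pathway the FCC lies in
[0, 1]: 0 means the enzyme exerts no control, 1 a directly proportional
relationship.  A two-sided t-based 95% confidence interval flags estimates
statistically indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FCCEstimate", "fcc_regression", "pointwise_fcc", "fcc_table"]

GENOTYPES = ("EV", "RNAi", "OE")


@dataclass(frozen=True)
class FCCEstimate:
    """Log-log regression estimate of the flux control coefficient."""

    fcc: float
    se: float
    ci95: tuple[float, float]
    n: int
    r2: float
    condition: str = ""
    zero_flag: bool = False  # True when the 95% CI covers 0


def _ols_loglog(J: np.ndarray, v: np.ndarray, condition: str) -> FCCEstimate:
    x = np.log(v)
    y = np.log(J)
    n = x.size
    res = stats.linregress(x, y)
    slope = float(res.slope)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    if n > 2 and se > 0:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        ci = (slope, slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return FCCEstimate(
        fcc=slope,
        se=se,
        ci95=(float(ci[0]), float(ci[1])),
        n=int(n),
        r2=r2,
        condition=condition,
        zero_flag=bool(ci[0] <= 0.0 <= ci[1]),
    )


def fcc_regression(
    records: pd.DataFrame, group_by_condition: bool = True
) -> list[FCCEstimate]:
    """FCC per condition group from a table with columns ``J``, ``v`` and
    (when grouping) ``condition``.

    Records with non-positive flux or activity cannot be log-transformed and
    are excluded; a group left with fewer than 3 records yields no estimate.
    """
    required = {"J", "v"} | ({"condition"} if group_by_condition else set())
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")

    usable = records[(records["J"] > 0) & (records["v"] > 0)]
    n_dropped = len(records) - len(usable)
    if n_dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d record(s) with non-positive J or v excluded from FCC regression",
            n_dropped,
        )

    groups = (
        usable.groupby("condition", sort=True)
        if group_by_condition
        else [("all", usable)]
    )
    estimates = []
    for cond, grp in groups:
        if len(grp) < 3:
            continue
        estimates.append(
            _ols_loglog(grp["J"].to_numpy(float), grp["v"].to_numpy(float), str(cond))
        )
    return estimates


def pointwise_fcc(dJ: float, J: float, dv: float, v: float) -> float:
    """Two-point FCC (dJ/J)/(dv/v); the finite-difference form of the slope."""
    if J == 0 or v == 0:
        raise ValueError("J and v must be nonzero")
    if dv == 0:
        raise ValueError("dv = 0: pointwise FCC undefined")
    return (dJ / J) / (dv / v)


def fcc_table(estimates: list[FCCEstimate]) -> pd.DataFrame:
    """Tidy output table ``condition,fcc,se,ci_low,ci_high,n,r2,zero_flag``."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition,
                "fcc": e.fcc,
                "se": e.se,
                "ci_low": e.ci95[0],
                "ci_high": e.ci95[1],
                "n": e.n,
                "r2": e.r2,
                "zero_flag": int(e.zero_flag),
            }
            for e in estimates
        ]
    )
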