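"""LC-MS/MS pool quantification for DXP, MEcDP and IDP+DMADP.

Inputs begin at integrated isotopologue channel areas (0-5 13C atoms for
each of the three C5 metabolites).  The module provides external-standard
quantification, internal-standard (ISTD) matrix-effect correction from
paired spiked/unspiked runs, natural-13C-abundance deconvolution, the
atom-weighted label fraction, and the plastidial-pool estimate obtained by
referencing each metabolite's final labeling to that of IDP+DMADP (assumed
exclusively plastidial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

__all__ = [
    "N_CARBON",
    "NATURAL_13C",
    "StandardCurve",
    "IsotopologueMeasurement",
    "PoolEstimate",
    "quantify_standard_curve",
    "istd_matrix_factor",
    "natural_abundance_matrix",
    "natural_abundance_convolve",
    "natural_abundance_correct",
    "metabolite_label_fraction",
    "plastidial_pool",
    "read_measurements",
    "read_standard_curves",
]

N_CARBON = 5
NATURAL_13C = 0.011
METABOLITES = ("DXP", "MEcDP", "IDP+DMADP")
#: channels dominated by biological label, used to scale the endogenous
#: contribution when isolating the ISTD signal
HEAVY_CHANNELS = (3, 4, 5)


@dataclass(frozen=True)
class StandardCurve:
    """Ordinary linear calibration ``intensity = slope * amount + intercept``.

    Built from >= 2 (amount, intensity) pairs with strictly increasing
    amounts; used both for inverse prediction of amounts and for the
    expected intensity of a known spike.
    """

    slope: float
    intercept: float

    @classmethod
    def fit(cls, points: list[tuple[float, float]]) -> "StandardCurve":
        if len(points) < 2:
            raise ValueError("standard curve needs at least 2 points")
        amounts = np.array([p[0] for p in points], dtype=float)
        intensities = np.array([p[1] for p in points], dtype=float)
        if np.any(np.diff(amounts) <= 0):
            raise ValueError("standard-curve amounts must be strictly increasing")
        slope, intercept = np.polyfit(amounts, intensities, 1)
        if slope <= 0:
            raise ValueError("non-increasing (singular) standard curve rejected")
        return cls(slope=float(slope), intercept=float(intercept))

    def invert(self, response: float) -> float:
        """Amount predicted for an intensity; negative predictions clamp to 0."""
        amount = (response - self.intercept) / self.slope
        if amount < 0:
            # tolerate pure rounding noise silently
            if amount < -1e-9 * (1.0 + abs(self.intercept / self.slope)):
                warnings.warn("negative inverse prediction clamped to 0", stacklevel=2)
            return 0.0
        return amount

    def expected(self, amount: float) -> float:
        return self.slope * amount + self.intercept


@dataclass(frozen=True)
class IsotopologueMeasurement:
    """Integrated channel areas for one metabolite in one LC-MS/MS run."""

    metabolite: str
    areas: np.ndarray
    with_istd: bool = False
    istd_amount: float = 0.0  # pmol, when spiked

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.shape != (N_CARBON + 1,):
            raise ValueError(f"expected {N_CARBON + 1} channel areas")
        if np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError("channel areas must be finite and >= 0")
        if self.metabolite not in METABOLITES:
            raise ValueError(f"unknown metabolite {self.metabolite!r}")
        if self.with_istd and self.istd_amount <= 0:
            raise ValueError("spiked run requires istd_amount > 0")
        object.__setattr__(self, "areas", areas)


@dataclass(frozen=True)
class PoolEstimate:
    """Total and plastidial pool (pmol mg^-1 DW) with the final label fraction."""

    metabolite: str
    total_pool: float
    plastidial_pool: float
    final_label: float


def quantify_standard_curve(response: float, curve: list[tuple[float, float]] | StandardCurve) -> float:
    """Inverse-predict an amount (pmol) from an intensity via a linear curve."""
    sc = curve if isinstance(curve, StandardCurve) else StandardCurve.fit(curve)
    return sc.invert(response)


def istd_matrix_factor(
    spiked: IsotopologueMeasurement,
    unspiked: IsotopologueMeasurement,
    curve: StandardCurve,
) -> float:
    """Recovery/matrix factor from a paired spiked + unspiked analysis.

    The unlabeled ISTD adds signal only on the 13C0 channel; the endogenous
    contribution to that channel is scaled out using the heavy channels
    (3, 4, 5 13C atoms), which in a post-labeling extract carry only
    biological material:

        s      = mean over heavy channels of spiked/unspiked signal
        spike  = spiked[0] - s * unspiked[0]
        factor = spike / expected intensity of istd_amount from the curve

    A factor of 1 means no matrix suppression; a corrected pool is the raw
    pool divided by the factor.  If every heavy channel is empty in the
    unspiked run, the factor falls back to the plain channel-0 difference
    (flagged lower-confidence via a warning).
    """
    if spiked.metabolite != unspiked.metabolite:
        raise ValueError("paired runs must measure the same metabolite")
    if not spiked.with_istd or unspiked.with_istd:
        raise ValueError("expected one spiked and one unspiked run")

    heavy_sp = spiked.areas[list(HEAVY_CHANNELS)]
    heavy_un = unspiked.areas[list(HEAVY_CHANNELS)]
    usable = heavy_un > 0
    if np.any(usable):
        s = float(np.mean(heavy_sp[usable] / heavy_un[usable]))
        spike_signal = spiked.areas[0] - s * unspiked.areas[0]
    else:
        warnings.warn(
            "no endogenous heavy-channel signal; ISTD factor from channel-0 "
            "difference alone (lower confidence)",
            stacklevel=2,
        )
        spike_signal = spiked.areas[0] - unspiked.areas[0]

    expected = curve.expected(spiked.istd_amount) - curve.intercept
    if expected <= 0:
        raise ValueError("standard curve predicts no signal for the spike amount")
    factor = spike_signal / expected
    if factor <= 0:
        raise ValueError("non-positive recovery factor: spike signal not detected")
    return float(factor)


def natural_abundance_matrix(p13: float = NATURAL_13C, n_carbons: int = N_CARBON) -> np.ndarray:
    """Binomial convolution matrix M with M[i, j] = P(observe i 13C | j labeled).

    Each of the ``n - j`` biologically unlabeled carbons is independently 13C
    with probability ``p13``; labeled carbons stay 13C.
    """
    if not 0 <= p13 < 0.5:
        raise ValueError("natural 13C abundance must be in [0, 0.5)")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        M[j + k, j] = comb(n - j, k) * p13**k * (1 - p13) ** (n - j - k)
    return M


def natural_abundance_convolve(x, p13: float = NATURAL_13C) -> np.ndarray:
    """Forward model: apply natural 13C abundance to a channel distribution."""
    x = np.asarray(x, dtype=float)
    return natural_abundance_matrix(p13, x.size - 1) @ x


def natural_abundance_correct(areas, p13: float = NATURAL_13C) -> np.ndarray:
    """Deconvolve natural 13C abundance from observed channel areas.

    Solves M x = areas for the binomial convolution matrix, clamps negative
    components at zero and renormalizes to the observed total signal.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("channel areas must be >= 0")
    total = areas.sum()
    if total == 0:
        return areas.copy()
    M = natural_abundance_matrix(p13, areas.size - 1)
    x = np.linalg.solve(M, areas)
    x = np.clip(x, 0.0, None)
    s = x.sum()
    return x * (total / s) if s > 0 else x


def metabolite_label_fraction(areas) -> float:
    """Atom-weighted 13C fraction of a corrected 6-channel distribution.

    Same contract as the isoprene labeling formula: sum_i i*S_i / (n * sum S_i).
    All-zero input is undefined and returns NaN.
    """
    s = np.asarray(areas, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative channel area")
    total = s.sum()
    if total == 0:
        return float("nan")
    weights = np.arange(s.size, dtype=float)
    return float((s * weights).sum() / ((s.size - 1) * total))


def plastidial_pool(total: float, final_label_met: float, final_label_ref: float) -> float:
    """Plastidial share of a total pool from final label fractions.

    Only plastidial DXP/MEcDP become labeled on the experiment's time scale,
    so plastidial = total * (final label of the metabolite / final label of
    IDP+DMADP), capped at the total.  The reference labeling must be > 0.
    """
    if total < 0:
        raise ValueError("total pool must be >= 0")
    if not final_label_ref > 0:
        raise ValueError("reference (IDP+DMADP) label fraction must be > 0")
    if final_label_met < 0:
        raise ValueError("label fraction must be >= 0")
    est = total * final_label_met / final_label_ref
    if est <= total * (1.0 + 1e-12):
        return float(min(est, total))
    if est > total:
        warnings.warn(
            "metabolite label exceeds IDP+DMADP reference; plastidial pool capped at total",
            stacklevel=2,
        )
        return float(total)
    return float(est)


# ---------------------------------------------------------------------------
# I/O

MEASUREMENT_COLUMNS = [
    "sample_id", "metabolite", "with_istd", "istd_pmol",
    "a0", "a1", "a2", "a3", "a4", "a5",
]


def read_measurements(path_or_buffer) -> pd.DataFrame:
    """Read the measurement CSV (``sample_id,metabolite,with_istd,istd_pmol,a0..a5``)."""
    df = pd.read_csv(path_or_buffer)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df


def read_standard_curves(path_or_buffer) -> dict[str, StandardCurve]:
    """Read ``metabolite,amount_pmol,intensity`` CSV into fitted curves."""
    df = pd.read_csv(path_or_buffer)
    missing = {"metabolite", "amount_pmol", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"standard-curve CSV missing columns: {sorted(missing)}")
    curves = {}
    for met, grp in df.groupby("metabolite"):
        grp = grp.sort_values("amount_pmol")
        curves[str(met)] = StandardCurve.fit(
            list(zip(grp["amount_pmol"], grp["intensity"]))
        )
    return curves
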