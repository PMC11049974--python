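"""PTR-MS signal processing for isoprene isotopologues.

Proton transfer reaction mass spectrometry reports counts per second (cps)
at the protonated isoprene masses m/z 69-74, which carry 0-5 13C atoms.
Raw counts are normalized (ncps) to the hydronium primary-ion signal
(m/z 21, with the water dimer m/z 37 and trimer m/z 55) and to drift-tube
pressure, background from an empty cuvette is subtracted, and the
atom-weighted fractional labeling

    f = sum_i i * S_i / (5 * sum_i S_i)

is computed from the six isotopologue intensities S_0..S_5.  Steady-state
ncps, a calibration factor and the leaf area give the emission rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flux_model import LabelCurve

__all__ = [
    "PtrmsConfig",
    "EmissionResult",
    "ISOTOPOLOGUE_CHANNELS",
    "PRIMARY_CHANNELS",
    "normalize_cps",
    "subtract_background",
    "emission_rate",
    "fractional_labeling",
    "correct_natural_isoprene",
    "process_run",
    "read_ptrms_run",
    "write_label_curve",
]

ISOTOPOLOGUE_CHANNELS = ["mz69", "mz70", "mz71", "mz72", "mz73", "mz74"]
PRIMARY_CHANNELS = ["mz21", "mz37", "mz55"]
N_CARBON = 5

#: fraction of carbon that is 13C in normal air / unlabeled biomass
NATURAL_13C = 0.011


@dataclass(frozen=True)
class PtrmsConfig:
    """Normalization constants for a PTR-MS run.

    ``w37``/``w55`` weight the hydronium dimer and trimer in the primary-ion
    sum; ``p_ref`` is the reference drift pressure in mbar (instrument drift
    tubes run near 2.2 mbar).  ``correct_natural`` toggles subtraction of the
    natural-abundance 13C1 contribution (5 x 1.1% of the m/z 69 signal) from
    m/z 70 before labeling computation.
    """

    w37: float = 1.0
    w55: float = 1.0
    p_ref: float = 2.2
    correct_natural: bool = True


@dataclass(frozen=True)
class EmissionResult:
    """Leaf-area-normalized isoprene emission, nmol m^-2 s^-1."""

    emission: float
    leaf_area: float
    background: float = 0.0


def _check_frame(df: pd.DataFrame, channels: list[str]) -> None:
    missing = set(channels) - set(df.columns)
    if missing:
        raise ValueError(f"PTR-MS table missing channels: {sorted(missing)}")


def normalize_cps(scan: pd.DataFrame, config: PtrmsConfig = PtrmsConfig()) -> pd.DataFrame:
    """Normalize isotopologue cps to the primary-ion sum and drift pressure.

    ncps = cps / (cps21 + w37*cps37 + w55*cps55) * (p_ref / p_drift)

    The result is invariant to a common multiplicative gain on all channels.
    Rows with a non-positive primary-ion sum or pressure are rejected.
    """
    _check_frame(scan, ISOTOPOLOGUE_CHANNELS + PRIMARY_CHANNELS + ["p_drift_mbar"])
    primary = (
        scan["mz21"].to_numpy(float)
        + config.w37 * scan["mz37"].to_numpy(float)
        + config.w55 * scan["mz55"].to_numpy(float)
    )
    pressure = scan["p_drift_mbar"].to_numpy(float)
    if np.any(primary <= 0):
        raise ValueError("non-positive primary-ion sum: scan rejected")
    if np.any(pressure <= 0):
        raise ValueError("non-positive drift pressure: scan rejected")

    out = pd.DataFrame(index=scan.index)
    if "time_min" in scan.columns:
        out["time_min"] = scan["time_min"]
    scale = (config.p_ref / pressure) / primary
    for ch in ISOTOPOLOGUE_CHANNELS:
        out[ch] = scan[ch].to_numpy(float) * scale
    return out


def subtract_background(series: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-channel mean empty-cuvette ncps; clamp at zero.

    ``background`` is a same-schema ncps table (any number of rows; its
    channel means are used) and must not be longer than the measurement.
    """
    _check_frame(series, ISOTOPOLOGUE_CHANNELS)
    _check_frame(background, ISOTOPOLOGUE_CHANNELS)
    if len(background) > len(series):
        raise ValueError("background series longer than measurement")
    out = series.copy()
    for ch in ISOTOPOLOGUE_CHANNELS:
        out[ch] = np.clip(
            series[ch].to_numpy(float) - float(background[ch].mean()), 0.0, None
        )
    return out


def emission_rate(mean_ncps: float, cal_factor: float | None, leaf_area: float) -> EmissionResult:
    """Isoprene emission from steady-state ncps.

    ``cal_factor`` converts ncps to nmol s^-1 and must be supplied from an
    instrument calibration; ``leaf_area`` is in m^2.
    """
    if cal_factor is None or cal_factor <= 0:
        raise ValueError("a positive ncps->nmol/s calibration factor is required")
    if leaf_area <= 0:
        raise ValueError("leaf area must be > 0")
    if mean_ncps < 0:
        mean_ncps = 0.0
    return EmissionResult(emission=mean_ncps * cal_factor / leaf_area, leaf_area=leaf_area)


def fractional_labeling(iso_signals) -> float:
    """Atom-weighted 13C fraction from six isotopologue intensities.

    f = sum_i i*S_i / (5 * sum_i S_i) for channels carrying 0..5 13C atoms.
    An all-zero vector is undefined and returns NaN (flagged missing).
    """
    s = np.asarray(iso_signals, dtype=float)
    if s.shape[-1] != N_CARBON + 1:
        raise ValueError(f"expected {N_CARBON + 1} isotopologue channels")
    if np.any(s < 0):
        raise ValueError("negative isotopologue intensity")
    total = s.sum(axis=-1)
    weights = np.arange(N_CARBON + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (s * weights).sum(axis=-1) / (N_CARBON * total)
    return np.where(total > 0, f, np.nan) if f.ndim else (float(f) if total > 0 else float("nan"))


def correct_natural_isoprene(frame: pd.DataFrame, p13: float = NATURAL_13C) -> pd.DataFrame:
    """Remove the natural-abundance 13C1 contribution from m/z 70.

    Unlabeled isoprene carries ~5*p13 of its signal at m/z 70 purely from
    natural 13C; that share of the m/z 69 channel is subtracted from m/z 70
    (clamped at zero) so the labeling computation sees biological label only.
    """
    out = frame.copy()
    out["mz70"] = np.clip(
        frame["mz70"].to_numpy(float) - N_CARBON * p13 * frame["mz69"].to_numpy(float),
        0.0,
        None,
    )
    return out


def process_run(
    run: pd.DataFrame,
    background: pd.DataFrame | None = None,
    config: PtrmsConfig = PtrmsConfig(),
) -> LabelCurve:
    """Full per-run chain: normalize, background-subtract, correct m/z 70,
    compute f(t).  Rows where all channels are zero are dropped."""
    ncps = normalize_cps(run, config)
    if background is not None:
        bg_ncps = normalize_cps(background, config)
        ncps = subtract_background(ncps, bg_ncps)
    if config.correct_natural:
        ncps = correct_natural_isoprene(ncps)
    sig = ncps[ISOTOPOLOGUE_CHANNELS].to_numpy(float)
    f = np.array([fractional_labeling(row) for row in sig])
    keep = np.isfinite(f)
    times = ncps["time_min"].to_numpy(float)[keep]
    return LabelCurve(times=times, f=np.clip(f[keep], 0.0, 1.0))


# ---------------------------------------------------------------------------
# I/O

RUN_COLUMNS = ["time_min", *ISOTOPOLOGUE_CHANNELS, *PRIMARY_CHANNELS, "p_drift_mbar"]


def read_ptrms_run(path_or_buffer) -> pd.DataFrame:
    """Read a PTR-MS run CSV (``time_min,mz69..mz74,mz21,mz37,mz55,p_drift_mbar``)."""
    df = pd.read_csv(path_or_buffer)
    _check_frame(df, RUN_COLUMNS)
    return df


def write_label_curve(curve: LabelCurve, path) -> None:
    """Write a ``time_min\\tf_label`` TSV consumed by the flux fit."""
    pd.DataFrame({"time_min": curve.times, "f_label": curve.f}).to_csv(
        path, sep="\t", index=False
    )
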