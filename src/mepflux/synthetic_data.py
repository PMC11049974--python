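"""Synthetic study generator for the whole labeling pipeline.

Emulates the full experimental design — three poplar genotypes (empty-vector
control ``EV``, RNAi-silenced ``RNAi`` at ~45% of control DXS activity,
overexpressor ``OE`` at ~125%) crossed with four environments (1000/250 PPFD
x 30/21 degC) — and produces every raw table the analysis stages consume:
PTR-MS isotopologue time courses, paired spiked/unspiked LC-MS/MS pool
measurements with standard curves, DXS activity values, plus a truth table
for recovery testing that the analysis stages never read.

Reference values (per-cell replicate counts, plateau labeling, the three
pool sizes and the pathway flux) are the printed study means, held in
``REFERENCE_STUDY``.  Two anchoring modes are supported:

``anchor="table"``
    every genotype x condition cell draws around its own reference row —
    used to check that the estimation chain reproduces known fluxes;
``anchor="control-law"``
    transgenic fluxes are derived from the EV baseline through an enzyme
    control law ``J = J_EV * (v / v_EV)^fcc_true``, so a known flux control
    coefficient can be planted and recovered.

All randomness flows from a single ``numpy.random.default_rng`` seed;
identical seeds give identical tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ptrms
from .flux_model import PoolSizes, label_fraction
from .pools import natural_abundance_convolve

__all__ = [
    "REFERENCE_STUDY",
    "CONDITIONS",
    "ACTIVITY_MULTIPLIERS",
    "BASELINE_ACTIVITY",
    "StudyDesign",
    "NoiseConfig",
    "StudyData",
    "generate_study",
    "generate_label_run",
    "condition_key",
]

# ---------------------------------------------------------------------------
# Reference study conditions

#: (PPFD umol m-2 s-1, leaf temperature degC)
CONDITIONS: tuple[tuple[int, int], ...] = ((1000, 30), (250, 30), (1000, 21), (250, 21))

#: genotype DXS-activity multipliers relative to the empty-vector control
ACTIVITY_MULTIPLIERS: dict[str, float] = {"EV": 1.00, "RNAi": 0.45, "OE": 1.25}

#: arbitrary activity scale for the EV control (the FCC is scale-invariant)
BASELINE_ACTIVITY = 100.0

_REFERENCE_ROWS = """\
genotype,ppfd,temp_c,n,m,se_m,A,se_A,B,se_B,C,se_C,J,se_J
EV,1000,30,10,0.912,0.007,41.65,2.22,85.59,14.43,38.09,4.01,28.65,2.95
RNAi,1000,30,14,0.912,0.005,46.01,3.86,124.9,12.14,47.74,4.67,38.94,2.62
OE,1000,30,18,0.902,0.006,58.61,3.21,139.4,15.89,41.20,4.76,38.52,2.56
EV,250,30,10,0.823,0.036,28.53,1.49,54.98,4.06,18.47,3.23,15.66,1.42
RNAi,250,30,15,0.870,0.008,25.61,1.29,46.99,2.66,22.03,1.68,16.49,0.96
OE,250,30,20,0.865,0.018,35.97,2.55,65.43,5.23,19.41,2.44,19.69,1.24
EV,1000,21,9,0.932,0.008,27.18,1.45,48.57,6.53,13.64,0.78,9.79,0.87
RNAi,1000,21,13,0.929,0.009,28.64,1.96,48.19,3.39,19.44,1.35,12.15,0.55
OE,1000,21,16,0.943,0.005,33.51,1.93,53.36,3.79,16.90,1.14,13.50,0.93
EV,250,21,8,0.946,0.009,21.99,1.29,35.74,4.54,13.31,1.89,7.43,0.65
RNAi,250,21,10,0.940,0.005,22.29,1.70,36.92,3.85,19.57,2.04,7.91,0.73
OE,250,21,19,0.957,0.006,24.59,0.97,43.21,3.37,13.18,1.32,9.55,0.64
"""

#: per-cell reference means: plateau m, plastidial pools A (DXP), B (MEcDP),
#: C (IDP+DMADP) in pmol mg-1 DW, flux J in pmol min-1 mg-1 DW, with SEs
REFERENCE_STUDY: pd.DataFrame = pd.read_csv(io.StringIO(_REFERENCE_ROWS))

#: plastidial share of the total pool assumed for the two upstream
#: metabolites (IDP+DMADP is taken as exclusively plastidial)
PLASTIDIAL_FRACTIONS: dict[str, float] = {"DXP": 0.75, "MEcDP": 0.85, "IDP+DMADP": 1.0}

#: mg dry weight extracted per LC-MS sample
EXTRACT_DW_MG = 5.0

#: external-standard response, intensity per pmol (through the origin)
CURVE_SLOPES: dict[str, float] = {"DXP": 120.0, "MEcDP": 95.0, "IDP+DMADP": 150.0}

#: unlabeled internal-standard spike, pmol, roughly matching extract content
ISTD_AMOUNTS: dict[str, float] = {"DXP": 200.0, "MEcDP": 400.0, "IDP+DMADP": 150.0}


def condition_key(ppfd: int, temp_c: int) -> str:
    return f"{ppfd}PPFD-{temp_c}C"


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class StudyDesign:
    """Genotype x condition layout and replicate counts.

    ``n_per_cell`` may be an int (same count everywhere), a mapping from
    (genotype, ppfd, temp_c) to a count, or None for the reference study's
    per-cell replicate numbers (8-20).
    """

    genotypes: dict[str, float] = field(
        default_factory=lambda: dict(ACTIVITY_MULTIPLIERS)
    )
    conditions: tuple[tuple[int, int], ...] = CONDITIONS
    n_per_cell: int | dict | None = None
    seed: int = 0

    def replicates(self, genotype: str, ppfd: int, temp_c: int) -> int:
        if isinstance(self.n_per_cell, int):
            n = self.n_per_cell
        elif isinstance(self.n_per_cell, dict):
            n = self.n_per_cell[(genotype, ppfd, temp_c)]
        else:
            ref = REFERENCE_STUDY
            row = ref[
                (ref.genotype == genotype) & (ref.ppfd == ppfd) & (ref.temp_c == temp_c)
            ]
            if row.empty:
                raise KeyError(f"no reference replicate count for {genotype}/{ppfd}/{temp_c}")
            n = int(row["n"].iloc[0])
        if n < 1:
            raise ValueError("n_per_cell must be >= 1")
        return n


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-model settings.

    Biological spread is multiplicative lognormal (``sd_*`` are the log-scale
    standard deviations); instrument noise is additive Gaussian on each
    channel with sd = ``channel_sd_frac`` x the run's maximum channel signal.
    ``natural_abundance`` applies the deterministic natural-13C convolution
    to generated channel distributions; ``istd_factor`` is the planted
    matrix-suppression/recovery factor on LC-MS runs; ``bg_frac`` the
    empty-cuvette background as a fraction of the isoprene signal.
    """

    sd_v: float = 0.15
    sd_J: float = 0.10
    sd_pool: float = 0.15
    sd_m: float = 0.02
    channel_sd_frac: float = 0.01
    natural_abundance: bool = True
    istd_factor: float = 0.85
    bg_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("sd_v", "sd_J", "sd_pool", "sd_m", "channel_sd_frac", "bg_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise sd {name} must be >= 0")
        if self.istd_factor <= 0:
            raise ValueError("istd_factor must be > 0")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        """Idealized instrument: no spread, no background, no isotope
        interference, full recovery."""
        return cls(
            sd_v=0.0, sd_J=0.0, sd_pool=0.0, sd_m=0.0,
            channel_sd_frac=0.0, natural_abundance=False,
            istd_factor=1.0, bg_frac=0.0,
        )


@dataclass
class StudyData:
    """Bundle of generated raw tables plus the hidden truth."""

    runs: dict[str, pd.DataFrame]            # sample_id -> PTR-MS run table
    background: pd.DataFrame                 # empty-cuvette PTR-MS table
    pool_measurements: pd.DataFrame          # LC-MS measurement CSV schema
    standard_curves: pd.DataFrame            # metabolite,amount_pmol,intensity
    activities: pd.DataFrame                 # sample_id,genotype,ppfd,temp_c,activity
    truth: pd.DataFrame                      # TruthRecord table (never analyzed)

    def to_dir(self, outdir) -> None:
        """Write every table under ``outdir`` (runs/<sample>.csv etc.)."""
        out = Path(outdir)
        (out / "runs").mkdir(parents=True, exist_ok=True)
        for sid, run in self.runs.items():
            run.to_csv(out / "runs" / f"{sid}.csv", index=False)
        self.background.to_csv(out / "background.csv", index=False)
        self.pool_measurements.to_csv(out / "pool_measurements.csv", index=False)
        self.standard_curves.to_csv(out / "standard_curves.csv", index=False)
        self.activities.to_csv(out / "activities.csv", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cascade state helpers (closed forms for the upstream pools)

def _upstream_labels(t: float, pools: PoolSizes, J: float, m: float) -> tuple[float, float, float]:
    """Fractional labeling of plastidial DXP, MEcDP and IDP+DMADP at time t."""
    A, B, C = pools.as_tuple()
    ea, eb = np.exp(-J * t / A), np.exp(-J * t / B)
    a = m * (1.0 - ea)
    b = m * (1.0 - A / (A - B) * ea - B / (B - A) * eb)
    c = float(label_fraction(t, pools, J, m))
    return float(np.clip(a, 0, m)), float(np.clip(b, 0, m)), c


def _binomial_split(f: np.ndarray, n: int = 5) -> np.ndarray:
    """Expected isotopologue fractions for per-carbon label probability f.

    Returns shape (len(f), n+1); rows sum to 1.
    """
    from scipy.special import comb

    f = np.asarray(f, dtype=float)[:, None]
    k = np.arange(n + 1)[None, :]
    return comb(n, k) * f**k * (1.0 - f) ** (n - k)


# ---------------------------------------------------------------------------
# Generators

#: PTR-MS instrument constants for generated runs
_PRIMARY_CPS = {"mz21": 1.2e6, "mz37": 2.0e5, "mz55": 3.0e4}
_ISOPRENE_CPS = 3000.0
_DRIFT_MBAR = 2.25
_DEFAULT_GRID = np.arange(0.0, 50.0 + 1e-9, 0.5)


def generate_label_run(
    pools: PoolSizes,
    J: float,
    m: float,
    grid: np.ndarray | None = None,
    noise: NoiseConfig = NoiseConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One PTR-MS run table for a leaf with the given cascade parameters.

    Channel signals are the total isoprene cps split by the expected
    binomial(5, f(t)) isotopologue fractions (optionally convolved with
    natural 13C abundance), plus background and additive channel noise.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    t = _DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    f = np.atleast_1d(label_fraction(t, pools, J, m))
    frac = _binomial_split(f)
    if noise.natural_abundance:
        frac = np.array([natural_abundance_convolve(row) for row in frac])
    signal = _ISOPRENE_CPS * frac
    signal += noise.bg_frac * _ISOPRENE_CPS / 6.0
    if noise.channel_sd_frac > 0:
        signal = signal + rng.normal(
            0.0, noise.channel_sd_frac * signal.max(), size=signal.shape
        )
        signal = np.clip(signal, 0.0, None)

    run = pd.DataFrame({"time_min": t})
    for i, ch in enumerate(ptrms.ISOTOPOLOGUE_CHANNELS):
        run[ch] = signal[:, i]
    for ch, cps in _PRIMARY_CPS.items():
        run[ch] = cps
    run["p_drift_mbar"] = _DRIFT_MBAR
    return run


def _background_table(grid: np.ndarray, noise: NoiseConfig) -> pd.DataFrame:
    bg = pd.DataFrame({"time_min": grid})
    for ch in ptrms.ISOTOPOLOGUE_CHANNELS:
        bg[ch] = noise.bg_frac * _ISOPRENE_CPS / 6.0
    for ch, cps in _PRIMARY_CPS.items():
        bg[ch] = cps
    bg["p_drift_mbar"] = _DRIFT_MBAR
    return bg


def _pool_measurement_rows(
    sample_id: str,
    metabolite: str,
    plastidial: float,
    label_plastidial: float,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Paired unspiked + ISTD-spiked LC-MS rows for one metabolite."""
    phi = PLASTIDIAL_FRACTIONS[metabolite]
    total_per_mg = plastidial / phi
    amount = total_per_mg * EXTRACT_DW_MG  # pmol in the extract
    slope = CURVE_SLOPES[metabolite]

    # endogenous channel distribution: labeled plastidial share + unlabeled rest
    labeled = _binomial_split(np.array([label_plastidial]))[0]
    dist = phi * labeled
    dist[0] += 1.0 - phi
    istd_dist = np.zeros(6)
    istd_dist[0] = 1.0
    if noise.natural_abundance:
        dist = natural_abundance_convolve(dist)
        istd_dist = natural_abundance_convolve(istd_dist)

    endogenous = slope * amount * dist
    spike = slope * ISTD_AMOUNTS[metabolite] * istd_dist
    unspiked = noise.istd_factor * endogenous
    spiked = noise.istd_factor * (endogenous + spike)

    def noisy(areas: np.ndarray) -> np.ndarray:
        if noise.channel_sd_frac > 0:
            areas = areas + rng.normal(0.0, noise.channel_sd_frac * areas.max(), 6)
        return np.clip(areas, 0.0, None)

    rows = []
    for with_istd, areas in ((False, noisy(unspiked)), (True, noisy(spiked))):
        rows.append(
            {
                "sample_id": sample_id,
                "metabolite": metabolite,
                "with_istd": int(with_istd),
                "istd_pmol": ISTD_AMOUNTS[metabolite] if with_istd else 0.0,
                **{f"a{i}": areas[i] for i in range(6)},
            }
        )
    return rows


def _standard_curve_table() -> pd.DataFrame:
    rows = []
    for met, slope in CURVE_SLOPES.items():
        for amount in (0.0, 50.0, 100.0, 200.0, 400.0, 800.0):
            rows.append(
                {"metabolite": met, "amount_pmol": amount, "intensity": slope * amount}
            )
    return pd.DataFrame(rows)


def generate_study(
    design: StudyDesign = StudyDesign(),
    fcc_true: float = 0.18,
    noise: NoiseConfig = NoiseConfig(),
    anchor: str = "control-law",
    grid: np.ndarray | None = None,
) -> StudyData:
    """Generate the complete raw-data bundle plus its truth table.

    ``fcc_true`` (in [0, 1]) is the planted flux control coefficient used in
    ``anchor="control-law"`` mode; it is ignored when ``anchor="table"``
    pins every genotype x condition cell to its reference row.
    """
    if not 0.0 <= fcc_true <= 1.0:
        raise ValueError("fcc_true must be in [0, 1]")
    if anchor not in ("control-law", "table"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    rng = np.random.default_rng(design.seed)
    t_grid = _DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    t_end = float(t_grid[-1])

    ref = REFERENCE_STUDY.set_index(["genotype", "ppfd", "temp_c"])
    runs: dict[str, pd.DataFrame] = {}
    pool_rows: list[dict] = []
    activity_rows: list[dict] = []
    truth_rows: list[dict] = []

    def lognormal(sd: float) -> float:
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    for ppfd, temp_c in design.conditions:
        ev = ref.loc[("EV", ppfd, temp_c)]
        for genotype, mult in design.genotypes.items():
            cell = ref.loc[(genotype, ppfd, temp_c)] if anchor == "table" else ev
            n = design.replicates(genotype, ppfd, temp_c)
            for rep in range(1, n + 1):
                sid = f"{genotype}_{ppfd}PPFD{temp_c}C_r{rep:02d}"
                true_v = BASELINE_ACTIVITY * mult * lognormal(noise.sd_v)
                if anchor == "table":
                    true_J = float(cell["J"]) * lognormal(noise.sd_J)
                else:
                    true_J = (
                        float(ev["J"])
                        * (true_v / BASELINE_ACTIVITY) ** fcc_true
                        * lognormal(noise.sd_J)
                    )
                pools_true = PoolSizes(
                    A=float(cell["A"]) * lognormal(noise.sd_pool),
                    B=float(cell["B"]) * lognormal(noise.sd_pool),
                    C=float(cell["C"]) * lognormal(noise.sd_pool),
                )
                m_true = min(float(cell["m"]) * lognormal(noise.sd_m), 1.0)

                runs[sid] = generate_label_run(
                    pools_true, true_J, m_true, t_grid, noise, rng
                )

                la, lb, lc = _upstream_labels(t_end, pools_true, true_J, m_true)
                for met, plast, lab in (
                    ("DXP", pools_true.A, la),
                    ("MEcDP", pools_true.B, lb),
                    ("IDP+DMADP", pools_true.C, lc),
                ):
                    pool_rows.extend(
                        _pool_measurement_rows(sid, met, plast, lab, noise, rng)
                    )

                activity_rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "ppfd": ppfd,
                        "temp_c": temp_c,
                        "activity": true_v,
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "ppfd": ppfd,
                        "temp_c": temp_c,
                        "true_v": true_v,
                        "true_J": true_J,
                        "true_A": pools_true.A,
                        "true_B": pools_true.B,
                        "true_C": pools_true.C,
                        "true_m": m_true,
                        "phi_DXP": PLASTIDIAL_FRACTIONS["DXP"],
                        "phi_MEcDP": PLASTIDIAL_FRACTIONS["MEcDP"],
                        "istd_factor": noise.istd_factor,
                    }
                )

    return StudyData(
        runs=runs,
        background=_background_table(t_grid, noise),
        pool_measurements=pd.DataFrame(pool_rows),
        standard_curves=_standard_curve_table(),
        activities=pd.DataFrame(activity_rows),
        truth=pd.DataFrame(truth_rows),
    )
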