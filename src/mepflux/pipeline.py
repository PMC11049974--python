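"""End-to-end orchestration: raw data -> label curves -> pools -> flux -> FCC.

The pipeline either generates a synthetic study or ingests files in the
documented CSV schemas, then runs the four analysis stages in order:

1. LC-MS pool quantification (ISTD matrix correction, natural-abundance
   deconvolution, plastidial-pool estimation via the IDP+DMADP label ratio);
2. PTR-MS processing of each labeling run into a fractional-labeling curve;
3. per-sample nonlinear fit of the three-pool model for flux J and plateau m,
   with that sample's plastidial pools fixed (or cell means, see
   ``pool_mode``);
4. per-condition log-log regression of flux on DXS activity for the flux
   control coefficient.

Every sample ends up either in the flux table or in the exclusion log with a
reason; outputs are deterministic given the seed and inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mca, pools, ptrms, synthetic_data
from .flux_model import FluxFit, PoolSizes, fit_flux
from .pools import (
    IsotopologueMeasurement,
    StandardCurve,
    istd_matrix_factor,
    metabolite_label_fraction,
    natural_abundance_correct,
    plastidial_pool,
)
from .synthetic_data import EXTRACT_DW_MG, NoiseConfig, StudyData, StudyDesign, condition_key

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_study_from_files"]

log = logging.getLogger("mepflux")

METABOLITES = ("DXP", "MEcDP", "IDP+DMADP")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "simulate"                 # "simulate" | "files"
    out_dir: str = "mepflux_out"
    seed: int = 0

    # simulate mode
    fcc_true: float = 0.18
    anchor: str = "control-law"            # "control-law" | "table"
    noise: str = "default"                 # "default" | "noiseless"
    n_per_cell: int | None = None          # None -> reference per-cell counts

    # files mode
    runs_dir: str | None = None
    background_csv: str | None = None
    pool_measurements_csv: str | None = None
    standard_curves_csv: str | None = None
    activities_csv: str | None = None

    # analysis knobs
    pool_mode: str = "per-sample"          # "per-sample" | "mean"
    correct_natural: bool | None = None    # None -> follow noise preset / True
    cal_factor: float | None = None        # ncps -> nmol s-1, optional
    leaf_area_m2: float = 0.0057
    dw_mg: float = EXTRACT_DW_MG
    write_raw: bool = False                # copy simulated raw tables to out_dir

    def noise_config(self) -> NoiseConfig:
        if self.noise == "noiseless":
            return NoiseConfig.noiseless()
        if self.noise == "default":
            return NoiseConfig()
        raise ValueError(f"unknown noise preset {self.noise!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Tidy result bundle; all tables are also written to the output directory."""

    sample_table: pd.DataFrame     # one row per fitted sample, joined metadata
    pool_table: pd.DataFrame       # per sample x metabolite pool estimates
    flux_table: pd.DataFrame       # per-sample FluxFit rows
    fcc_table: pd.DataFrame        # per-condition FCC estimates
    exclusions: pd.DataFrame       # sample_id,stage,reason
    config: RunConfig = field(repr=False, default=None)


def load_study_from_files(config: RunConfig) -> StudyData:
    """Assemble a StudyData bundle from user-supplied CSV files."""
    needed = {
        "runs_dir": config.runs_dir,
        "pool_measurements_csv": config.pool_measurements_csv,
        "standard_curves_csv": config.standard_curves_csv,
        "activities_csv": config.activities_csv,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError(f"files mode requires config entries: {missing}")
    runs = {}
    for path in sorted(Path(config.runs_dir).glob("*.csv")):
        runs[path.stem] = ptrms.read_ptrms_run(path)
    if not runs:
        raise ValueError(f"no run CSVs found in {config.runs_dir}")
    background = (
        ptrms.read_ptrms_run(config.background_csv)
        if config.background_csv
        else None
    )
    return StudyData(
        runs=runs,
        background=background if background is not None else pd.DataFrame(),
        pool_measurements=pools.read_measurements(config.pool_measurements_csv),
        standard_curves=pd.read_csv(config.standard_curves_csv),
        activities=pd.read_csv(config.activities_csv),
        truth=pd.DataFrame(),
    )


def _estimate_pools(
    measurements: pd.DataFrame,
    curves: dict[str, StandardCurve],
    correct_natural: bool,
    dw_mg: float,
    exclusions: list[dict],
) -> pd.DataFrame:
    """Stage 1: per sample x metabolite totals, labels, plastidial pools."""
    rows = []
    for sid, sample_grp in measurements.groupby("sample_id", sort=True):
        per_met: dict[str, dict] = {}
        for met, grp in sample_grp.groupby("metabolite"):
            try:
                unspiked_rows = grp[grp.with_istd == 0]
                spiked_rows = grp[grp.with_istd == 1]
                if unspiked_rows.empty:
                    raise ValueError("no unspiked run")
                areas_cols = [f"a{i}" for i in range(6)]
                unspiked = IsotopologueMeasurement(
                    metabolite=met,
                    areas=unspiked_rows.iloc[0][areas_cols].to_numpy(float),
                )
                curve = curves[met]
                if not spiked_rows.empty:
                    spiked = IsotopologueMeasurement(
                        metabolite=met,
                        areas=spiked_rows.iloc[0][areas_cols].to_numpy(float),
                        with_istd=True,
                        istd_amount=float(spiked_rows.iloc[0]["istd_pmol"]),
                    )
                    factor = istd_matrix_factor(spiked, unspiked, curve)
                else:
                    factor = 1.0
                raw_amount = curve.invert(float(unspiked.areas.sum()))
                total = raw_amount / factor / dw_mg  # pmol mg-1 DW
                areas = unspiked.areas
                if correct_natural:
                    areas = natural_abundance_correct(areas)
                label = metabolite_label_fraction(areas)
                per_met[met] = {"total": total, "label": label}
            except Exception as exc:
                exclusions.append({"sample_id": sid, "stage": "pools", "reason": f"{met}: {exc}"})
        if set(per_met) != set(METABOLITES):
            continue
        ref_label = per_met["IDP+DMADP"]["label"]
        for met in METABOLITES:
            total = per_met[met]["total"]
            label = per_met[met]["label"]
            try:
                plast = total if met == "IDP+DMADP" else plastidial_pool(total, label, ref_label)
            except ValueError as exc:
                exclusions.append({"sample_id": sid, "stage": "pools", "reason": str(exc)})
                plast = np.nan
            rows.append(
                {
                    "sample_id": sid,
                    "metabolite": met,
                    "total_pool": total,
                    "plastidial_pool": plast,
                    "final_label": label,
                }
            )
    return pd.DataFrame(rows)


def _sample_pools(
    pool_table: pd.DataFrame,
    activities: pd.DataFrame,
    pool_mode: str,
) -> dict[str, PoolSizes]:
    """Per-sample fixed pool sizes for the flux fit (A=DXP, B=MEcDP, C=IDP+DMADP)."""
    wide = pool_table.pivot(index="sample_id", columns="metabolite", values="plastidial_pool")
    if pool_mode == "mean":
        meta = activities.set_index("sample_id")[["genotype", "ppfd", "temp_c"]]
        wide = wide.join(meta, how="left")
        means = wide.groupby(["genotype", "ppfd", "temp_c"]).transform("mean")
        wide[list(METABOLITES)] = means[list(METABOLITES)]
    elif pool_mode != "per-sample":
        raise ValueError(f"unknown pool_mode {pool_mode!r}")
    out = {}
    for sid, row in wide.iterrows():
        try:
            out[sid] = PoolSizes(
                A=float(row["DXP"]), B=float(row["MEcDP"]), C=float(row["IDP+DMADP"])
            )
        except (ValueError, KeyError):
            continue
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the result tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    exclusions: list[dict] = []
    try:
        # --- acquire data -------------------------------------------------
        noise = config.noise_config()
        if config.mode == "simulate":
            design = StudyDesign(seed=config.seed, n_per_cell=config.n_per_cell)
            study = synthetic_data.generate_study(
                design, fcc_true=config.fcc_true, noise=noise, anchor=config.anchor
            )
            if config.write_raw:
                study.to_dir(out / "raw")
            correct_natural = (
                noise.natural_abundance
                if config.correct_natural is None
                else config.correct_natural
            )
        elif config.mode == "files":
            study = load_study_from_files(config)
            correct_natural = True if config.correct_natural is None else config.correct_natural
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        log.info("loaded %d labeling runs", len(study.runs))

        # --- stage 1: pools ----------------------------------------------
        curves = {
            str(met): StandardCurve.fit(
                list(zip(grp.sort_values("amount_pmol")["amount_pmol"], grp.sort_values("amount_pmol")["intensity"]))
            )
            for met, grp in study.standard_curves.groupby("metabolite")
        }
        pool_table = _estimate_pools(
            study.pool_measurements, curves, correct_natural, config.dw_mg, exclusions
        )
        sample_pools = _sample_pools(pool_table, study.activities, config.pool_mode)

        # --- stages 2+3: label curves and flux fits -----------------------
        ptrms_cfg = ptrms.PtrmsConfig(correct_natural=correct_natural)
        background = study.background if len(study.background) else None
        flux_rows = []
        for sid in sorted(study.runs):
            if sid not in sample_pools:
                exclusions.append(
                    {"sample_id": sid, "stage": "fit", "reason": "no valid pool estimates"}
                )
                continue
            try:
                curve = ptrms.process_run(study.runs[sid], background, ptrms_cfg)
                fit = fit_flux(curve, sample_pools[sid])
            except Exception as exc:
                exclusions.append({"sample_id": sid, "stage": "fit", "reason": str(exc)})
                continue
            if not fit.converged:
                exclusions.append({"sample_id": sid, "stage": "fit", "reason": fit.message})
                continue
            flux_rows.append(
                {
                    "sample_id": sid,
                    "J": fit.J,
                    "se_J": fit.se_J,
                    "m": fit.m,
                    "se_m": fit.se_m,
                    "rss": fit.rss,
                    "n_points": fit.n_points,
                    "converged": int(fit.converged),
                }
            )
        flux_table = pd.DataFrame(flux_rows)
        log.info(
            "flux stage: %d fitted, %d excluded", len(flux_table),
            sum(1 for e in exclusions if e["stage"] == "fit"),
        )

        # --- join sample metadata -----------------------------------------
        if not flux_table.empty:
            sample_table = flux_table.merge(study.activities, on="sample_id", how="left")
            sample_table["condition"] = [
                condition_key(int(p), int(t)) if np.isfinite(p) else "unknown"
                for p, t in zip(sample_table["ppfd"], sample_table["temp_c"])
            ]
            pool_wide = pool_table.pivot(
                index="sample_id", columns="metabolite", values="plastidial_pool"
            ).rename(columns={"DXP": "A_DXP", "MEcDP": "B_MEcDP", "IDP+DMADP": "C_IDPDMADP"})
            sample_table = sample_table.merge(pool_wide, on="sample_id", how="left")
        else:
            sample_table = pd.DataFrame()

        # --- stage 4: FCC --------------------------------------------------
        if not sample_table.empty:
            records = sample_table.rename(columns={"activity": "v"})[
                ["condition", "J", "v"]
            ]
            fcc_estimates = mca.fcc_regression(records, group_by_condition=True)
            fcc_tbl = mca.fcc_table(fcc_estimates)
        else:
            fcc_tbl = pd.DataFrame()

        # --- write outputs --------------------------------------------------
        excl_table = pd.DataFrame(exclusions, columns=["sample_id", "stage", "reason"])
        pool_table.to_csv(out / "pool_table.tsv", sep="\t", index=False)
        flux_table.to_csv(out / "flux_table.tsv", sep="\t", index=False)
        sample_table.to_csv(out / "sample_table.tsv", sep="\t", index=False)
        fcc_tbl.to_csv(out / "fcc_table.tsv", sep="\t", index=False)
        excl_table.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        config.to_yaml(out / "config.yaml")
        log.info("pipeline complete: results in %s", out)

        return PipelineResult(
            sample_table=sample_table,
            pool_table=pool_table,
            flux_table=flux_table,
            fcc_table=fcc_tbl,
            exclusions=excl_table,
            config=config,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
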