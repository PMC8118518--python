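"""Pipeline orchestration: simulate/ingest -> gm estimation -> A/Ci fit ->
limitation partition -> sensitivity -> statistics, with CSV/JSON artifacts.

Stages are individually callable as functions on in-memory tables; the
:func:`run_pipeline` entry point glues them together from a config mapping
and writes each stage's outputs plus a run log.  A stage failure halts the
run with the stage name attached.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import aci as aci_mod
from . import drydown as drydown_mod
from . import io as io_mod
from . import limitation as lim_mod
from . import stats as stats_mod
from .config import DEFAULT_CONFIG, PhotoConfig
from .core import (H2O_CO2_DIFFUSIVITY, electron_transport_rate, gm_variable_j,
                   phi_psii, rd_from_dark)

KNOWN_CONFIG_KEYS = {
    "source", "scenario", "files", "rdark", "kinetics", "aci_fit",
    "seed", "outdir", "include_aci", "temperature_unit", "column_map",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def estimate_gm_table(observations: pd.DataFrame,
                      kinetics: PhotoConfig = DEFAULT_CONFIG,
                      rdark: float = 2.0) -> pd.DataFrame:
    """Per-record fluorescence reduction and variable-J gm estimation.

    Adds phi_psii, Jf, gamma_star (at each record's Tleaf), Rd, the gm/Cc
    estimate with validity flag and reason, and the conductance summary
    (gsc, gt, WUEi).  Invalid estimates keep their rows with NaN gm.
    """
    rd = rd_from_dark(rdark)
    out = observations.copy().reset_index(drop=True)
    out["phi_psii"] = phi_psii(out["Fs"].to_numpy(), out["Fm_prime"].to_numpy())
    out["Jf"] = electron_transport_rate(
        out["phi_psii"].to_numpy(), out["PPFD"].to_numpy(),
        kinetics.alpha, kinetics.beta)
    out["gamma_star"] = kinetics.gamma_star_at(out["Tleaf"].to_numpy())
    out["Rd"] = rd
    gms, ccs, valids, reasons = [], [], [], []
    for row in out.itertuples(index=False):
        est = gm_variable_j(row.An, row.Ci, row.gamma_star, rd, row.Jf)
        gms.append(est.gm)
        ccs.append(est.Cc)
        valids.append(est.valid)
        reasons.append(est.reason or "")
    out["gm"] = gms
    out["Cc"] = ccs
    out["valid"] = valids
    out["reason"] = reasons
    out["gsc"] = out["gs"] / H2O_CO2_DIFFUSIVITY
    out["gt"] = np.where(out["valid"],
                         1.0 / (1.0 / out["gsc"] + 1.0 / out["gm"]), np.nan)
    out["WUEi"] = out["An"] / out["gs"]
    return out


def fit_vcmax_table(aci_table: pd.DataFrame,
                    kinetics: PhotoConfig = DEFAULT_CONFIG,
                    rdark: float = 2.0,
                    ci_cutoff: float = 300.0,
                    x_col: str = "Ci") -> pd.DataFrame:
    """Fit Vcmax per (plant_id, day) curve; failed fits are flagged rows."""
    rows = []
    for (plant, day), grp in aci_table.groupby(["plant_id", "day"], sort=True):
        tleaf = float(grp["Tleaf"].median())
        params = aci_mod.FvCBParams(
            Vcmax=1.0, Rd=rd_from_dark(rdark),
            gamma_star=kinetics.gamma_star_at(tleaf),
            Kc=kinetics.kc_at(tleaf), Ko=kinetics.ko_at(tleaf),
            O=kinetics.O_mmol_mol,
        )
        row: dict[str, Any] = {
            "plant_id": plant, "day": day,
            "treatment": grp["treatment"].iloc[0] if "treatment" in grp else None,
        }
        try:
            fit = aci_mod.fit_vcmax(grp, params, ci_cutoff=ci_cutoff, x_col=x_col)
            row.update(Vcmax=fit.Vcmax, Rd=fit.Rd, rss=fit.rss,
                       n_points=fit.n_points, ci_cutoff=fit.ci_cutoff,
                       basis=fit.basis, error="")
        except aci_mod.FitError as exc:
            row.update(Vcmax=np.nan, Rd=np.nan, rss=np.nan, n_points=0,
                       ci_cutoff=ci_cutoff, basis=x_col, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def partition_table_from_estimates(estimates: pd.DataFrame,
                                   vcmax_fits: Optional[pd.DataFrame],
                                   kinetics: PhotoConfig = DEFAULT_CONFIG,
                                   default_vcmax: float = 100.0) -> pd.DataFrame:
    """Grassi–Magnani partition per valid record.

    dA/dCc is evaluated at each record's estimated Cc with the Vcmax fitted
    for that plant/day (falling back to ``default_vcmax`` when no fit is
    available); the evaluation point choice is recorded in ``attrs``.
    """
    df = estimates[estimates["valid"]].copy()
    if vcmax_fits is not None and len(vcmax_fits):
        good = vcmax_fits[np.isfinite(vcmax_fits["Vcmax"])]
        df = df.merge(good[["plant_id", "day", "Vcmax"]],
                      on=["plant_id", "day"], how="left")
    else:
        df["Vcmax"] = np.nan
    df["Vcmax"] = df["Vcmax"].fillna(default_vcmax)
    dadcc = []
    for row in df.itertuples(index=False):
        params = aci_mod.FvCBParams(
            Vcmax=row.Vcmax, Rd=row.Rd, gamma_star=row.gamma_star,
            Kc=kinetics.kc_at(row.Tleaf), Ko=kinetics.ko_at(row.Tleaf),
            O=kinetics.O_mmol_mol,
        )
        dadcc.append(aci_mod.dA_dCc(params, row.Cc))
    df["dAdCc"] = dadcc
    out = lim_mod.partition_table(df)
    out.attrs["dAdCc_evaluated_at"] = "record-level estimated Cc, per-plant/day fitted Vcmax"
    return out


def analyze_dataset(dataset: io_mod.Dataset,
                    kinetics: PhotoConfig = DEFAULT_CONFIG,
                    rdark: float = 2.0,
                    ci_cutoff: float = 300.0) -> dict[str, Any]:
    """Run every analysis stage on an in-memory dataset."""
    results: dict[str, Any] = {}
    stage = "gm"
    try:
        estimates = estimate_gm_table(dataset.observations, kinetics, rdark)
        results["estimates"] = estimates
        stage = "aci-fit"
        if dataset.aci is not None:
            results["vcmax"] = fit_vcmax_table(dataset.aci, kinetics, rdark,
                                               ci_cutoff=ci_cutoff)
        stage = "limits"
        results["limitation"] = partition_table_from_estimates(
            estimates, results.get("vcmax"), kinetics)
        stage = "sensitivity"
        valid = estimates[estimates["valid"]]
        if len(valid):
            results["sensitivity"] = lim_mod.gm_sensitivity_table(
                valid[["An", "Ci", "gamma_star", "Rd", "Jf"]])
        stage = "stats"
        analysis = stats_mod.derive_analysis_table(estimates)
        if dataset.water_status is not None:
            analysis = analysis.merge(
                dataset.water_status[["plant_id", "day", "treatment",
                                      "psi_soil", "psi_leaf", "ABA"]],
                on=["plant_id", "day", "treatment"], how="left")
        results["analysis"] = analysis
        results["correlation"] = stats_mod.correlation_matrix(analysis)
        comparisons = {}
        if "treatment" in analysis.columns and analysis["treatment"].nunique() > 1:
            for var in ("An", "gs", "gm", "WUEi"):
                comparisons[var] = stats_mod.compare_to_control(analysis, var)
        results["comparisons"] = comparisons
        fits = {}
        valid_an = analysis.dropna(subset=["gm", "gs"])
        if len(valid_an) >= 4:
            fits["gm_vs_gs"] = stats_mod.fit_best_relationship(
                valid_an["gs"], valid_an["gm"])
            pos = valid_an[(valid_an["gm_over_gs"] > 0) & (valid_an["WUEi"] > 0)]
            if len(pos) >= 4:
                fits["WUEi_vs_gm_over_gs"] = stats_mod.fit_best_relationship(
                    pos["gm_over_gs"], pos["WUEi"])
        results["fits"] = fits
    except Exception as exc:  # attach the failing stage
        raise StageError(stage, str(exc)) from exc
    return results


def _build_dataset(config: Mapping[str, Any]) -> io_mod.Dataset:
    source = config.get("source", "simulate")
    if source == "simulate":
        scenario_kwargs = dict(config.get("scenario", {}))
        noise = scenario_kwargs.pop("noise", None)
        if noise is not None:
            scenario_kwargs["noise"] = drydown_mod.NoiseModel(**noise)
        if "seed" in config and "seed" not in scenario_kwargs:
            scenario_kwargs["seed"] = int(config["seed"])
        scenario = drydown_mod.DrydownScenario(**scenario_kwargs)
        tables = drydown_mod.generate_observations(
            scenario, include_aci=bool(config.get("include_aci", True)))
        return io_mod.Dataset(
            observations=tables["observations"],
            water_status=tables["water_status"],
            truth=tables["truth"],
            aci=tables.get("aci"),
            metadata={"source": "simulate", "seed": scenario.seed},
        )
    if source == "files":
        files = config.get("files", {})
        if "observations" not in files:
            raise ValueError("files source requires files.observations")
        obs, rejects = io_mod.read_gas_exchange_table(
            files["observations"],
            column_map=config.get("column_map"),
            temperature_unit=config.get("temperature_unit", "C"),
        )
        ds = io_mod.Dataset(observations=obs,
                            metadata={"source": files["observations"],
                                      "n_rejected": len(rejects)})
        ds.metadata["rejects"] = rejects
        for key in ("water_status", "aci", "truth"):
            if key in files:
                setattr(ds, key, io_mod.read_table(files[key]))
        return ds
    raise ValueError(f"unknown source {source!r}")


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline from a config mapping, writing artifacts.

    Validates the config before any stage runs.  Writes estimates,
    limitation, sensitivity, Vcmax-fit and correlation CSVs, fit summaries
    as JSON and a run log with the config echo, seed and row accounting.
    Returns the in-memory results dict.
    """
    unknown = set(config) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kinetics = DEFAULT_CONFIG
    if "kinetics" in config:
        kinetics = PhotoConfig.from_mapping(config["kinetics"])
    rdark = float(config.get("rdark", 2.0))
    ci_cutoff = float(config.get("aci_fit", {}).get("ci_cutoff", 300.0))

    meta = {"seed": config.get("seed", ""), "config_hash": io_mod.config_hash(config)}
    dataset = _build_dataset(config)
    results = analyze_dataset(dataset, kinetics, rdark, ci_cutoff=ci_cutoff)

    io_mod.write_table(dataset.observations, outdir / "observations.csv", meta)
    if dataset.water_status is not None:
        io_mod.write_table(dataset.water_status, outdir / "water_status.csv", meta)
    if dataset.truth is not None:
        io_mod.write_table(dataset.truth, outdir / "truth.csv", meta)
    io_mod.write_table(results["estimates"], outdir / "estimates.csv", meta)
    io_mod.write_table(results["limitation"], outdir / "limitation.csv", meta)
    if "vcmax" in results:
        io_mod.write_table(results["vcmax"], outdir / "vcmax.csv", meta)
    if "sensitivity" in results:
        io_mod.write_table(results["sensitivity"], outdir / "sensitivity.csv", meta)
    io_mod.write_table(stats_mod.correlation_matrix_csv(results["correlation"]),
                       outdir / "correlation.csv", meta)
    for var, table in results["comparisons"].items():
        io_mod.write_table(table, outdir / f"compare_{var}.csv",
                           {**meta, "method": table.attrs.get("method", "")})
    fits_json = {
        name: {"family": fit.family, "coefficients": list(fit.coefficients),
               "r2": fit.r2, "p_value": fit.p_value, "n": fit.n,
               "significant": fit.significant}
        for name, fit in results["fits"].items()
    }
    (outdir / "fits.json").write_text(json.dumps(fits_json, indent=2))

    estimates = results["estimates"]
    log = {
        "config": {k: v for k, v in config.items()},
        "config_hash": meta["config_hash"],
        "seed": config.get("seed"),
        "n_input": int(len(dataset.observations))
        + int(dataset.metadata.get("n_rejected", 0)),
        "n_accepted": int(len(dataset.observations)),
        "n_rejected": int(dataset.metadata.get("n_rejected", 0)),
        "n_gm_valid": int(estimates["valid"].sum()),
        "n_gm_flagged": int((~estimates["valid"]).sum()),
        "flag_reasons": estimates.loc[~estimates["valid"], "reason"]
        .value_counts().to_dict(),
        "dAdCc_evaluated_at": results["limitation"].attrs.get("dAdCc_evaluated_at"),
        "comparison_method": "per-day Welch t vs control, Holm-adjusted across days",
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    results["dataset"] = dataset
    results["log"] = log
    return results
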