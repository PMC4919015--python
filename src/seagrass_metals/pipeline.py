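"""End-to-end orchestration: simulate → fit WRE → fit decomposition → predict
→ sediment statistics, with derived per-stage seeds and a reproduction
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import (
    DECOMP_SCHEDULE,
    EXPERIMENTS,
    METALS,
    fit_decomposition,
    substitute_detection_limits,
)
from .mixing import MCMCConfig, WRE_SCHEDULE, fit_wre, summarize_sources
from .predictive import draw_initial_carbon, fold_change, predict_concentration
from .sediment import ELEMENTS, d13c_trend, kruskal_wallis, steel_dwass_mc
from .synthetic import LOWEST_C, SimulationConfig, simulate_all
from .tables import config_to_dict, write_manifest, write_table


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    master_seed: int = 0
    simulation: SimulationConfig | None = None  # None -> defaults with derived seed
    wre_mcmc: MCMCConfig = WRE_SCHEDULE
    decomp_mcmc: MCMCConfig = DECOMP_SCHEDULE
    tracers: tuple[str, ...] = ("c_content", "d13c")
    predictive_iterations: int = 100_000
    metals: tuple[str, ...] = METALS
    experiments: tuple[str, ...] = EXPERIMENTS

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)


@dataclass
class RunReport:
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None
    outputs: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order, leaving completed outputs on a
    partial failure and naming the failing stage in the report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    sim_cfg = config.simulation or SimulationConfig(
        seed=derive_seed(config.master_seed, "simulate")
    )
    manifest: dict[str, Any] = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {
            s: derive_seed(config.master_seed, s)
            for s in ("simulate", "fit_wre", "fit_decomp", "predict", "sediment")
        },
        "simulation": config_to_dict(sim_cfg),
        "wre_mcmc": dataclasses.asdict(config.wre_mcmc),
        "decomp_mcmc": dataclasses.asdict(config.decomp_mcmc),
        "tracers": list(config.tracers),
        "stages": {},
    }

    stage = "simulate"
    try:
        data = simulate_all(sim_cfg)
        for name, df in data.items():
            write_table(df, out / f"{name}.csv")
        manifest["stages"][stage] = {"tables": sorted(data)}
        report.stages_completed.append(stage)
        report.outputs["tables"] = data
    except Exception as exc:
        return _fail(report, manifest, out, stage, exc)

    stage = "fit_wre"
    try:
        sources = summarize_sources(data["sources"], config.tracers)
        pair = (sources["eelgrass"], sources["epiphytes"])
        wre_mcmc = dataclasses.replace(
            config.wre_mcmc, seed=derive_seed(config.master_seed, stage)
        )
        wre = fit_wre(data["initial_leaves"], pair, config.tracers, wre_mcmc)
        write_table(pd.DataFrame({"r": wre.draws}), out / "wre_draws.csv")
        wre_summary = {
            "r_true": sim_cfg.r_true,
            **wre.summary,
            "acceptance_rate": wre.acceptance_rate,
            "n_retained": wre.n_retained,
        }
        write_table(pd.DataFrame([wre_summary]), out / "wre_summary.csv")
        manifest["stages"][stage] = {k: float(v) for k, v in wre.summary.items()}
        report.stages_completed.append(stage)
        report.outputs["wre"] = wre
    except Exception as exc:
        return _fail(report, manifest, out, stage, exc)

    stage = "fit_decomp"
    try:
        obs = substitute_detection_limits(
            data["decomposition"], sim_cfg.detection_limits
        )
        fits = {}
        rows = []
        for k, (metal, exp) in enumerate(
            (m, e) for m in config.metals for e in config.experiments
        ):
            mc = dataclasses.replace(
                config.decomp_mcmc,
                seed=derive_seed(config.master_seed, f"{stage}:{metal}:{exp}"),
            )
            fit = fit_decomposition(obs, metal, exp, mc)
            fits[(metal, exp)] = fit
            truth = sim_cfg.decomp_truth.get((metal, exp))
            row = {"metal": metal, "experiment": exp, "n_obs": fit.n_obs}
            for i, p in enumerate(("beta1", "beta2", "sigma2")):
                s = fit.summaries[p]
                row[f"{p}_true"] = truth[i] if truth else np.nan
                row[f"{p}_mean"] = s["mean"]
                row[f"{p}_ci_low"] = s["ci_low"]
                row[f"{p}_ci_high"] = s["ci_high"]
                row[f"{p}_rhat"] = fit.rhat[p]
            rows.append(row)
        write_table(pd.DataFrame(rows), out / "decomposition_posteriors.csv")
        manifest["stages"][stage] = {"fits": len(fits)}
        report.stages_completed.append(stage)
        report.outputs["decomp_fits"] = fits
    except Exception as exc:
        return _fail(report, manifest, out, stage, exc)

    stage = "predict"
    try:
        seed = derive_seed(config.master_seed, stage)
        eel, epi = sim_cfg.source_params
        c0 = draw_initial_carbon(
            report.outputs["wre"],
            (eel.means["c_content"], eel.sds["c_content"]),
            (epi.means["c_content"], epi.sds["c_content"]),
            n_iter=config.predictive_iterations,
            seed=seed,
        )
        rows = []
        for (metal, exp), fit in fits.items():
            p_init = predict_concentration(
                fit, c0, config.predictive_iterations, seed=seed + 1
            )
            p_low = predict_concentration(
                fit,
                LOWEST_C[exp],
                config.predictive_iterations,
                seed=seed + 2,
            )
            fc = fold_change(p_low, p_init)
            rows.append(
                {
                    "metal": metal,
                    "experiment": exp,
                    "pred_initial_mean": p_init.summary_linear["mean"],
                    "pred_lowest_mean": p_low.summary_linear["mean"],
                    **{k: v for k, v in fc.items() if k not in ("metal", "experiment")},
                }
            )
        write_table(pd.DataFrame(rows), out / "fold_changes.csv")
        manifest["stages"][stage] = {"targets": len(rows)}
        report.stages_completed.append(stage)
        report.outputs["fold_changes"] = rows
    except Exception as exc:
        return _fail(report, manifest, out, stage, exc)

    stage = "sediment"
    try:
        seed = derive_seed(config.master_seed, stage)
        sed = data["sediment"]
        trends = []
        for pool in ("eelgrass", "reference"):
            for el in ELEMENTS:
                t = d13c_trend(sed, el, pool)
                trends.append(dataclasses.asdict(t))
        write_table(pd.DataFrame(trends), out / "sediment_trends.csv")
        kw_rows = []
        surf = sed[sed["layer"] == "surface"]
        bottom_eel = sed[(sed["layer"] == "bottom") & (sed["pool"] == "eelgrass")]
        for el in ELEMENTS:
            groups = [
                surf[surf["pool"] == "eelgrass"][el].to_numpy(),
                surf[surf["pool"] == "reference"][el].to_numpy(),
                bottom_eel[el].to_numpy(),
            ]
            kw_rows.append({"element": el, **kruskal_wallis(groups)})
        write_table(pd.DataFrame(kw_rows), out / "sediment_kruskal.csv")
        manifest["stages"][stage] = {"trend_fits": len(trends)}
        report.stages_completed.append(stage)
        report.outputs["trends"] = trends
    except Exception as exc:
        return _fail(report, manifest, out, stage, exc)

    write_manifest(manifest, out / "manifest.yaml")
    return report


def _fail(
    report: RunReport, manifest: dict, out: Path, stage: str, exc: Exception
) -> RunReport:
    report.failed_stage = stage
    report.error = f"{type(exc).__name__}: {exc}"
    manifest["stages"][stage] = {"error": report.error}
    manifest["traceback"] = traceback.format_exc()
    write_manifest(manifest, out / "manifest.yaml")
    return report


# ---------------------------------------------------------------------------
# table validation

_VOCABULARIES = {
    "pool": {"eelgrass", "reference"},
    "layer": {"surface", "bottom"},
    "experiment": {"EX1", "EX2", "EX3"},
    "source": {"eelgrass", "epiphytes"},
}
_POSITIVE_COLS = ("cu", "zn", "cd", "pb")
_PERCENT_COLS = ("c_content", "n_content")


def validate_table(df: pd.DataFrame, name: str = "table") -> list[str]:
    """Schema/vocabulary/range checks for one pipeline table.

    Returns human-readable violation strings naming row and column; empty
    list means the table is clean.
    """
    violations: list[str] = []
    for col, vocab in _VOCABULARIES.items():
        if col not in df.columns:
            continue
        bad = ~df[col].isin(vocab)
        for idx in df.index[bad]:
            violations.append(
                f"{name} row {idx}, column {col!r}: unknown value {df.at[idx, col]!r}"
            )
    for col in _POSITIVE_COLS:
        if col not in df.columns:
            continue
        bad = ~(df[col] > 0)
        for idx in df.index[bad]:
            violations.append(
                f"{name} row {idx}, column {col!r}: non-positive concentration "
                f"{df.at[idx, col]!r}"
            )
    for col in _PERCENT_COLS:
        if col not in df.columns:
            continue
        bad = (df[col] < 0) | (df[col] > 100)
        for idx in df.index[bad]:
            violations.append(
                f"{name} row {idx}, column {col!r}: content outside [0, 100] "
                f"({df.at[idx, col]!r})"
            )
    if "d13c" in df.columns:
        bad = ~np.isfinite(df["d13c"].to_numpy(dtype=float))
        for idx in df.index[bad]:
            violations.append(f"{name} row {idx}, column 'd13c': non-finite value")
    return violations


def validate_tables(files: dict[str, str | Path]) -> dict[str, list[str]]:
    """Validate several table files; see `validate_table`."""
    from .tables import read_table

    report: dict[str, list[str]] = {}
    for name, path in files.items():
        df = read_table(path)
        report[name] = validate_table(df, name)
    return report
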