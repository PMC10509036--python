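"""End-to-end pipeline: screen -> fit -> diagnose -> project -> inequality.

`run_pipeline` orchestrates the stages over a panel + covariate pair
(either loaded from CSV or freshly simulated), writes every intermediate
table to the output directory, and emits a run manifest recording the
configuration hash, seeds, stage timings, row counts and any diagnostic
warnings.  Identical configuration + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import (FitDiagnostics, compute_dic,
                          posterior_predictive_check, prior_sensitivity,
                          psrf, vif_screen)
from .inequality import sii_draws, inequality_trend
from .io import read_covariates, read_panel
from .model import MCMCSpec, ModelSpec, build_design, fit, log_density_per_obs
from .projection import (DEFAULT_REPORT_YEARS, TARGET_CCI, aggregate_region,
                         count_on_track, predict_all, predict_country,
                         summarise_draws)
from .synthetic import ScenarioConfig, TrueParameters, generate_bundle

__all__ = ["PipelineConfig", "run_pipeline"]

_STRATUM_LEVELS_ORDERED = {
    "residence": ["urban", "rural"],
    "wealth": ["Q1", "Q2", "Q3", "Q4", "Q5"],
    "education": ["none", "primary", "secondary+"],
}


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    output_dir: str = "pipeline_out"
    panel_csv: str | None = None          # None -> simulate
    covariates_csv: str | None = None
    panel_dialect: str = "equity"
    scenario: dict = field(default_factory=dict)   # ScenarioConfig overrides
    variant: str = "residence"
    candidate_covariates: tuple[str, ...] = ("sdi", "ggdph", "gdpc")
    vif_threshold: float = 5.0
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 1
    interactions: bool = False
    prior_family: str = "gamma"
    sensitivity_refit: bool = False
    report_years: tuple[int, ...] = DEFAULT_REPORT_YEARS
    target: float = TARGET_CCI
    aggregation: str = "re_meta"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("candidate_covariates", "report_years"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stratum_levels_for(variant: str) -> list[str]:
    if variant == "national":
        return ["national"]
    if variant == "residence":
        return ["national", "urban", "rural"]
    return _STRATUM_LEVELS_ORDERED[variant]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest (also written to disk).

    Outputs in ``config.output_dir``: ``panel.csv``/``covariates.csv`` (when
    simulated), ``vif_rounds.csv``, ``projections_country.csv``,
    ``projections_region.csv``, ``inequality.csv``, ``diagnostics.json``,
    ``model_summary.csv`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    # ------------------------------------------------------------------ data
    t0 = time.time()
    if config.panel_csv is None:
        sc_kwargs = dict(config.scenario)
        sc_kwargs.setdefault("seed", config.seed)
        if config.variant in ("wealth", "education"):
            sc_kwargs.setdefault("stratum_types", ("national", config.variant))
        scenario = ScenarioConfig(**sc_kwargs)
        bundle = generate_bundle(scenario)
        panel, covariates = bundle.panel, bundle.covariates
        panel.to_csv(out / "panel.csv", index=False)
        covariates.to_csv(out / "covariates.csv", index=False)
        bundle.truth.to_yaml(out / "truth.yaml")
    else:
        panel = read_panel(config.panel_csv, dialect=config.panel_dialect)
        covariates = read_covariates(config.covariates_csv,
                                     required=config.candidate_covariates)
    timings["data"] = time.time() - t0

    # ------------------------------------------------------------ VIF screen
    t0 = time.time()
    vif = vif_screen(covariates, list(config.candidate_covariates),
                     threshold=config.vif_threshold)
    vif.to_frame().to_csv(out / "vif_rounds.csv", index=False)
    if vif.eliminated:
        warnings_log.append(f"VIF screen eliminated: {vif.eliminated}")
    timings["vif_screen"] = time.time() - t0

    # ------------------------------------------------------------------- fit
    t0 = time.time()
    spec = ModelSpec(
        variant=config.variant, covariates=tuple(vif.retained),
        prior_family=config.prior_family, interactions=config.interactions,
        mcmc=MCMCSpec(chains=config.chains, iterations=config.iterations,
                      burn_in=config.burn_in, thin=config.thin,
                      seed=config.seed))
    design = build_design(panel, covariates, spec)
    draws = fit(design, spec)
    draws.summary().to_csv(out / "model_summary.csv", index=False)
    if not draws.converged:
        warnings_log.append(f"PSRF above threshold: max={draws.max_psrf:.3f}")
    timings["fit"] = time.time() - t0

    # ------------------------------------------------------------ diagnostics
    t0 = time.time()
    dev = log_density_per_obs(draws, design)
    dic = compute_dic(dev["deviance_draws"], dev["deviance_at_mean"])
    ppc = posterior_predictive_check(draws, design)
    psrf_map = {k: psrf(v) for k, v in draws.parameter_chains().items()}
    sens = None
    if config.sensitivity_refit:
        alt = "half_cauchy" if config.prior_family == "gamma" else "gamma"
        spec_alt = ModelSpec(
            variant=spec.variant, covariates=spec.covariates, prior_family=alt,
            interactions=spec.interactions, mcmc=spec.mcmc)
        draws_alt = fit(design, spec_alt)
        first, second = ((draws, draws_alt) if config.prior_family == "gamma"
                         else (draws_alt, draws))
        sens = prior_sensitivity(first, second)
        if sens["flag"]:
            warnings_log.append("prior sensitivity: fixed-effect shift > 0.5 SD")
    diag = FitDiagnostics(dic=dic["dic"], pD=dic["pD"], ppc_pvalue=ppc,
                          psrf=psrf_map,
                          sensitivity_mad=sens["mad"] if sens else None)
    warnings_log.extend(diag.flags())
    with open(out / "diagnostics.json", "w") as fh:
        json.dump({"dic": diag.dic, "pD": diag.pD, "ppc_pvalue": diag.ppc_pvalue,
                   "psrf": diag.psrf, "sensitivity_mad": diag.sensitivity_mad,
                   "sensitivity_flag": sens["flag"] if sens else None},
                  fh, indent=2, default=float)
    timings["diagnostics"] = time.time() - t0

    # ------------------------------------------------------------ projections
    t0 = time.time()
    years = list(config.report_years)
    levels = _stratum_levels_for(config.variant)
    country_tables = []
    grids: dict[str, dict[str, np.ndarray]] = {lvl: {} for lvl in levels}
    for lvl in levels:
        table, g = predict_all(draws, covariates, years, lvl, config.target)
        country_tables.append(table)
        grids[lvl] = g
    proj_country = pd.concat(country_tables, ignore_index=True)
    proj_country.to_csv(out / "projections_country.csv", index=False)

    region_tables = []
    reg_of = dict(zip(design.countries,
                      [design.regions[k] for k in design.region_of_country]))
    for lvl in levels:
        for region in design.regions:
            members = {c: grids[lvl][c] for c in design.countries
                       if reg_of[c] == region}
            table, _, _ = aggregate_region(members, years, region, lvl,
                                           method=config.aggregation,
                                           target=config.target)
            region_tables.append(table)
    proj_region = pd.concat(region_tables, ignore_index=True)
    proj_region.to_csv(out / "projections_region.csv", index=False)

    base_lvl = "national" if "national" in levels else levels[0]
    on_track = count_on_track(
        proj_country.loc[proj_country["stratum_level"] == base_lvl], year=2030)
    timings["projection"] = time.time() - t0

    # ------------------------------------------------------------- inequality
    t0 = time.time()
    ineq_rows = []
    if config.variant == "residence":
        for c in design.countries:
            for t, yr in enumerate(years):
                gap = 100.0 * (grids["urban"][c][:, t] - grids["rural"][c][:, t])
                lo, hi = np.percentile(gap, [2.5, 97.5])
                ineq_rows.append({"unit": c, "year": yr,
                                  "stratifier": "residence",
                                  "metric": "urban_rural_gap",
                                  "value": float(gap.mean()),
                                  "cri_low": float(lo), "cri_high": float(hi)})
    elif config.variant in ("wealth", "education"):
        ordered = _STRATUM_LEVELS_ORDERED[config.variant]
        for c in design.countries:
            level_grid = np.stack([grids[lvl][c] for lvl in ordered])  # (g,D,T)
            for t, yr in enumerate(years):
                s = sii_draws(100.0 * level_grid[:, :, t].T)
                lo, hi = np.percentile(s, [2.5, 97.5])
                ineq_rows.append({"unit": c, "year": yr,
                                  "stratifier": config.variant, "metric": "sii",
                                  "value": float(s.mean()),
                                  "cri_low": float(lo), "cri_high": float(hi)})
    ineq = pd.DataFrame(ineq_rows)
    trend_rows = []
    if not ineq.empty:
        for c, sub in ineq.groupby("unit"):
            tr = inequality_trend(dict(zip(sub["year"], sub["value"])))
            tr["unit"] = c
            trend_rows.append(tr)
    pd.DataFrame(trend_rows).to_csv(out / "inequality_trends.csv", index=False)
    ineq.to_csv(out / "inequality.csv", index=False)
    timings["inequality"] = time.time() - t0

    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "n_panel_rows": int(len(panel)),
        "n_countries": len(design.countries),
        "n_regions": len(design.regions),
        "vif_retained": vif.retained,
        "vif_eliminated": vif.eliminated,
        "dic": diag.dic,
        "ppc_pvalue": diag.ppc_pvalue,
        "max_psrf_fixed_effects": draws.max_psrf,
        "on_track_2030": on_track,
        "warnings": warnings_log,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_time_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
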