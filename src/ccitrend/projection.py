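"""Country trajectories 2000-2030, target-attainment probabilities, and
regional aggregation.

Predictions push every posterior draw through the linear predictor and the
inverse logit, so credible intervals and the probability of reaching the
80% universal-coverage target by 2030 come directly from the posterior.
Regional aggregates combine country trajectories on the logit scale either
by DerSimonian-Laird random-effects meta-analysis (default) or by a
user-weighted mean, then back-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Design, PosteriorDraws, inv_logit

__all__ = [
    "DEFAULT_REPORT_YEARS",
    "TARGET_CCI",
    "ON_TRACK_PROBABILITY",
    "predict_country",
    "predict_all",
    "prob_target",
    "summarise_draws",
    "dersimonian_laird",
    "aggregate_region",
    "count_on_track",
]

#: reporting grid mirroring the figure years
DEFAULT_REPORT_YEARS = (2000, 2005, 2010, 2015, 2020, 2025, 2030)
#: universal health coverage operational target (proportion)
TARGET_CCI = 0.80
#: posterior probability above which a unit is classed on track
ON_TRACK_PROBABILITY = 0.70


def predict_country(draws: PosteriorDraws, covariates: pd.DataFrame,
                    country: str, years, stratum_level: str = "national",
                    use_interactions: bool = True) -> np.ndarray:
    """Per-draw CCI grid for one country: shape (draws_total, len(years)).

    Every requested year must appear in the covariate table for the
    country.  The linear predictor adds the country and region intercepts
    to the fixed-effect row; predictions through the inverse logit are
    always strictly inside (0, 1).
    """
    design = draws.design
    if country not in design.countries:
        raise ValueError(f"country {country!r} not in the fitted design")
    j = design.countries.index(country)
    years = list(years)
    cov = covariates.loc[covariates["country_id"] == country].set_index("year")
    missing = [y for y in years if y not in cov.index]
    if missing:
        raise ValueError(f"covariates missing for {country!r} years {missing}")

    beta = draws.stacked("beta")
    u = draws.stacked("u")[:, j] if design.hierarchical else 0.0
    out = np.empty((beta.shape[0], len(years)))
    for t, yr in enumerate(years):
        row = design.prediction_row(yr, stratum_level, cov.loc[yr].to_dict())
        if use_interactions:
            row = row + design.interaction_indicator(country, stratum_level)
        out[:, t] = inv_logit(beta @ row + u)
    return out


def prob_target(cci_draws: np.ndarray, target: float = TARGET_CCI) -> float:
    """Fraction of posterior draws at or above the coverage target."""
    d = np.asarray(cci_draws, dtype=float).ravel()
    if d.size < 100:
        raise ValueError("need at least 100 draws for a stable probability")
    return float(np.mean(d >= target))


def summarise_draws(cci_draws: np.ndarray, years, unit: str, stratum_level: str,
                    target: float = TARGET_CCI,
                    target_year: int | None = 2030) -> pd.DataFrame:
    """Posterior mean, central 95% CrI (percent scale) and P(CCI >= target).

    ``p_target`` is reported for every year; ``on_track`` uses the
    probability threshold at ``target_year`` only.
    """
    years = list(years)
    rows = []
    for t, yr in enumerate(years):
        d = cci_draws[:, t]
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({
            "unit": unit, "stratum_level": stratum_level, "year": yr,
            "mean": 100.0 * float(d.mean()),
            "cri_low": 100.0 * float(lo),
            "cri_high": 100.0 * float(hi),
            "p_target": prob_target(d, target) if d.size >= 100 else np.nan,
        })
    out = pd.DataFrame(rows)
    if target_year is not None and target_year in years:
        p30 = float(out.loc[out["year"] == target_year, "p_target"].iloc[0])
        out["on_track"] = p30 >= ON_TRACK_PROBABILITY
    return out


def predict_all(draws: PosteriorDraws, covariates: pd.DataFrame,
                years=DEFAULT_REPORT_YEARS, stratum_level: str = "national",
                target: float = TARGET_CCI) -> tuple[pd.DataFrame, dict]:
    """Projection table plus raw per-draw grids for every fitted country."""
    tables, grids = [], {}
    for c in draws.design.countries:
        g = predict_country(draws, covariates, c, years, stratum_level)
        grids[c] = g
        tables.append(summarise_draws(g, years, c, stratum_level, target))
    return pd.concat(tables, ignore_index=True), grids


def dersimonian_laird(estimates, ses) -> dict:
    """DerSimonian-Laird random-effects pooling of k independent estimates.

    Returns the pooled estimate, its SE, Cochran's Q, the method-of-moments
    between-study variance tau2, and the normalised random-effects weights.
    """
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.shape != s.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("estimates and ses must be equal-length 1-D arrays")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = y.size
    w = 1.0 / s ** 2
    ybar_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar_fe) ** 2))
    if k > 1:
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_re = 1.0 / (s ** 2 + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se_pooled = float(np.sqrt(1.0 / np.sum(w_re)))
    return {"pooled": pooled, "se": se_pooled, "Q": Q, "tau2": tau2,
            "weights": w_re / np.sum(w_re)}


def aggregate_region(country_grids: dict[str, np.ndarray], years,
                     region: str, stratum_level: str = "national",
                     method: str = "re_meta",
                     weights: dict[str, float] | None = None,
                     target: float = TARGET_CCI) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Combine the member countries' per-draw CCI grids into a regional one.

    ``re_meta`` (default): per year, country trajectories are pooled on the
    logit scale with DerSimonian-Laird random-effects weights derived from
    each country's posterior mean and SD; the pooling weights are then
    applied to every posterior draw, and summaries are taken over draws.
    ``weighted_mean``: per-draw weighted average on the logit scale using
    caller-supplied weights (e.g. population).  A single-country region
    returns the country grid unchanged.

    Returns (summary table, per-draw regional grid, metadata with the
    heterogeneity SD and the weights used).
    """
    if not country_grids:
        raise ValueError("region has no member countries")
    names = sorted(country_grids)
    grids = np.stack([country_grids[c] for c in names])  # (k, D, T)
    k, D, T = grids.shape
    years = list(years)
    if len(years) != T:
        raise ValueError("years length does not match grid width")

    if k == 1:
        agg = grids[0]
        meta = {"method": method, "heterogeneity_sd": [0.0] * T,
                "weights": {names[0]: 1.0}}
    elif method == "weighted_mean":
        if weights is None:
            raise ValueError("weighted_mean requires per-country weights")
        missing = [c for c in names if c not in weights]
        if missing:
            raise ValueError(f"missing weights for {missing}")
        w = np.array([weights[c] for c in names], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
        logit_g = np.log(grids / (1.0 - grids))
        agg = inv_logit(np.tensordot(w, logit_g, axes=(0, 0)))
        meta = {"method": method, "heterogeneity_sd": [np.nan] * T,
                "weights": dict(zip(names, w))}
    elif method == "re_meta":
        logit_g = np.log(grids / (1.0 - grids))
        agg = np.empty((D, T))
        het, wlast = [], None
        for t in range(T):
            est = logit_g[:, :, t].mean(axis=1)
            se = logit_g[:, :, t].std(axis=1, ddof=1)
            se = np.maximum(se, 1e-8)
            dl = dersimonian_laird(est, se)
            het.append(float(np.sqrt(dl["tau2"])))
            w = dl["weights"]
            wlast = w
            agg[:, t] = inv_logit(np.tensordot(w, logit_g[:, :, t], axes=(0, 0)))
        meta = {"method": method, "heterogeneity_sd": het,
                "weights": dict(zip(names, wlast))}
    else:
        raise ValueError(f"unknown aggregation method {method!r}")

    table = summarise_draws(agg, years, region, stratum_level, target)
    table["heterogeneity_sd"] = meta["heterogeneity_sd"]
    return table, agg, meta


def count_on_track(projections: pd.DataFrame, year: int = 2030,
                   threshold: float = ON_TRACK_PROBABILITY) -> dict:
    """Units whose P(CCI >= target) at ``year`` meets the probability bar.

    ``projections`` is the long table from :func:`summarise_draws` /
    :func:`predict_all` (columns unit, year, p_target).
    """
    sub = projections.loc[projections["year"] == year]
    if sub.empty:
        raise ValueError(f"no projections for year {year}")
    on = sub.loc[sub["p_target"] >= threshold, "unit"].tolist()
    return {"count": len(on), "units": sorted(on), "year": year,
            "threshold": threshold, "n_units": len(sub)}
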