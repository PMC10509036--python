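"""Bayesian hierarchical linear regression on logit-transformed CCI.

The observation model is

    y_l = logit(CCI_l) = x_l' beta + u_{j(l)} + eps_l,   eps_l ~ N(0, tau^2)

where x_l collects a global intercept, calendar year (centred at 2015 and
scaled per decade), stratum dummies (residence / wealth quintile / maternal
education, with a declared reference level), standardised time-varying
country covariates (SDI, GGDPH, log GDPC, ...), and optionally
residence-by-country interaction dummies.  Country intercepts are partially
pooled within regions,

    u_j ~ N(v_{k(j)}, sigma_c^2),    v_k ~ N(0, sigma_r^2),

so that countries with a single survey borrow strength from their region.

Inference is by a blocked Gibbs sampler: every full conditional is available
in closed form.  Two hyperprior families are supported:

* ``gamma`` (baseline): Gamma(0.01, 0.01) on each precision
  (1/tau^2, 1/sigma_c^2, 1/sigma_r^2);
* ``half_cauchy`` (sensitivity): half-Cauchy(0, scale) on each SD, handled
  through the inverse-gamma scale-mixture representation
  sigma^2 | a ~ InvGamma(1/2, 1/a),  a ~ InvGamma(1/2, 1/scale^2),
  which keeps every update conjugate.

Fixed effects get independent N(0, prior_sd^2) priors (diffuse by default;
interaction blocks get a tighter shrinkage prior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "logit",
    "inv_logit",
    "ModelSpec",
    "MCMCSpec",
    "Design",
    "PosteriorDraws",
    "build_design",
    "fit",
    "log_density_per_obs",
    "save_draws",
    "load_draws",
    "STRATUM_REFERENCE",
]

#: reference level per stratum type (absorbed into the intercept)
STRATUM_REFERENCE = {
    "national": "national",
    "residence": "national",
    "wealth": "Q1",
    "education": "none",
}

#: canonical level order per stratum type
STRATUM_LEVELS = {
    "national": ["national"],
    "residence": ["national", "urban", "rural"],
    "wealth": ["Q1", "Q2", "Q3", "Q4", "Q5"],
    "education": ["none", "primary", "secondary+"],
}


def logit(p, eps: float = 1e-3):
    """Log-odds of a proportion, clipping to [eps, 1-eps] first.

    Boundary CCI values (0 or 1) occur in sparse strata; clipping keeps the
    transform finite without discarding the observation.
    """
    p = np.asarray(p, dtype=float)
    if not (0.0 < eps <= 0.01):
        raise ValueError(f"eps must be in (0, 0.01], got {eps}")
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Inverse logit; output always strictly inside (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    # clamp saturation so the open-interval contract survives underflow
    out = np.clip(out, np.finfo(float).tiny, np.nextafter(1.0, 0.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class MCMCSpec:
    """Sampler settings.  PSRF needs at least two chains."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (PSRF)")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelSpec:
    """Which model variant to fit and with what priors.

    variant
        ``residence`` | ``wealth`` | ``education`` | ``national``.
        The wealth and education variants use year + stratum dummies +
        covariates only (no residence terms).
    covariates
        Ordered subset of columns of the covariate table to include
        (``gdpc`` is log-transformed before standardisation).
    prior_family
        ``gamma`` (baseline) or ``half_cauchy`` (sensitivity analysis,
        scale ``half_cauchy_scale``, default 25).
    interactions
        Include residence-by-country interaction dummies (residence
        variant only).
    """

    variant: str = "residence"
    covariates: tuple[str, ...] = ("sdi", "ggdph", "gdpc")
    prior_family: str = "gamma"
    half_cauchy_scale: float = 25.0
    interactions: bool = False
    beta_prior_sd: float = 10.0
    interaction_prior_sd: float = 1.0
    logit_eps: float = 1e-3
    psrf_threshold: float = 1.1
    mcmc: MCMCSpec = field(default_factory=MCMCSpec)

    def __post_init__(self) -> None:
        if self.variant not in STRATUM_LEVELS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.prior_family not in ("gamma", "half_cauchy"):
            raise ValueError(f"unknown prior_family {self.prior_family!r}")
        if self.interactions and self.variant != "residence":
            raise ValueError("interactions are residence-by-country only")


@dataclass
class Design:
    """Immutable design structure produced by :func:`build_design`.

    Holds the response on the logit scale, the fixed-effect matrix with its
    per-column prior SDs, the country/region index maps, and the centring
    and scaling constants needed to build prediction rows later.
    """

    y: np.ndarray                    # (n,) logit CCI
    X: np.ndarray                    # (n, p) fixed effects
    col_names: list[str]
    prior_sd: np.ndarray             # (p,) prior SD per column
    country_idx: np.ndarray          # (n,) 0..J-1
    countries: list[str]             # J labels
    region_of_country: np.ndarray    # (J,) 0..K-1
    regions: list[str]               # K labels
    variant: str
    stratum_reference: str
    year_center: float
    year_scale: float
    covariate_stats: dict            # name -> {"mean":, "sd":, "log": bool}
    obs_stratum: np.ndarray          # (n,) stratum level labels
    obs_year: np.ndarray             # (n,) calendar year
    obs_cci: np.ndarray              # (n,) observed CCI proportion

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def hierarchical(self) -> bool:
        return len(self.countries) > 1

    def covariate_row(self, cov_values: dict) -> dict:
        """Standardise raw covariate values with the design's constants."""
        out = {}
        for name, st in self.covariate_stats.items():
            v = float(cov_values[name])
            if st["log"]:
                v = np.log(v)
            out[name] = (v - st["mean"]) / st["sd"]
        return out

    def prediction_row(self, year: float, stratum_level: str, cov_values: dict) -> np.ndarray:
        """Fixed-effect row vector for one (year, stratum, covariates) cell.

        Interaction columns, when present, are not used for prediction of
        new cells; country-specific residence shifts are carried by the
        corresponding interaction dummies of that country.
        """
        row = np.zeros(len(self.col_names))
        std = self.covariate_row(cov_values)
        for i, name in enumerate(self.col_names):
            if name == "intercept":
                row[i] = 1.0
            elif name == "year_c":
                row[i] = (year - self.year_center) / self.year_scale
            elif name.startswith("stratum["):
                row[i] = 1.0 if name == f"stratum[{stratum_level}]" else 0.0
            elif name in std:
                row[i] = std[name]
        return row

    def interaction_indicator(self, country: str, stratum_level: str) -> np.ndarray:
        """Indicator vector selecting this country's interaction column, if any."""
        row = np.zeros(len(self.col_names))
        name = f"stratum[{stratum_level}]:country[{country}]"
        if name in self.col_names:
            row[self.col_names.index(name)] = 1.0
        return row


def build_design(panel: pd.DataFrame, covariates: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble the model design from a coverage panel and covariate table.

    The panel must have columns ``country_id, region_id, year, stratum_type,
    stratum_level, cci``; rows are restricted to the stratum types implied
    by ``spec.variant`` (national rows are kept for the residence variant,
    where "national" is the reference level).  Every (country, year) pair in
    the panel must appear in the covariate table.

    Returns a :class:`Design`; rows are canonicalised (sorted) so the
    posterior does not depend on input row order.
    """
    req = {"country_id", "region_id", "year", "stratum_type", "stratum_level", "cci"}
    if not req.issubset(panel.columns):
        raise ValueError(f"panel missing columns: {sorted(req - set(panel.columns))}")

    if spec.variant == "residence":
        keep = panel["stratum_type"].isin(["national", "residence"])
    elif spec.variant == "national":
        keep = panel["stratum_type"] == "national"
    else:
        keep = panel["stratum_type"] == spec.variant
    sub = panel.loc[keep].copy()
    if len(sub) == 0:
        raise ValueError(f"panel has no rows for variant {spec.variant!r}")

    levels = STRATUM_LEVELS[spec.variant]
    bad = set(sub["stratum_level"]) - set(levels)
    if bad:
        raise ValueError(f"unknown stratum levels for {spec.variant!r}: {sorted(bad)}")

    # canonical row order -> posterior invariant to input permutation
    sub["__lvl"] = sub["stratum_level"].map({l: i for i, l in enumerate(levels)})
    sub = sub.sort_values(["country_id", "year", "__lvl"], kind="mergesort").reset_index(drop=True)

    # covariate lookup; report every gap, not just the first
    cov = covariates.set_index(["country_id", "year"])
    pairs = list(zip(sub["country_id"], sub["year"]))
    gaps = sorted({p for p in pairs if p not in cov.index})
    if gaps:
        raise ValueError(f"covariate table missing (country, year) pairs: {gaps[:20]}")
    cov_rows = cov.loc[pairs]

    countries = sorted(sub["country_id"].unique())
    c_map = {c: j for j, c in enumerate(countries)}
    country_idx = sub["country_id"].map(c_map).to_numpy()
    reg = sub.drop_duplicates("country_id").set_index("country_id")["region_id"]
    if sub.groupby("country_id")["region_id"].nunique().max() > 1:
        raise ValueError("a country maps to more than one region")
    regions = sorted(reg.unique())
    r_map = {r: k for k, r in enumerate(regions)}
    region_of_country = np.array([r_map[reg[c]] for c in countries])

    year_center, year_scale = 2015.0, 10.0
    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    prior_sd = [spec.beta_prior_sd]

    cols.append((sub["year"].to_numpy(float) - year_center) / year_scale)
    names.append("year_c")
    prior_sd.append(spec.beta_prior_sd)

    reference = STRATUM_REFERENCE[spec.variant]
    for lvl in levels:
        if lvl == reference:
            continue
        cols.append((sub["stratum_level"] == lvl).to_numpy(float))
        names.append(f"stratum[{lvl}]")
        prior_sd.append(spec.beta_prior_sd)

    cov_stats: dict[str, dict] = {}
    for name in spec.covariates:
        if name not in cov_rows.columns:
            raise ValueError(f"covariate {name!r} not in covariate table")
        v = cov_rows[name].to_numpy(float)
        use_log = name == "gdpc"
        if use_log:
            if np.any(v <= 0):
                raise ValueError("gdpc must be positive for log transform")
            v = np.log(v)
        m, s = float(v.mean()), float(v.std(ddof=0))
        if s == 0.0:
            raise ValueError(
                f"covariate {name!r} is constant over the panel; "
                "remove it (see the VIF screen)"
            )
        cols.append((v - m) / s)
        names.append(name)
        prior_sd.append(spec.beta_prior_sd)
        cov_stats[name] = {"mean": m, "sd": s, "log": use_log}

    if spec.interactions:
        # urban/rural shifts per non-reference country (shrunk toward 0)
        for lvl in ("urban", "rural"):
            for c in countries[1:]:
                ind = ((sub["stratum_level"] == lvl) & (sub["country_id"] == c)).to_numpy(float)
                if ind.sum() == 0:
                    continue
                cols.append(ind)
                names.append(f"stratum[{lvl}]:country[{c}]")
                prior_sd.append(spec.interaction_prior_sd)

    X = np.column_stack(cols)
    # exact collinearity check (rank of standardised X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (collinear columns); "
            "run the VIF screen on the candidate covariates"
        )

    y = logit(sub["cci"].to_numpy(float), eps=spec.logit_eps)
    return Design(
        y=np.asarray(y, float),
        X=X,
        col_names=names,
        prior_sd=np.array(prior_sd),
        country_idx=country_idx,
        countries=countries,
        region_of_country=region_of_country,
        regions=regions,
        variant=spec.variant,
        stratum_reference=reference,
        year_center=year_center,
        year_scale=year_scale,
        covariate_stats=cov_stats,
        obs_stratum=sub["stratum_level"].to_numpy(),
        obs_year=sub["year"].to_numpy(float),
        obs_cci=sub["cci"].to_numpy(float),
    )


@dataclass
class PosteriorDraws:
    """MCMC output organised by chain.

    ``beta`` has shape (chains, draws, p); ``u`` (country intercept
    deviations) and ``v`` (region deviations) are (chains, draws, J) and
    (chains, draws, K); the variance parameters are (chains, draws).
    """

    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau2: np.ndarray
    sigma2_country: np.ndarray
    sigma2_region: np.ndarray
    design: Design
    spec: ModelSpec
    converged: bool = True
    max_psrf: float = np.nan

    @property
    def n_draws_total(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        a = getattr(self, name)
        return a.reshape(-1, *a.shape[2:])

    def parameter_chains(self) -> dict[str, np.ndarray]:
        """Scalar parameters as {name: (chains, draws)} — input to PSRF."""
        out = {}
        for i, nm in enumerate(self.design.col_names):
            out[nm] = self.beta[:, :, i]
        out["tau"] = np.sqrt(self.tau2)
        if self.design.hierarchical:
            out["sigma_country"] = np.sqrt(self.sigma2_country)
            out["sigma_region"] = np.sqrt(self.sigma2_region)
        return out

    def fixed_effect_names(self) -> list[str]:
        return [n for n in self.design.col_names if ":country[" not in n]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and central 95% CrI per fixed effect."""
        rows = []
        b = self.stacked("beta")
        for i, nm in enumerate(self.design.col_names):
            d = b[:, i]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append({"parameter": nm, "mean": d.mean(), "sd": d.std(ddof=1),
                         "cri_low": lo, "cri_high": hi})
        t = self.stacked("tau2") ** 0.5
        lo, hi = np.percentile(t, [2.5, 97.5])
        rows.append({"parameter": "tau", "mean": t.mean(), "sd": t.std(ddof=1),
                     "cri_low": lo, "cri_high": hi})
        return pd.DataFrame(rows)

    def coef_raw_scale(self) -> pd.DataFrame:
        """Covariate and trend coefficients mapped back to raw units.

        ``year_c`` is already per decade; each covariate coefficient is
        divided by the SD used in standardisation (per unit of the possibly
        log-transformed covariate).
        """
        b = self.stacked("beta")
        rows = []
        for i, nm in enumerate(self.design.col_names):
            if nm in self.design.covariate_stats:
                sc = self.design.covariate_stats[nm]["sd"]
            elif nm == "year_c" or nm.startswith("stratum["):
                sc = 1.0
            else:
                continue
            d = b[:, i] / sc
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append({"parameter": nm, "mean": d.mean(), "sd": d.std(ddof=1),
                         "cri_low": lo, "cri_high": hi})
        return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws plus the design and spec to one ``.npz``."""
    import json

    d, s = draws.design, draws.spec
    meta = {
        "col_names": d.col_names, "countries": d.countries, "regions": d.regions,
        "variant": d.variant, "stratum_reference": d.stratum_reference,
        "year_center": d.year_center, "year_scale": d.year_scale,
        "covariate_stats": d.covariate_stats,
        "spec": {
            "variant": s.variant, "covariates": list(s.covariates),
            "prior_family": s.prior_family, "half_cauchy_scale": s.half_cauchy_scale,
            "interactions": s.interactions, "beta_prior_sd": s.beta_prior_sd,
            "interaction_prior_sd": s.interaction_prior_sd,
            "logit_eps": s.logit_eps, "psrf_threshold": s.psrf_threshold,
            "mcmc": {"chains": s.mcmc.chains, "iterations": s.mcmc.iterations,
                     "burn_in": s.mcmc.burn_in, "thin": s.mcmc.thin,
                     "seed": s.mcmc.seed},
        },
        "converged": bool(draws.converged), "max_psrf": float(draws.max_psrf),
    }
    np.savez_compressed(
        path, meta=np.array(json.dumps(meta)),
        beta=draws.beta, u=draws.u, v=draws.v, tau2=draws.tau2,
        sigma2_country=draws.sigma2_country, sigma2_region=draws.sigma2_region,
        y=d.y, X=d.X, prior_sd=d.prior_sd, country_idx=d.country_idx,
        region_of_country=d.region_of_country,
        obs_stratum=d.obs_stratum.astype(str), obs_year=d.obs_year,
        obs_cci=d.obs_cci)


def load_draws(path) -> PosteriorDraws:
    import json

    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    sp = meta["spec"]
    spec = ModelSpec(variant=sp["variant"], covariates=tuple(sp["covariates"]),
                     prior_family=sp["prior_family"],
                     half_cauchy_scale=sp["half_cauchy_scale"],
                     interactions=sp["interactions"],
                     beta_prior_sd=sp["beta_prior_sd"],
                     interaction_prior_sd=sp["interaction_prior_sd"],
                     logit_eps=sp["logit_eps"],
                     psrf_threshold=sp["psrf_threshold"],
                     mcmc=MCMCSpec(**sp["mcmc"]))
    design = Design(
        y=z["y"], X=z["X"], col_names=list(meta["col_names"]),
        prior_sd=z["prior_sd"], country_idx=z["country_idx"],
        countries=list(meta["countries"]),
        region_of_country=z["region_of_country"], regions=list(meta["regions"]),
        variant=meta["variant"], stratum_reference=meta["stratum_reference"],
        year_center=meta["year_center"], year_scale=meta["year_scale"],
        covariate_stats=meta["covariate_stats"],
        obs_stratum=z["obs_stratum"], obs_year=z["obs_year"], obs_cci=z["obs_cci"])
    return PosteriorDraws(
        beta=z["beta"], u=z["u"], v=z["v"], tau2=z["tau2"],
        sigma2_country=z["sigma2_country"], sigma2_region=z["sigma2_region"],
        design=design, spec=spec, converged=meta["converged"],
        max_psrf=meta["max_psrf"])


def _sample_invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    # InvGamma(shape, rate) via 1 / Gamma(shape, scale=1/rate)
    return rate / rng.gamma(shape)


def _run_chain(design: Design, spec: ModelSpec, seed: int,
               fixed_tau2: float | None) -> dict[str, np.ndarray]:
    """One Gibbs chain.

    The hierarchical case uses the centred parameterization — the global
    intercept beta0 is the hypermean of the region effects,
    v_k ~ N(beta0, sigma_r^2), u_j ~ N(v_{k(j)}, sigma_c^2), and the
    likelihood mean is X[:, 1:] beta[1:] + u_{j(l)} — which is the same
    joint posterior as intercept-in-X but avoids the additive ridge between
    the intercept and the random-effect means that cripples mixing.
    Stored draws convert back to the deviation convention (u, v relative to
    beta0) so predictions are always ``X @ beta + u``.
    """
    rng = np.random.default_rng(seed)
    y, X = design.y, design.X
    n, p = X.shape
    J = len(design.countries)
    K = len(design.regions)
    cidx = design.country_idx
    rofc = design.region_of_country
    hier = design.hierarchical
    if hier and design.col_names[0] != "intercept":
        raise ValueError("first design column must be the intercept")

    prior_prec = 1.0 / design.prior_sd ** 2
    n_by_country = np.bincount(cidx, minlength=J).astype(float)
    n_by_region = np.bincount(rofc, minlength=K).astype(float)

    if hier:
        Xs = X[:, 1:]                       # slopes only; intercept via hierarchy
        prec_s = prior_prec[1:]
        prec_b0 = prior_prec[0]
    else:
        Xs = X
        prec_s = prior_prec
        prec_b0 = 0.0
    XtX = Xs.T @ Xs
    ps = Xs.shape[1]

    # initial values: ridge solve, moderate variances
    beta_all = np.linalg.solve(X.T @ X + np.diag(prior_prec), X.T @ y)
    b0 = beta_all[0] if hier else 0.0
    bs = beta_all[1:] if hier else beta_all
    u = np.full(J, b0)
    v = np.full(K, b0)
    tau2 = fixed_tau2 if fixed_tau2 is not None else float(np.var(y - X @ beta_all) + 0.1)
    s2c, s2r = 0.5, 0.5
    hc2 = spec.half_cauchy_scale ** 2
    a_tau = a_c = a_r = 1.0  # scale-mixture auxiliaries (half-Cauchy family)

    kept = (spec.mcmc.iterations - spec.mcmc.burn_in) // spec.mcmc.thin
    out_beta = np.empty((kept, p))
    out_u = np.empty((kept, J))
    out_v = np.empty((kept, K))
    out_t2 = np.empty(kept)
    out_s2c = np.empty(kept)
    out_s2r = np.empty(kept)

    g_shape, g_rate = 0.01, 0.01  # baseline gamma prior on precisions
    half_cauchy = spec.prior_family == "half_cauchy"

    k = 0
    for it in range(spec.mcmc.iterations):
        # --- slope fixed effects ---
        resid_u = y - u[cidx] if hier else y
        Q = XtX / tau2 + np.diag(prec_s)
        L = np.linalg.cholesky(Q)
        rhs = Xs.T @ resid_u / tau2
        mean = np.linalg.solve(Q, rhs)
        bs = mean + np.linalg.solve(L.T, rng.standard_normal(ps))

        if hier:
            # --- country intercepts (centred: carry beta0) ---
            r = y - Xs @ bs
            sums = np.bincount(cidx, weights=r, minlength=J)
            prec = n_by_country / tau2 + 1.0 / s2c
            mu_u = (sums / tau2 + v[rofc] / s2c) / prec
            u = mu_u + rng.standard_normal(J) / np.sqrt(prec)

            # --- region means around beta0 ---
            sums_u = np.bincount(rofc, weights=u, minlength=K)
            prec_v = n_by_region / s2c + 1.0 / s2r
            mu_v = (sums_u / s2c + b0 / s2r) / prec_v
            v = mu_v + rng.standard_normal(K) / np.sqrt(prec_v)

            # --- global intercept = hypermean of regions ---
            prec0 = K / s2r + prec_b0
            mu0 = (v.sum() / s2r) / prec0
            b0 = mu0 + rng.standard_normal() / np.sqrt(prec0)

            # --- hierarchy variances ---
            ss_c = float(np.sum((u - v[rofc]) ** 2))
            ss_r = float(np.sum((v - b0) ** 2))
            if half_cauchy:
                s2c = _sample_invgamma(rng, 0.5 + J / 2.0, 1.0 / a_c + ss_c / 2.0)
                a_c = _sample_invgamma(rng, 1.0, 1.0 / hc2 + 1.0 / s2c)
                s2r = _sample_invgamma(rng, 0.5 + K / 2.0, 1.0 / a_r + ss_r / 2.0)
                a_r = _sample_invgamma(rng, 1.0, 1.0 / hc2 + 1.0 / s2r)
            else:
                s2c = _sample_invgamma(rng, g_shape + J / 2.0, g_rate + ss_c / 2.0)
                s2r = _sample_invgamma(rng, g_shape + K / 2.0, g_rate + ss_r / 2.0)

        # --- residual variance ---
        if fixed_tau2 is None:
            rr = y - Xs @ bs - (u[cidx] if hier else 0.0)
            ssr = float(rr @ rr)
            if half_cauchy:
                tau2 = _sample_invgamma(rng, 0.5 + n / 2.0, 1.0 / a_tau + ssr / 2.0)
                a_tau = _sample_invgamma(rng, 1.0, 1.0 / hc2 + 1.0 / tau2)
            else:
                tau2 = _sample_invgamma(rng, g_shape + n / 2.0, g_rate + ssr / 2.0)

        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            if hier:
                out_beta[k, 0] = b0
                out_beta[k, 1:] = bs
                out_u[k] = u - b0        # deviation convention for prediction
                out_v[k] = v - b0
            else:
                out_beta[k] = bs
                out_u[k] = 0.0
                out_v[k] = 0.0
            out_t2[k] = tau2
            out_s2c[k] = s2c
            out_s2r[k] = s2r
            k += 1

    return {"beta": out_beta[:k], "u": out_u[:k], "v": out_v[:k],
            "tau2": out_t2[:k], "s2c": out_s2c[:k], "s2r": out_s2r[:k]}


def fit(design: Design, spec: ModelSpec, *, fixed_tau2: float | None = None) -> PosteriorDraws:
    """Draw from the posterior of the hierarchical model by blocked Gibbs.

    ``fixed_tau2`` holds the residual variance at a known value (used by
    closed-form validation against the conjugate normal regression).

    Convergence is assessed with the Gelman–Rubin PSRF on every scalar
    parameter; if any fixed-effect PSRF exceeds ``spec.psrf_threshold`` the
    result is flagged (``converged=False``) with a warning, never silently.
    """
    if design.n_obs == 0:
        raise ValueError("empty design")
    if spec.mcmc.seed is None:
        raise ValueError("an explicit MCMC seed is required for reproducibility")

    seeds = np.random.SeedSequence(spec.mcmc.seed).spawn(spec.mcmc.chains)
    chains = [_run_chain(design, spec, int(s.generate_state(1)[0] % (2 ** 31)), fixed_tau2)
              for s in seeds]

    draws = PosteriorDraws(
        beta=np.stack([c["beta"] for c in chains]),
        u=np.stack([c["u"] for c in chains]),
        v=np.stack([c["v"] for c in chains]),
        tau2=np.stack([c["tau2"] for c in chains]),
        sigma2_country=np.stack([c["s2c"] for c in chains]),
        sigma2_region=np.stack([c["s2r"] for c in chains]),
        design=design,
        spec=spec,
    )

    from .diagnostics import psrf  # local import avoids a cycle

    vals = []
    for nm in draws.fixed_effect_names():
        i = design.col_names.index(nm)
        vals.append(psrf(draws.beta[:, :, i]))
    with np.errstate(invalid="ignore"):
        draws.max_psrf = float(np.nanmax(vals)) if vals else np.nan
    if np.isfinite(draws.max_psrf) and draws.max_psrf > spec.psrf_threshold:
        draws.converged = False
        warnings.warn(
            f"PSRF {draws.max_psrf:.3f} exceeds {spec.psrf_threshold}; "
            "chains may not have converged", RuntimeWarning, stacklevel=2)
    return draws


def _mu_matrix(draws: PosteriorDraws, design: Design) -> np.ndarray:
    """Linear predictor for every draw x observation: (D, n)."""
    beta = draws.stacked("beta")
    mu = beta @ design.X.T
    if design.hierarchical:
        u = draws.stacked("u")
        mu = mu + u[:, design.country_idx]
    return mu


def log_density_per_obs(draws: PosteriorDraws, design: Design) -> dict:
    """Deviance inputs for DIC.

    Returns ``deviance_draws`` (-2 log-likelihood per posterior draw) and
    ``deviance_at_mean`` (the deviance at the posterior means of the
    parameters), the two ingredients of the Spiegelhalter pD.
    """
    y = design.y
    n = y.shape[0]
    mu = _mu_matrix(draws, design)
    t2 = draws.stacked("tau2")
    sq = ((y[None, :] - mu) ** 2).sum(axis=1)
    ll = -0.5 * (n * np.log(2 * np.pi * t2) + sq / t2)

    beta_bar = draws.stacked("beta").mean(axis=0)
    mu_bar = design.X @ beta_bar
    if design.hierarchical:
        mu_bar = mu_bar + draws.stacked("u").mean(axis=0)[design.country_idx]
    t2_bar = float(t2.mean())
    sq_bar = float(((y - mu_bar) ** 2).sum())
    ll_bar = -0.5 * (n * np.log(2 * np.pi * t2_bar) + sq_bar / t2_bar)
    return {"deviance_draws": -2.0 * ll, "deviance_at_mean": -2.0 * ll_bar}
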