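"""Synthetic multi-country coverage panels with known ground truth.

Emulates the structure of the stratified RMNCH coverage extracts that
national household surveys (DHS/MICS-style) provide: ~70 countries nested
in 9 regions, sparse survey years within 2000-2020 (a configurable fraction
of countries contributes a single data point), strata for residence
(national/urban/rural), wealth quintiles Q1-Q5 and maternal education, and
smooth country-level covariate trajectories (SDI, GGDPH, GDP per capita,
optionally DAH and HRH) extending to 2030.

Observations are generated from the same hierarchical model the package
fits: a latent logit-CCI surface built from the true parameters, plus
Normal noise on the logit scale at sampled survey years.  Because the truth
is known, parameter recovery, credible-interval calibration and projection
accuracy are all directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cci import INDICATORS, WEIGHTS, IndicatorSet, compute_cci
from .model import inv_logit

__all__ = [
    "ScenarioConfig",
    "TrueParameters",
    "SyntheticPanelBundle",
    "generate_hierarchy",
    "generate_covariates",
    "generate_panel",
    "generate_bundle",
    "derive_indicator_components",
]


@dataclass
class ScenarioConfig:
    """Dimensions and noise level of a synthetic study.

    Defaults mirror the study conditions the package is designed around:
    9 UN-style regions, 70 countries, surveys observed 2000-2020 with
    projections to 2030, 20/70 of countries contributing a single survey
    and the rest 3-8 surveys (~290 national data points), and residual
    logit-scale noise of 0.25.
    """

    n_regions: int = 9
    n_countries: int = 70
    countries_per_region: list[int] | None = None
    observed_year_range: tuple[int, int] = (2000, 2020)
    projection_year_range: tuple[int, int] = (2000, 2030)
    surveys_per_country: tuple[int, int] = (3, 8)
    single_survey_fraction: float = 20 / 70
    stratum_types: tuple[str, ...] = ("national", "residence")
    noise_sd_logit: float = 0.25
    extra_covariates: bool = False      # add dah and hrh columns
    collinear_extra: bool = False       # add a near-copy of gdpc (VIF testing)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.countries_per_region is not None:
            if any(c < 1 for c in self.countries_per_region):
                raise ValueError("countries_per_region entries must be >= 1")
            if len(self.countries_per_region) != self.n_regions:
                raise ValueError("countries_per_region length != n_regions")
            self.n_countries = sum(self.countries_per_region)
        if self.n_countries < self.n_regions:
            raise ValueError("need at least one country per region")
        o0, o1 = self.observed_year_range
        p0, p1 = self.projection_year_range
        if not (p0 <= o0 <= o1 <= p1):
            raise ValueError("observed range must lie inside projection range")
        lo, hi = self.surveys_per_country
        if not (1 <= lo <= hi):
            raise ValueError("surveys_per_country bounds must satisfy 1 <= min <= max")
        if hi > o1 - o0 + 1:
            raise ValueError("more surveys requested than observable years")
        if not (0.0 <= self.single_survey_fraction <= 1.0):
            raise ValueError("single_survey_fraction must be in [0, 1]")
        if self.noise_sd_logit <= 0:
            raise ValueError("noise_sd_logit must be positive")


_STRATUM_LEVELS = {
    "national": ["national"],
    "residence": ["urban", "rural"],
    "wealth": ["Q1", "Q2", "Q3", "Q4", "Q5"],
    "education": ["none", "primary", "secondary+"],
}


@dataclass
class TrueParameters:
    """Ground-truth generative parameters on the logit scale.

    Year enters per decade (centred at 2015); covariate slopes apply to the
    raw SDI/GGDPH and to log GDP per capita, matching the scale on which
    the model reports back-transformed coefficients.  Default wealth and
    education offsets are monotone non-decreasing; urban >= rural.

    The default intercept offsets the mean contribution of the covariate
    terms (SDI ~0.55, GGDPH ~3.5% of GDP, log GDPC ~8.4 at 2015) so that a
    typical country sits near 55-60% national CCI in 2015 with a wide
    cross-country spread — the landscape household surveys report, where
    the 80% target is within reach of some countries but not most.
    """

    global_intercept: float = -1.9
    region_intercept_sd: float = 0.4
    country_intercept_sd: float = 0.35
    beta_year: float = 0.45
    beta_residence: dict = field(default_factory=lambda: {
        "national": 0.0, "urban": 0.30, "rural": -0.35})
    beta_wealth: dict = field(default_factory=lambda: {
        "Q1": 0.0, "Q2": 0.25, "Q3": 0.50, "Q4": 0.75, "Q5": 1.05})
    beta_education: dict = field(default_factory=lambda: {
        "none": 0.0, "primary": 0.35, "secondary+": 0.80})
    beta_sdi: float = 1.5
    beta_ggdph: float = 0.04
    beta_gdpc: float = 0.15

    def __post_init__(self) -> None:
        for name in ("global_intercept", "beta_year", "beta_sdi",
                     "beta_ggdph", "beta_gdpc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("region_intercept_sd", "country_intercept_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a finite non-negative SD")

    def stratum_offset(self, stratum_type: str, level: str) -> float:
        if stratum_type == "national":
            return 0.0
        table = {"residence": self.beta_residence,
                 "wealth": self.beta_wealth,
                 "education": self.beta_education}.get(stratum_type)
        if table is None or level not in table:
            raise ValueError(f"truth has no offset for {stratum_type}/{level}")
        return float(table[level])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrueParameters":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticPanelBundle:
    panel: pd.DataFrame            # observed CCI rows (strict subset of grid)
    covariates: pd.DataFrame       # complete country x projection-year grid
    latent_surface: pd.DataFrame   # true CCI for every grid cell
    truth: TrueParameters
    hierarchy: pd.DataFrame
    config: ScenarioConfig
    country_effects: pd.DataFrame  # true u_j (and region v_k) draws

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.panel.to_csv(out / "panel.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.latent_surface.to_csv(out / "latent_surface.csv", index=False)
        self.truth.to_yaml(out / "truth.yaml")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_hierarchy(config: ScenarioConfig) -> pd.DataFrame:
    """Assign countries to regions; deterministic for a fixed config.

    Returns a frame with one row per country: ``country_id, region_id``.
    Counts come from ``countries_per_region`` when given, otherwise
    ``n_countries`` is split as evenly as possible across regions.
    """
    if config.countries_per_region is not None:
        counts = list(config.countries_per_region)
    else:
        base, extra = divmod(config.n_countries, config.n_regions)
        counts = [base + (1 if k < extra else 0) for k in range(config.n_regions)]
    rows = []
    j = 0
    for k, c in enumerate(counts):
        for _ in range(c):
            rows.append({"country_id": f"C{j + 1:03d}", "region_id": f"R{k + 1}"})
            j += 1
    return pd.DataFrame(rows)


def generate_covariates(hierarchy: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Country-year covariate trajectories over the projection range.

    SDI follows country-specific logistic growth (strictly increasing,
    inside (0,1)); GDP per capita grows log-linearly; GGDPH follows an
    AR(1) around a linear trend, clipped inside (0, 20) % of GDP.  With
    ``extra_covariates`` the table adds DAH (negatively coupled to SDI) and
    HRH (positively coupled); with ``collinear_extra`` it adds
    ``gdpc_copy``, a near-duplicate of GDPC for multicollinearity tests.
    """
    if len(hierarchy) == 0:
        raise ValueError("empty hierarchy")
    rng = _rng(config.seed, 1)
    y0, y1 = config.projection_year_range
    years = np.arange(y0, y1 + 1)
    frames = []
    for cid in hierarchy["country_id"]:
        L = rng.uniform(0.55, 0.95)
        r = rng.uniform(0.03, 0.10)
        t0 = rng.uniform(1990.0, 2015.0)
        sdi = L / (1.0 + np.exp(-r * (years - t0)))

        a = rng.uniform(6.5, 9.5)
        g = rng.uniform(0.005, 0.05)
        gdpc = np.exp(a + g * (years - y0))

        base = rng.uniform(1.0, 6.0)
        slope = rng.uniform(-0.02, 0.06)
        eps = rng.normal(0.0, 0.15, size=len(years))
        ar = np.zeros(len(years))
        for t in range(1, len(years)):
            ar[t] = 0.8 * ar[t - 1] + eps[t]
        ggdph = np.clip(base + slope * (years - y0) + ar, 0.2, 19.8)

        df = pd.DataFrame({"country_id": cid, "year": years,
                           "sdi": sdi, "ggdph": ggdph, "gdpc": gdpc})
        if config.extra_covariates:
            # dah and hrh share a country-level aid/health-system factor
            # independent of sdi, making them a strongly collinear pair —
            # the textbook case the iterative VIF screen resolves
            dah = np.clip(rng.uniform(2.0, 10.0)
                          + rng.uniform(-0.05, 0.15) * (years - y0)
                          + rng.normal(0, 0.5, len(years)), 0.0, None)
            df["dah"] = dah
            df["hrh"] = np.clip(4.0 + 2.0 * dah
                                + rng.normal(0, 0.7, len(years)), 1.0, None)
        if config.collinear_extra:
            # near-duplicate of gdpc (r > 0.99).  The faint sdi coupling
            # makes the copy's auxiliary R^2 strictly the larger of the
            # pair, so the screen removes the copy, not the real series
            df["gdpc_copy"] = gdpc * (1.0 + rng.normal(0, 1e-2, len(years))
                                      + 0.05 * (sdi - 0.5))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _latent_logit(truth: TrueParameters, u_j: float, year: np.ndarray,
                  sdi, ggdph, gdpc, offset: float) -> np.ndarray:
    return (truth.global_intercept + u_j
            + truth.beta_year * (np.asarray(year, float) - 2015.0) / 10.0
            + offset
            + truth.beta_sdi * np.asarray(sdi, float)
            + truth.beta_ggdph * np.asarray(ggdph, float)
            + truth.beta_gdpc * np.log(np.asarray(gdpc, float)))


def generate_panel(hierarchy: pd.DataFrame, covariates: pd.DataFrame,
                   truth: TrueParameters, config: ScenarioConfig) -> SyntheticPanelBundle:
    """Sample survey observations from the latent CCI surface.

    Steps: draw region effects v_k ~ N(0, region_sd) and country effects
    u_j ~ N(v_k, country_sd); build the latent logit-CCI grid for every
    country x projection-year x stratum cell; pick survey years per country
    (a ``single_survey_fraction`` of countries is forced to exactly one
    survey, the rest draw a uniform count within ``surveys_per_country``,
    years sampled without replacement from the observed range); observe
    CCI = inv_logit(latent + Normal(0, noise_sd_logit)) at those cells.
    """
    for st in config.stratum_types:
        if st == "national":
            continue
        for lvl in _STRATUM_LEVELS[st]:
            truth.stratum_offset(st, lvl)  # raises if truth lacks the level

    rng = _rng(config.seed, 2)
    countries = hierarchy["country_id"].tolist()
    regions = hierarchy["region_id"].tolist()
    uniq_regions = sorted(set(regions))
    v = {r: rng.normal(0.0, truth.region_intercept_sd) for r in uniq_regions}
    u = {c: rng.normal(v[r], truth.country_intercept_sd)
         for c, r in zip(countries, regions)}

    cov = covariates.set_index(["country_id", "year"]).sort_index()
    y0, y1 = config.projection_year_range
    grid_years = np.arange(y0, y1 + 1)

    latent_rows = []
    for c, r in zip(countries, regions):
        block = cov.loc[c].loc[grid_years]
        for st in config.stratum_types:
            for lvl in _STRATUM_LEVELS[st]:
                lin = _latent_logit(truth, u[c], grid_years, block["sdi"],
                                    block["ggdph"], block["gdpc"],
                                    truth.stratum_offset(st, lvl))
                latent_rows.append(pd.DataFrame({
                    "country_id": c, "region_id": r, "year": grid_years,
                    "stratum_type": st, "stratum_level": lvl,
                    "cci_true": inv_logit(lin)}))
    latent = pd.concat(latent_rows, ignore_index=True)

    # survey schedule
    o0, o1 = config.observed_year_range
    obs_years = np.arange(o0, o1 + 1)
    n_single = int(round(config.single_survey_fraction * len(countries)))
    single_set = set(rng.permutation(countries)[:n_single])
    lo, hi = config.surveys_per_country
    schedule = {}
    for c in countries:
        k = 1 if c in single_set else int(rng.integers(lo, hi + 1))
        schedule[c] = np.sort(rng.choice(obs_years, size=k, replace=False))

    lat_idx = latent.set_index(
        ["country_id", "year", "stratum_type", "stratum_level"])["cci_true"]
    rows = []
    for c, r in zip(countries, regions):
        for yr in schedule[c]:
            for st in config.stratum_types:
                for lvl in _STRATUM_LEVELS[st]:
                    true_cci = lat_idx.loc[(c, yr, st, lvl)]
                    lin = np.log(true_cci / (1.0 - true_cci))
                    obs = inv_logit(lin + rng.normal(0.0, config.noise_sd_logit))
                    rows.append({"country_id": c, "region_id": r, "year": int(yr),
                                 "stratum_type": st, "stratum_level": lvl,
                                 "cci": float(obs)})
    panel = pd.DataFrame(rows)

    eff = pd.DataFrame({"country_id": countries,
                        "region_id": regions,
                        "u_true": [u[c] for c in countries],
                        "v_true": [v[r] for r in regions]})
    return SyntheticPanelBundle(panel=panel, covariates=covariates,
                                latent_surface=latent, truth=truth,
                                hierarchy=hierarchy, config=config,
                                country_effects=eff)


def generate_bundle(config: ScenarioConfig | None = None,
                    truth: TrueParameters | None = None) -> SyntheticPanelBundle:
    """One-call generator: hierarchy -> covariates -> panel."""
    config = config or ScenarioConfig()
    truth = truth or TrueParameters()
    hierarchy = generate_hierarchy(config)
    covariates = generate_covariates(hierarchy, config)
    return generate_panel(hierarchy, covariates, truth, config)


def derive_indicator_components(target_cci: float, seed: int = 0) -> IndicatorSet:
    """Invent eight indicator proportions whose weighted CCI equals a target.

    Draws a random point in [0,1]^8 and moves it along the line toward the
    all-zero or all-one corner until the weighted average hits the target;
    both moves preserve the unit box, so any target in [0,1] is feasible.
    The round trip through :func:`ccitrend.cci.compute_cci` recovers the
    target to ~1e-12.
    """
    t = float(target_cci)
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"target CCI must be in [0, 1], got {t}")
    rng = np.random.default_rng(seed)
    w = np.array([WEIGHTS[k] for k in INDICATORS])
    v = rng.uniform(0.0, 1.0, size=8)
    c = float(w @ v)
    if c > t:
        x = v * (t / c if c > 0 else 0.0)
    elif c < t:
        lam = (t - c) / (1.0 - c)
        x = v + (1.0 - v) * lam
    else:
        x = v
    ind = IndicatorSet(**dict(zip(INDICATORS, np.clip(x, 0.0, 1.0))))
    assert abs(compute_cci(ind) - t) < 1e-9
    return ind
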