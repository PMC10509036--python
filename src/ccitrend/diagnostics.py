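"""Model-building and checking machinery.

Covers the four checks used to select and validate the hierarchical model:
variance-inflation-factor (VIF) screening of candidate covariates, the
deviance information criterion (DIC), posterior predictive checks (PPC),
Gelman–Rubin convergence (PSRF), and the gamma vs half-Cauchy hyperprior
sensitivity comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Design, PosteriorDraws, _mu_matrix, inv_logit

__all__ = [
    "VifReport",
    "FitDiagnostics",
    "vif_screen",
    "compute_dic",
    "posterior_predictive_check",
    "psrf",
    "prior_sensitivity",
]


@dataclass
class VifReport:
    """Round-by-round record of the iterative VIF elimination."""

    rounds: list[dict] = field(default_factory=list)  # [{cov: vif, ...}, ...]
    eliminated: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    threshold: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rnd in enumerate(self.rounds, start=1):
            for cov, vif in rnd.items():
                rows.append({"round": i, "covariate": cov, "vif": vif,
                             "eliminated": (len(self.eliminated) >= i
                                            and self.eliminated[i - 1] == cov)})
        return pd.DataFrame(rows)


@dataclass
class FitDiagnostics:
    dic: float
    pD: float
    ppc_pvalue: float
    psrf: dict[str, float]
    sensitivity_mad: dict[str, float] | None = None

    def flags(self, psrf_threshold: float = 1.1,
              ppc_band: tuple[float, float] = (0.05, 0.95)) -> list[str]:
        out = []
        bad = [k for k, v in self.psrf.items()
               if np.isfinite(v) and v > psrf_threshold]
        if bad:
            out.append(f"PSRF>{psrf_threshold}: {bad}")
        if not (ppc_band[0] <= self.ppc_pvalue <= ppc_band[1]):
            out.append(f"PPC p-value {self.ppc_pvalue:.3f} outside {ppc_band}")
        return out


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R²) from the auxiliary regression of x_j on the
    other columns plus an intercept."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return np.inf
    r2 = 1.0 - float(resid @ resid) / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(covariates: pd.DataFrame, candidates: list[str] | None = None,
               threshold: float = 5.0) -> VifReport:
    """Iteratively drop the covariate with the highest VIF while any VIF
    exceeds ``threshold`` (default 5).

    Ties break alphabetically; a perfectly collinear covariate has infinite
    VIF and is removed first.  Every round's VIF values are recorded.
    """
    if candidates is None:
        candidates = [c for c in covariates.columns
                      if c not in ("country_id", "region_id", "year")]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate covariates")
    if len(covariates) < 3:
        raise ValueError("need at least 3 rows")

    current = sorted(candidates)
    report = VifReport(threshold=threshold)
    while len(current) >= 2:
        X = covariates.loc[:, current].to_numpy(dtype=float)
        vifs = {c: _vif_one(X, i) for i, c in enumerate(current)}
        report.rounds.append(vifs)
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # alphabetical tie-break among covariates sharing the worst VIF
        drop = sorted(c for c in current if vifs[c] == worst)[0]
        report.eliminated.append(drop)
        current = [c for c in current if c != drop]
    report.retained = current
    return report


def compute_dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> dict:
    """Spiegelhalter DIC: pD = mean(D) - D(posterior mean); DIC = mean(D) + pD."""
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 100:
        raise ValueError("need at least 100 posterior draws for DIC")
    if not (np.all(np.isfinite(d)) and np.isfinite(deviance_at_mean)):
        raise ValueError("non-finite deviance")
    dbar = float(d.mean())
    pD = dbar - float(deviance_at_mean)
    return {"dic": dbar + pD, "pD": pD}


_PPC_STATS = {
    "mean": lambda p: float(np.mean(p)),
    "sd": lambda p: float(np.std(p, ddof=1)),
}


def posterior_predictive_check(draws: PosteriorDraws, design: Design,
                               statistic: str = "mean",
                               quantile: float | None = None,
                               rng: np.random.Generator | None = None,
                               shift_logit: float = 0.0) -> float:
    """Bayesian p-value comparing replicated to observed CCI proportions.

    For every posterior draw, a replicate panel is simulated from the fitted
    model (linear predictor + Normal(0, tau) noise on the logit scale, then
    inverse-logit); the discrepancy statistic (default: mean of the CCI
    proportions) is computed on the replicate and on the observed data, and

        p = Pr(T(y_rep) >= T(y_obs)),   ties counted as 1/2.

    Values near 0.5 indicate no evidence of misfit; values near 0 or 1
    indicate the model cannot reproduce the observed statistic.
    ``shift_logit`` adds a constant to replicate linear predictors (used to
    demonstrate the direction of the check on misspecified replicates).
    """
    if quantile is not None:
        stat = lambda p: float(np.quantile(p, quantile))  # noqa: E731
    else:
        if statistic not in _PPC_STATS:
            raise ValueError(f"unknown statistic {statistic!r}")
        stat = _PPC_STATS[statistic]
    if rng is None:
        seed = draws.spec.mcmc.seed if draws.spec.mcmc.seed is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7717]))

    mu = _mu_matrix(draws, design) + shift_logit
    tau = np.sqrt(draws.stacked("tau2"))[:, None]
    y_rep = mu + tau * rng.standard_normal(mu.shape)
    obs = stat(design.obs_cci)
    rep_stats = np.array([stat(inv_logit(row)) for row in y_rep])
    greater = float(np.mean(rep_stats > obs))
    ties = float(np.mean(rep_stats == obs))
    return greater + 0.5 * ties


def psrf(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor (classic, non-split).

    ``chains`` is (m, n): m >= 2 chains of equal length n >= 10.  With
    within-chain variance W and between-chain variance B = n * Var(chain
    means), the statistic is sqrt(((n-1)/n * W + B/n) / W).  Values near 1
    indicate convergence; all chains constant and equal yields NaN with a
    warning (no variance to compare).
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    m, n = a.shape
    if n < 10:
        raise ValueError("need chain length >= 10")
    W = float(np.mean(np.var(a, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(a, axis=1), ddof=1))
    if W == 0.0:
        warnings.warn("zero within-chain variance; PSRF undefined",
                      RuntimeWarning, stacklevel=2)
        return np.nan
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def split_psrf(chains: np.ndarray) -> float:
    """PSRF after splitting each chain in half (detects within-chain drift)."""
    a = np.asarray(chains, dtype=float)
    m, n = a.shape
    h = n // 2
    return psrf(np.vstack([a[:, :h], a[:, h:2 * h]]))


def prior_sensitivity(fit_gamma: PosteriorDraws, fit_halfcauchy: PosteriorDraws,
                      threshold_sd_ratio: float = 0.5) -> dict:
    """Median-absolute-difference comparison of the two hyperprior families.

    For every scalar parameter, reports |median_gamma - median_halfcauchy|;
    fixed effects additionally get the ratio of that difference to the
    (gamma-fit) posterior SD.  ``flag`` is set when any fixed-effect ratio
    exceeds ``threshold_sd_ratio``.
    """
    pg = fit_gamma.parameter_chains()
    ph = fit_halfcauchy.parameter_chains()
    if set(pg) != set(ph):
        raise ValueError("parameter sets differ between the two fits")
    mad: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for name in pg:
        a, b = pg[name].ravel(), ph[name].ravel()
        mad[name] = float(abs(np.median(a) - np.median(b)))
        sd = float(np.std(a, ddof=1))
        ratio[name] = mad[name] / sd if sd > 0 else np.inf
    fixed = fit_gamma.fixed_effect_names()
    flag = any(ratio[n] > threshold_sd_ratio for n in fixed)
    return {"mad": mad, "mad_sd_ratio": ratio, "flag": flag,
            "fixed_effects": fixed}
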