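"""Shared study definition for the numbered analysis scripts.

One synthetic multi-country study at the full dimensions (9 regions, 70
countries, ~290 national survey points, residence strata observed
2000-2020, covariates through 2030), regenerated deterministically from a
fixed seed so every script is self-contained and reproducible.
"""

from pathlib import Path

from ccitrend.model import MCMCSpec, ModelSpec, build_design, fit
from ccitrend.synthetic import ScenarioConfig, TrueParameters, generate_bundle

STUDY_SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_bundle(stratum_types=("national", "residence"), **overrides):
    cfg = ScenarioConfig(stratum_types=stratum_types, seed=STUDY_SEED,
                         **overrides)
    return generate_bundle(cfg, TrueParameters())


def fit_study(bundle, variant="residence", prior_family="gamma",
              covariates=("sdi", "ggdph", "gdpc"), seed=STUDY_SEED):
    spec = ModelSpec(variant=variant, prior_family=prior_family,
                     covariates=tuple(covariates),
                     mcmc=MCMCSpec(chains=4, iterations=2500, burn_in=1250,
                                   seed=seed))
    design = build_design(bundle.panel, bundle.covariates, spec)
    return fit(design, spec)
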