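"""Shared fixtures: synthetic bundles and fitted models reused across tests.

The parameter-recovery experiment (20 independently seeded bundles at the
study's reduced dimensions, each fitted with 4 chains) is expensive enough
to share session-wide; calibration, convergence, predictive-check and
prior-sensitivity tests all read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccitrend.model import MCMCSpec, ModelSpec, build_design, fit
from ccitrend.synthetic import ScenarioConfig, TrueParameters, generate_bundle

RECOVERY_N_BUNDLES = 20


def recovery_scenario(seed: int) -> ScenarioConfig:
    """9 regions x 36 countries, ~190 residence-stratified observations,
    with the usual fraction of single-survey countries."""
    return ScenarioConfig(n_regions=9, n_countries=36,
                          surveys_per_country=(1, 3),
                          single_survey_fraction=20 / 70, seed=seed)


@pytest.fixture(scope="session")
def recovery_truth() -> TrueParameters:
    return TrueParameters()


@pytest.fixture(scope="session")
def recovery_fits(recovery_truth):
    """20 (bundle, posterior) pairs from independently seeded replicates."""
    out = []
    for rep in range(RECOVERY_N_BUNDLES):
        bundle = generate_bundle(recovery_scenario(1000 + rep), recovery_truth)
        spec = ModelSpec(mcmc=MCMCSpec(chains=4, iterations=2000,
                                       burn_in=1000, seed=rep))
        design = build_design(bundle.panel, bundle.covariates, spec)
        out.append((bundle, fit(design, spec)))
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """3 regions x 9 countries; quick end-to-end material."""
    cfg = ScenarioConfig(n_regions=3, n_countries=9,
                         surveys_per_country=(3, 6),
                         single_survey_fraction=0.2, seed=7)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_fit(small_bundle):
    spec = ModelSpec(mcmc=MCMCSpec(chains=2, iterations=1500,
                                   burn_in=500, seed=11))
    design = build_design(small_bundle.panel, small_bundle.covariates, spec)
    return fit(design, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
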