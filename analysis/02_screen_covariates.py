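"""Covariate selection: multicollinearity screen, then DIC comparison.

Stage 1 screens the candidate country-level predictors (SDI, DAH, HRH,
GGDPH, GDPC, plus a deliberately near-duplicate GDPC series) by iterative
VIF elimination at the usual threshold of 5; the DAH/HRH pair shares an
aid/health-system factor, so one of the two goes.  Stage 2 compares
nested models on the survivors with DIC: the remaining aid covariate has
no generative effect and should not lower DIC, leaving SDI, GGDPH and
GDPC as the working covariate set.
"""

from _study import RESULTS, fit_study, study_bundle
from ccitrend.diagnostics import compute_dic, vif_screen
from ccitrend.model import log_density_per_obs


def dic_of(bundle, covariates):
    draws = fit_study(bundle, covariates=covariates)
    dev = log_density_per_obs(draws, draws.design)
    return compute_dic(dev["deviance_draws"], dev["deviance_at_mean"])["dic"]


def main() -> None:
    bundle = study_bundle(extra_covariates=True, collinear_extra=True)
    candidates = ["sdi", "dah", "hrh", "ggdph", "gdpc", "gdpc_copy"]
    report = vif_screen(bundle.covariates, candidates, threshold=5.0)

    RESULTS.mkdir(exist_ok=True)
    report.to_frame().to_csv(RESULTS / "vif_rounds.csv", index=False)
    for i, rnd in enumerate(report.rounds, start=1):
        print(f"round {i}: " + ", ".join(f"{c}={v:.2f}" for c, v in rnd.items()))
        if i <= len(report.eliminated):
            print(f"  -> eliminated {report.eliminated[i - 1]} (VIF > 5)")
    print(f"VIF survivors: {report.retained}")

    extras = [c for c in report.retained if c in ("dah", "hrh")]
    base = [c for c in report.retained if c not in extras]
    final = list(report.retained)
    if extras:
        dic_with = dic_of(bundle, tuple(report.retained))
        dic_without = dic_of(bundle, tuple(base))
        print(f"\nDIC with {extras}: {dic_with:.1f}; "
              f"without: {dic_without:.1f}")
        final = report.retained if dic_with < dic_without else base
    print(f"final covariate set: {sorted(final)}")
    print(f"rounds table -> {RESULTS / 'vif_rounds.csv'}")


if __name__ == "__main__":
    main()
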