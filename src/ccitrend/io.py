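"""Readers and writers for the pipeline's CSV dialects.

Two panel dialects are accepted:

* ``equity`` — the long format of WHO Health Equity Monitor / DHS
  STATcompiler style extracts, columns
  ``iso3, region, year, stratifier, level, value, scale`` where ``scale``
  is ``proportion`` or ``percent``;
* ``canonical`` — the package's own columns
  ``country_id, region_id, year, stratum_type, stratum_level, cci``
  (proportion scale).

Validation is itemised: every offending row is reported, not just the
first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PanelValidationError", "read_panel", "read_covariates", "write_panel"]

_STRATIFIERS = {
    "national": {"national"},
    "residence": {"urban", "rural"},
    "wealth": {"Q1", "Q2", "Q3", "Q4", "Q5"},
    "education": {"none", "primary", "secondary+"},
}

_EQUITY_COLS = ["iso3", "region", "year", "stratifier", "level", "value", "scale"]
_CANONICAL_COLS = ["country_id", "region_id", "year", "stratum_type",
                   "stratum_level", "cci"]


class PanelValidationError(ValueError):
    """Raised with the full list of row-level problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        msg = f"{len(problems)} validation problem(s):\n" + "\n".join(problems[:50])
        super().__init__(msg)


def read_panel(path, dialect: str = "equity") -> pd.DataFrame:
    """Load and validate a coverage panel; returns canonical columns.

    Values are normalised to the proportion scale (a ``percent`` scale flag
    divides by 100).  Duplicate (country, year, stratifier, level) rows,
    unknown stratifier labels and out-of-range values are all rejected with
    an itemised report.
    """
    df = pd.read_csv(path)
    if dialect == "equity":
        missing = [c for c in _EQUITY_COLS if c not in df.columns]
        if missing:
            raise PanelValidationError([f"missing columns: {missing}"])
        df = df.rename(columns={"iso3": "country_id", "region": "region_id",
                                "stratifier": "stratum_type",
                                "level": "stratum_level"})
    elif dialect == "canonical":
        missing = [c for c in _CANONICAL_COLS if c not in df.columns]
        if missing:
            raise PanelValidationError([f"missing columns: {missing}"])
        df = df.copy()
        df["value"] = df["cci"]
        df["scale"] = "proportion"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    problems: list[str] = []
    scale_ok = df["scale"].isin(["proportion", "percent"])
    for i in df.index[~scale_ok]:
        problems.append(f"row {i}: unknown scale {df.at[i, 'scale']!r}")

    value = pd.to_numeric(df["value"], errors="coerce")
    prop = np.where(df["scale"].eq("percent"), value / 100.0, value)
    df["cci"] = prop

    for i in df.index:
        st, lvl = df.at[i, "stratum_type"], df.at[i, "stratum_level"]
        if st not in _STRATIFIERS:
            problems.append(f"row {i}: unknown stratifier {st!r}")
        elif lvl not in _STRATIFIERS[st]:
            problems.append(f"row {i}: unknown level {lvl!r} for stratifier {st!r}")
        v = df.at[i, "cci"]
        if not np.isfinite(v) or not (0.0 <= v <= 1.0):
            problems.append(
                f"row {i}: value {df.at[i, 'value']!r} ({df.at[i, 'scale']}) "
                "outside the unit interval after normalisation")

    key = ["country_id", "year", "stratum_type", "stratum_level"]
    dup = df.duplicated(subset=key, keep=False)
    for i in df.index[dup & ~df.duplicated(subset=key, keep="first")]:
        problems.append(f"row {i}: duplicate of an earlier "
                        f"(country, year, stratifier, level) row")

    region_counts = df.groupby("country_id")["region_id"].nunique()
    for c in region_counts.index[region_counts > 1]:
        problems.append(f"country {c!r} maps to multiple regions")

    if problems:
        raise PanelValidationError(problems)
    return df.loc[:, _CANONICAL_COLS].reset_index(drop=True)


def read_covariates(path, required=("sdi", "ggdph", "gdpc")) -> pd.DataFrame:
    """Country-year covariate table; checks presence and basic ranges."""
    df = pd.read_csv(path)
    problems = []
    for c in ("country_id", "year"):
        if c not in df.columns:
            problems.append(f"missing column {c!r}")
    for c in required:
        if c not in df.columns:
            problems.append(f"missing covariate column {c!r}")
    if problems:
        raise PanelValidationError(problems)
    if "sdi" in df.columns:
        bad = ~df["sdi"].between(0, 1)
        for i in df.index[bad]:
            problems.append(f"row {i}: sdi outside (0, 1)")
    if "gdpc" in df.columns:
        for i in df.index[df["gdpc"] <= 0]:
            problems.append(f"row {i}: non-positive gdpc")
    if problems:
        raise PanelValidationError(problems)
    return df


def write_panel(panel: pd.DataFrame, path, dialect: str = "equity") -> None:
    if dialect == "equity":
        out = panel.rename(columns={
            "country_id": "iso3", "region_id": "region",
            "stratum_type": "stratifier", "stratum_level": "level"})
        out["value"] = panel["cci"]
        out["scale"] = "proportion"
        out = out.loc[:, _EQUITY_COLS]
    elif dialect == "canonical":
        out = panel.loc[:, _CANONICAL_COLS]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, index=False)
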