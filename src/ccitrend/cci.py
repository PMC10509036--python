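"""Composite coverage index (CCI) for RMNCH interventions.

The CCI is the Countdown-to-2030 summary of reproductive, maternal, newborn
and child health service coverage: a weighted average of eight intervention
coverage proportions organised in four equally weighted domains,

    CCI = 1/4 * [ DFPSm  +  (ANC4 + SBA)/2  +  (BCG + 2*DPT3 + MSL)/4
                  +  (ORS + CAREP)/2 ]

with DPT3 double-weighted inside the immunisation domain.  Domains:
family planning (DFPSm — demand for family planning satisfied with modern
methods), maternal and newborn care (ANC4 — four or more antenatal visits,
SBA — skilled birth attendance), immunisation (BCG, DPT3, MSL — measles),
and case management of childhood illness (ORS — oral rehydration salts,
CAREP — care-seeking for suspected pneumonia).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "WEIGHTS",
    "IndicatorSet",
    "compute_cci",
    "batch_cci",
    "read_indicator_csv",
    "write_indicator_csv",
]

#: canonical indicator order
INDICATORS = ("dfpsm", "anc4", "sba", "bcg", "dpt3", "msl", "ors", "carep")

#: per-indicator weights implied by the four equally weighted domains
WEIGHTS = {
    "dfpsm": 1 / 4,
    "anc4": 1 / 8,
    "sba": 1 / 8,
    "bcg": 1 / 16,
    "dpt3": 1 / 8,
    "msl": 1 / 16,
    "ors": 1 / 8,
    "carep": 1 / 8,
}


@dataclass(frozen=True)
class IndicatorSet:
    """Coverage proportions for the eight RMNCH indicators of one stratum.

    All values are proportions in [0, 1].  Use ``percent=True`` on the
    constructor helpers if your source is on the 0–100 scale; values are
    never rescaled silently.
    """

    dfpsm: float
    anc4: float
    sba: float
    bcg: float
    dpt3: float
    msl: float
    ors: float
    carep: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"indicator {f.name!r} is not finite: {v!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"indicator {f.name!r} must be a proportion in [0, 1], got {v}"
                )

    @classmethod
    def from_mapping(cls, values, *, percent: bool = False) -> "IndicatorSet":
        missing = [k for k in INDICATORS if k not in values]
        if missing:
            raise ValueError(f"missing indicators: {missing}")
        scale = 100.0 if percent else 1.0
        return cls(**{k: float(values[k]) / scale for k in INDICATORS})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in INDICATORS], dtype=float)


def compute_cci(ind: IndicatorSet) -> float:
    """Weighted-average CCI of one indicator set, as a proportion in [0, 1]."""
    fp = ind.dfpsm
    matcare = (ind.anc4 + ind.sba) / 2.0
    immun = (ind.bcg + 2.0 * ind.dpt3 + ind.msl) / 4.0
    casemgmt = (ind.ors + ind.carep) / 2.0
    return (fp + matcare + immun + casemgmt) / 4.0


def batch_cci(table: pd.DataFrame, *, percent: bool = False) -> pd.DataFrame:
    """Append a ``cci`` column computed row-wise from the eight indicator columns.

    Parameters
    ----------
    table
        One row per stratum with columns named as in :data:`INDICATORS`.
    percent
        If True, indicator columns are on the 0–100 scale and the returned
        ``cci`` column is too.

    Raises
    ------
    ValueError
        If a column is missing or any row has a value outside range; the
        error names the offending row label.
    """
    missing = [k for k in INDICATORS if k not in table.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    out = table.copy()
    if len(table) == 0:
        out["cci"] = pd.Series(dtype=float)
        return out
    vals = table.loc[:, list(INDICATORS)].to_numpy(dtype=float)
    if percent:
        vals = vals / 100.0
    bad = ~np.isfinite(vals) | (vals < 0.0) | (vals > 1.0)
    if bad.any():
        row = table.index[np.where(bad.any(axis=1))[0][0]]
        raise ValueError(f"invalid indicator value(s) in row {row!r}")
    w = np.array([WEIGHTS[k] for k in INDICATORS])
    cci = vals @ w
    out["cci"] = cci * (100.0 if percent else 1.0)
    return out


def read_indicator_csv(path, *, percent: bool = False) -> pd.DataFrame:
    """Read an indicator table (canonical column names) and append CCI."""
    return batch_cci(pd.read_csv(path), percent=percent)


def write_indicator_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
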