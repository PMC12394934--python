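"""Between-condition distribution comparisons.

Two-sided Mann-Whitney U and two-sample Kolmogorov-Smirnov tests over
per-peptide properties (length, pI, GRAVY, net charge). The U test uses
exact enumeration p-values for small tie-free samples (n_A + n_B <= 16)
and the tie-corrected normal approximation otherwise; the method actually
used is recorded on each result so reported p-values are reproducible.
No multiplicity correction is applied by default (raw per-property
p-values); a Bonferroni flag exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PeptidePopulation
from .physchem import EMBOSS_PKA, KYTE_DOOLITTLE, HydropathyScale, PkaSet, properties_table

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "ks_two_sample",
    "compare_all_properties",
    "EXACT_MAX_TOTAL_N",
    "PROPERTY_COLUMNS",
]

#: Largest n_A + n_B for which the tie-free exact MWU p-value is used.
EXACT_MAX_TOTAL_N = 16

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-sample test on one property."""

    property_name: str
    test: str  # "mann_whitney_u" | "kolmogorov_smirnov"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str = ""  # "exact" | "asymptotic"

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample {name}")
    return arr


def mann_whitney_u(x, y, property_name: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U with midrank tie handling.

    Exact p by enumeration for tie-free samples with n_A + n_B <= 16,
    otherwise the normal approximation with tie correction (and no
    continuity correction, so identical samples give p = 1 exactly).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    no_ties = len(np.unique(np.concatenate([xa, ya]))) == xa.size + ya.size
    if no_ties and xa.size + ya.size <= EXACT_MAX_TOTAL_N:
        method = "exact"
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance degenerate case (all values tied)
        p = 1.0
    return GroupComparison(property_name, "mann_whitney_u",
                           float(res.statistic), min(p, 1.0),
                           xa.size, ya.size, method)


def ks_two_sample(x, y, property_name: str = "") -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y| with the
    asymptotic two-sided p-value."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    res = sps.ks_2samp(xa, ya, alternative="two-sided", method="asymp")
    return GroupComparison(property_name, "kolmogorov_smirnov",
                           float(res.statistic), float(min(res.pvalue, 1.0)),
                           xa.size, ya.size, "asymptotic")


PROPERTY_COLUMNS = {"length": "length", "pi": "pI", "gravy": "gravy",
                    "net_charge": "net_charge"}


def compare_all_properties(
    pop_a: PeptidePopulation,
    pop_b: PeptidePopulation,
    properties: Sequence[str] = ("length", "pi", "gravy", "net_charge"),
    scale: HydropathyScale = KYTE_DOOLITTLE,
    pka: PkaSet = EMBOSS_PKA,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run both tests for each requested property of two populations.

    Returns a tidy frame with one row per property x test, flagged for
    significance at alpha = 0.05 (Bonferroni-adjusted across rows only if
    requested; off by default, matching raw per-property reporting).
    """
    bad = [p for p in properties if p not in PROPERTY_COLUMNS]
    if bad:
        raise ValueError(f"unknown properties {bad}; known: {sorted(PROPERTY_COLUMNS)}")
    ta = properties_table(pop_a, scale, pka)
    tb = properties_table(pop_b, scale, pka)
    rows = []
    for prop in properties:
        col = PROPERTY_COLUMNS[prop]
        for fn in (mann_whitney_u, ks_two_sample):
            r = fn(ta[col].to_numpy(), tb[col].to_numpy(), property_name=prop)
            rows.append({
                "property": prop, "test": r.test, "statistic": r.statistic,
                "p_value": r.p_value, "n_a": r.n_a, "n_b": r.n_b,
                "method": r.method,
            })
    df = pd.DataFrame(rows)
    m = len(df) if bonferroni else 1
    df["significant"] = (df["p_value"] * m).clip(upper=1.0) < ALPHA
    return df
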