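"""Per-peptide physicochemical properties.

GRAVY (grand average of hydropathy) is the arithmetic mean of per-residue
Kyte-Doolittle hydropathy values. Net charge at a given pH follows the
Henderson-Hasselbalch summation over the two termini and the ionisable
side chains (D, E, C, Y negative; H, K, R positive); the isoelectric point
is the unique pH at which that sum vanishes, found by bisection (the sum
is strictly decreasing in pH). Monoisotopic mass is the residue-mass sum
plus one water, computed through pyteomics.

The default pKa values are the EMBOSS set. The source publication of the
peptide populations this package analyses does not state which set it
used, so the set is an explicit, configurable parameter recorded in output
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import pandas as pd
from pyteomics import mass as _ptmass

from .core import _AA_SET, AMINO_ACIDS, Peptide, PeptidePopulation, require_nonempty

__all__ = [
    "HydropathyScale",
    "KYTE_DOOLITTLE",
    "PkaSet",
    "EMBOSS_PKA",
    "PropertyRecord",
    "gravy",
    "gravy_rounded",
    "net_charge",
    "isoelectric_point",
    "mono_mass",
    "round_half_away",
    "properties_table",
]


@dataclass(frozen=True)
class HydropathyScale:
    """A residue -> hydropathy mapping; all 20 residues must be present."""

    values: Mapping[str, float]
    name: str = "Kyte-Doolittle 1982"

    def __post_init__(self) -> None:
        missing = _AA_SET - set(self.values)
        if missing:
            raise ValueError(f"hydropathy scale {self.name!r} missing {sorted(missing)}")


#: Kyte & Doolittle (1982) hydropathy values; positive = hydrophobic.
KYTE_DOOLITTLE = HydropathyScale({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "V": 4.2, "Y": -1.3,
})


@dataclass(frozen=True)
class PkaSet:
    """Ionisation constants for the termini and ionisable side chains."""

    n_term: float
    c_term: float
    side_chains: Mapping[str, float]  # keys among D, E, C, Y, H, K, R
    name: str = "custom"

    def __post_init__(self) -> None:
        for label, v in [("n_term", self.n_term), ("c_term", self.c_term),
                         *self.side_chains.items()]:
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa {label}={v} outside (0, 14)")


#: EMBOSS (iep) pKa values.
EMBOSS_PKA = PkaSet(
    n_term=8.6, c_term=3.6,
    side_chains={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                 "H": 6.5, "K": 10.8, "R": 12.5},
    name="EMBOSS",
)

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted(set(sequence) - _AA_SET)
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad!r} in {sequence!r}")


def gravy(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Mean per-residue hydropathy of the sequence (full precision)."""
    _check_sequence(sequence)
    return sum(scale.values[aa] for aa in sequence) / len(sequence)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table-display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gravy_rounded(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE,
                  ndigits: int = 2) -> float:
    """GRAVY rounded half-away-from-zero, computed in exact decimal
    arithmetic so 2-decimal table values are independent of binary
    round-off (Kyte-Doolittle values carry one decimal place)."""
    _check_sequence(sequence)
    total = sum(Decimal(repr(scale.values[aa])) for aa in sequence)
    q = Decimal(1).scaleb(-ndigits)
    return float((total / len(sequence)).quantize(q, rounding=ROUND_HALF_UP))


def net_charge(sequence: str, pH: float = 7.0, pka: PkaSet = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of the free peptide at ``pH``.

    Positive sites (N-terminus, H, K, R) each contribute
    ``+1 / (1 + 10**(pH - pKa))``; negative sites (C-terminus, D, E, C, Y)
    each contribute ``-1 / (1 + 10**(pKa - pH))``.
    """
    _check_sequence(sequence)
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH {pH} outside (0, 14)")
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in sequence:
        if aa in _POSITIVE and aa in pka.side_chains:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka.side_chains[aa]))
        elif aa in _NEGATIVE and aa in pka.side_chains:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.side_chains[aa] - pH))
    return charge


def isoelectric_point(sequence: str, pka: PkaSet = EMBOSS_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    The charge is strictly decreasing in pH, positive near 0 (protonated
    N-terminus) and negative near 14 (deprotonated C-terminus), so the
    root exists and is unique.
    """
    _check_sequence(sequence)
    lo, hi = 1e-6, 14.0 - 1e-6
    # Bisect to interval convergence rather than stopping at |charge| < tol:
    # near-neutral peptides have a very flat charge curve, and |charge| < tol
    # alone can leave the root several millis of pH off.
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pka)
        if c > 0:
            lo = mid
        else:
            hi = mid
    pI = 0.5 * (lo + hi)
    assert abs(net_charge(sequence, pI, pka)) < tol
    return pI


def mono_mass(sequence: str) -> float:
    """Monoisotopic mass in Da: residue masses plus one water."""
    _check_sequence(sequence)
    return float(_ptmass.calculate_mass(sequence=sequence))


def _nearest_int_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class PropertyRecord:
    """Computed properties of one peptide."""

    peptide: Peptide
    length: int
    gravy: float
    pI: float
    net_charge_pH7: float
    mono_mass: float

    @property
    def net_charge_int(self) -> int:
        """Integer charge bin (nearest integer, ties away from zero)."""
        return _nearest_int_half_away(self.net_charge_pH7)


def property_record(peptide: Peptide, scale: HydropathyScale = KYTE_DOOLITTLE,
                    pka: PkaSet = EMBOSS_PKA) -> PropertyRecord:
    seq = peptide.sequence
    return PropertyRecord(
        peptide=peptide,
        length=len(seq),
        gravy=gravy(seq, scale),
        pI=isoelectric_point(seq, pka),
        net_charge_pH7=net_charge(seq, 7.0, pka),
        mono_mass=mono_mass(seq),
    )


def properties_table(pop: PeptidePopulation, scale: HydropathyScale = KYTE_DOOLITTLE,
                     pka: PkaSet = EMBOSS_PKA) -> pd.DataFrame:
    """Property table for a population, one row per peptide (input order).

    Columns: peptide, condition, fraction, length, gravy, pI, net_charge,
    net_charge_int, mono_mass.
    """
    require_nonempty(pop)
    rows = []
    for p in pop:
        r = property_record(p, scale, pka)
        rows.append({
            "peptide": p.sequence,
            "condition": p.condition,
            "fraction": p.fraction,
            "length": r.length,
            "gravy": r.gravy,
            "pI": r.pI,
            "net_charge": r.net_charge_pH7,
            "net_charge_int": r.net_charge_int,
            "mono_mass": r.mono_mass,
        })
    return pd.DataFrame(rows)
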