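"""In-silico enzymatic digestion.

Cleavage is modelled by P1 specificity: a cut occurs on the C-terminal side
of any residue in the rule's P1 set, never after the final residue.
Missed cleavages re-join up to ``max_missed_cleavages`` adjacent fragments,
emulating incomplete digestion; length bounds are applied last, as a search
engine would when filtering candidate peptides.

Presets
-------
``trypsin``
    cuts after K, R (its canonical specificity).
``pepsin``
    promiscuous towards aromatic/hydrophobic side chains; default P1 set
    {F, W, Y, L}, configurable since the enzyme is not strictly specific.
``papain``
    broad preference for basic or hydrophobic P1 residues; default
    {K, R, H, L, V, I, F, W, A}, configurable for the same reason.

A cleave-before-proline exception (P1' = P blocks the cut, as many search
engines assume for trypsin) is available as a rule flag but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .core import _AA_SET, Peptide, PeptidePopulation

__all__ = [
    "CleavageRule",
    "TRYPSIN",
    "PEPSIN",
    "PAPAIN",
    "ENZYMES",
    "cleavage_sites",
    "digest",
    "sequential_digest",
]


@dataclass(frozen=True)
class CleavageRule:
    """An enzyme's cleavage specificity.

    ``p1_residues`` are the residues after which the bond is cut
    (C-terminal side). ``restrict_p1_prime`` optionally blocks the cut when
    the following residue is in that set (e.g. {"P"}).
    """

    enzyme_name: str
    p1_residues: frozenset[str]
    max_missed_cleavages: int = 2
    min_length: int = 1
    max_length: int = 10**9
    restrict_p1_prime: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1_residues", frozenset(self.p1_residues))
        object.__setattr__(self, "restrict_p1_prime", frozenset(self.restrict_p1_prime))
        if not self.p1_residues <= _AA_SET:
            raise ValueError(f"P1 residues {sorted(self.p1_residues - _AA_SET)} not canonical")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")

    def with_bounds(self, min_length: int, max_length: int) -> "CleavageRule":
        return replace(self, min_length=min_length, max_length=max_length)

    def with_missed(self, max_missed_cleavages: int) -> "CleavageRule":
        return replace(self, max_missed_cleavages=max_missed_cleavages)


TRYPSIN = CleavageRule("trypsin", frozenset("KR"))
PEPSIN = CleavageRule("pepsin", frozenset("FWYL"))
PAPAIN = CleavageRule("papain", frozenset("KRHLVIFWA"))

ENZYMES: dict[str, CleavageRule] = {
    "trypsin": TRYPSIN,
    "pepsin": PEPSIN,
    "papain": PAPAIN,
}


def cleavage_sites(protein: str, rule: CleavageRule) -> list[int]:
    """0-based positions i such that the bond after residue i is cut.

    The bond after the final residue is never a site (there is no bond).
    """
    last = len(protein) - 1
    sites = []
    for i, aa in enumerate(protein):
        if i == last:
            break
        if aa in rule.p1_residues and protein[i + 1] not in rule.restrict_p1_prime:
            sites.append(i)
    return sites


def _validate_protein(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    bad = sorted(set(protein) - _AA_SET)
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad!r} in protein")


def _fragments(protein: str, sites: list[int]) -> list[str]:
    bounds = [0] + [s + 1 for s in sites] + [len(protein)]
    return [protein[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def digest(
    protein: str,
    rule: CleavageRule,
    protein_id: Optional[str] = None,
    condition: str = "other",
) -> list[Peptide]:
    """Digest one protein, emitting peptides with up to the rule's allowed
    number of missed (internal, uncut) cleavage sites.

    Fragments are the maximal runs between adjacent sites; a peptide with
    ``m`` missed cleavages is the concatenation of ``m + 1`` consecutive
    fragments. Length bounds are applied after missed-cleavage expansion.
    """
    _validate_protein(protein)
    frags = _fragments(protein, cleavage_sites(protein, rule))
    out: list[Peptide] = []
    for i in range(len(frags)):
        seq = ""
        for m in range(rule.max_missed_cleavages + 1):
            if i + m >= len(frags):
                break
            seq += frags[i + m]
            if rule.min_length <= len(seq) <= rule.max_length:
                out.append(Peptide(seq, protein_id=protein_id, condition=condition))
    return out


def sequential_digest(
    protein: str,
    first: CleavageRule,
    second: CleavageRule,
    protein_id: Optional[str] = None,
    condition: str = "other",
) -> list[Peptide]:
    """Two-stage digestion: the second enzyme digests each fragment of the
    first (e.g. pepsin in the acidic stage, then trypsin).

    With zero missed cleavages on both rules this equals a single digestion
    at the union of both site sets. Length bounds of the *second* rule
    govern the emitted peptides; the first stage is taken to completion
    (its fragments are intermediate, so its bounds are not applied).
    """
    _validate_protein(protein)
    stage1 = replace(first, min_length=1, max_length=10**9, max_missed_cleavages=0)
    out: list[Peptide] = []
    for frag in _fragments(protein, cleavage_sites(protein, stage1)):
        out.extend(digest(frag, second, protein_id=protein_id, condition=condition))
    return out


def digest_population(
    proteins,
    rule: CleavageRule,
    condition: str = "other",
    label: str = "",
) -> PeptidePopulation:
    """Digest many (id, sequence) pairs or ProteinRecords into one population."""
    peptides: list[Peptide] = []
    for rec in proteins:
        pid, seq = (rec.protein_id, rec.sequence) if hasattr(rec, "sequence") else rec
        peptides.extend(digest(seq, rule, protein_id=pid, condition=condition))
    return PeptidePopulation(peptides, label)
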