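"""Core domain objects: peptides and peptide populations.

A :class:`Peptide` is a single identified (or simulated) sequence over the
20 canonical amino acids, optionally carrying its source protein, the search
engine's identification probability, the digestion condition that produced
it, and the chromatographic fraction it was observed in (the hydrolysate
itself, the IMAC flow-through, or the low-pH eluent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "AMINO_ACIDS",
    "CONDITIONS",
    "FRACTIONS",
    "Peptide",
    "PeptidePopulation",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_SET = frozenset(AMINO_ACIDS)

#: Digestion conditions recognised downstream.
CONDITIONS = frozenset({"pep_tryp", "papain", "other"})

#: Fraction labels: whole hydrolysate, IMAC flow-through, eluent, simulated.
FRACTIONS = frozenset({"RBPH", "FT", "E", "synthetic"})


@dataclass(frozen=True)
class Peptide:
    """One peptide record.

    Parameters
    ----------
    sequence : str
        Upper-case sequence over the 20-letter alphabet.
    protein_id : str, optional
        Accession of the source protein.
    probability : float, optional
        Identification probability in [0, 1]; ``None`` when the report had
        none or it could not be parsed (see ``issues``).
    condition : str
        One of ``pep_tryp``, ``papain``, ``other``.
    fraction : str
        One of ``RBPH``, ``FT``, ``E``, ``synthetic``.
    issues : tuple of str
        Ingest anomalies attached to the record instead of dropping it
        (e.g. ``"modifications_stripped"``, ``"unparseable_probability"``).
    """

    sequence: str
    protein_id: Optional[str] = None
    probability: Optional[float] = None
    condition: str = "other"
    fraction: str = "synthetic"
    issues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be nonempty")
        bad = sorted(set(self.sequence) - _AA_SET)
        if bad:
            raise ValueError(
                f"non-canonical residue(s) {bad!r} in sequence {self.sequence!r}"
            )
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {sorted(CONDITIONS)}"
            )
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"unknown fraction {self.fraction!r}; expected one of {sorted(FRACTIONS)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_fraction(self, fraction: str) -> "Peptide":
        return replace(self, fraction=fraction)


@dataclass
class PeptidePopulation:
    """An ordered collection of peptides with a label.

    Populations may be empty only transiently (while being assembled);
    analytical operations reject empty inputs.
    """

    peptides: list[Peptide] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def conditions(self) -> set[str]:
        return {p.condition for p in self.peptides}

    def subset(self, predicate, label: Optional[str] = None) -> "PeptidePopulation":
        return PeptidePopulation(
            [p for p in self.peptides if predicate(p)],
            label if label is not None else self.label,
        )

    def by_condition(self) -> dict[str, "PeptidePopulation"]:
        out: dict[str, PeptidePopulation] = {}
        for p in self.peptides:
            out.setdefault(p.condition, PeptidePopulation([], p.condition)).peptides.append(p)
        return out

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        label: str = "",
        condition: str = "other",
        fraction: str = "synthetic",
    ) -> "PeptidePopulation":
        return cls(
            [Peptide(s, condition=condition, fraction=fraction) for s in sequences],
            label,
        )


def require_nonempty(pop: PeptidePopulation, what: str = "population") -> None:
    if len(pop) == 0:
        raise ValueError(f"empty {what}: downstream analytics require at least one peptide")
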