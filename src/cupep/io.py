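"""Reading and writing the formats the pipeline touches.

FASTA proteins are read through Biopython. Peptide-identification reports
are delimited tables (TSV or CSV, auto-detected) in the style of
FragPipe/MSFragger peptide output, with a configurable column map binding
report headers to :class:`~cupep.core.Peptide` fields. All result tables
are written as TSV, UTF-8, ``.`` decimal separator, with ``#`` metadata
header lines.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .core import _AA_SET, Peptide, PeptidePopulation

__all__ = [
    "ProteinRecord",
    "FilterResult",
    "read_fasta",
    "strip_modifications",
    "read_peptide_report",
    "write_peptide_report",
    "filter_by_probability",
    "DEFAULT_COLUMN_MAP",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A FASTA record with an alphabet-validity flag.

    ``is_valid`` is False when the sequence contains characters outside the
    20 canonical one-letter codes (ambiguity codes B/J/Z/X, U, O, ``*``);
    the offending characters are listed in ``invalid_chars``.
    """

    protein_id: str
    sequence: str
    is_valid: bool = True
    invalid_chars: tuple[str, ...] = ()


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file of proteins.

    Sequences are upper-cased. Records with non-canonical characters are
    returned flagged rather than dropped, so callers can decide.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = tuple(sorted(set(seq) - _AA_SET))
        records.append(ProteinRecord(rec.id, seq, is_valid=not bad, invalid_chars=bad))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


# Bracketed mass annotations like [+42.0106] or [147], and lowercase
# terminal/site markers (n, c) or lowercase modified residues.
_BRACKET = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def strip_modifications(raw: str) -> tuple[str, bool]:
    """Strip modification annotations from a report sequence string.

    Removes bracketed/parenthesised mass annotations and lowercase
    characters (FragPipe marks termini ``n``/``c`` and modified residues in
    lowercase), returning the bare upper-case residue string and whether
    anything was stripped.
    """
    stripped = _BRACKET.sub("", raw)
    stripped = "".join(c for c in stripped if c.isupper())
    return stripped, stripped != raw


#: Default expected report headers (FragPipe peptide report style).
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "sequence": "Peptide",
    "protein_id": "Protein",
    "probability": "Probability",
    "condition": "Condition",
    "fraction": "Fraction",
}


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    return "\t"


def read_peptide_report(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    label: str = "",
    condition: str = "other",
    fraction: str = "synthetic",
) -> PeptidePopulation:
    """Read a delimited peptide-identification report into a population.

    Parameters
    ----------
    column_map
        Maps Peptide field names (``sequence``, ``protein_id``,
        ``probability``, ``condition``, ``fraction``) to report headers.
        Only ``sequence`` is mandatory in the file.
    condition, fraction
        Defaults used for rows where the report has no such column.

    Modification annotations in sequence cells are stripped to bare
    residues and noted on the record; unparseable probabilities flag the
    record instead of dropping it. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#", dtype=str)
    seq_col = cmap["sequence"]
    if seq_col not in df.columns:
        raise ValueError(
            f"report {path} lacks sequence column {seq_col!r}; columns: {list(df.columns)}"
        )
    peptides: list[Peptide] = []
    for _, row in df.iterrows():
        issues: list[str] = []
        seq, modified = strip_modifications(str(row[seq_col]))
        if modified:
            issues.append("modifications_stripped")
        prob: Optional[float] = None
        pcol = cmap.get("probability")
        if pcol and pcol in df.columns and not pd.isna(row[pcol]):
            try:
                prob = float(row[pcol])
                if math.isnan(prob):
                    prob = None
            except (TypeError, ValueError):
                prob = None
                issues.append("unparseable_probability")
        ccol = cmap.get("condition")
        cond = condition
        if ccol and ccol in df.columns and not pd.isna(row[ccol]):
            cond = str(row[ccol])
        fcol = cmap.get("fraction")
        frac = fraction
        if fcol and fcol in df.columns and not pd.isna(row[fcol]):
            frac = str(row[fcol])
        prot = None
        prcol = cmap.get("protein_id")
        if prcol and prcol in df.columns and not pd.isna(row[prcol]):
            prot = str(row[prcol])
        peptides.append(
            Peptide(seq, protein_id=prot, probability=prob,
                    condition=cond, fraction=frac, issues=tuple(issues))
        )
    return PeptidePopulation(peptides, label or path.stem)


def write_peptide_report(
    pop: PeptidePopulation,
    path,
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a population as a TSV report (round-trips with the reader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "Peptide": p.sequence,
            "Protein": p.protein_id if p.protein_id is not None else "",
            "Probability": "" if p.probability is None else repr(p.probability),
            "Condition": p.condition,
            "Fraction": p.fraction,
        }
        for p in pop
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            for k in sorted(metadata):
                fh.write(f"# {k}={metadata[k]}\n")
        pd.DataFrame(rows, columns=["Peptide", "Protein", "Probability",
                                    "Condition", "Fraction"]).to_csv(
            fh, sep="\t", index=False)


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a probability filter: the kept population plus accounting."""

    population: PeptidePopulation
    n_input: int
    n_below: int
    n_missing: int

    @property
    def n_retained(self) -> int:
        return len(self.population)


def filter_by_probability(pop: PeptidePopulation, threshold: float = 0.99) -> FilterResult:
    """Retain peptides with identification probability >= ``threshold``.

    Records lacking a probability are dropped and counted (``n_missing``),
    never silently discarded from the accounting. The comparison is
    inclusive, so a record at exactly the threshold is retained.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    kept, below, missing = [], 0, 0
    for p in pop:
        if p.probability is None:
            missing += 1
        elif p.probability >= threshold:
            kept.append(p)
        else:
            below += 1
    return FilterResult(
        PeptidePopulation(kept, pop.label), n_input=len(pop),
        n_below=below, n_missing=missing,
    )
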