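"""Composition and position-specific frequency profiling.

Global composition counts every residue in the population and reports
percentages of all residues. Positional analysis looks at two 3-residue
terminal windows — N-terminal positions 1-3 and the 3rd-last to last
C-terminal positions — and reports, per position, the percent of peptides
carrying each amino acid there. The positional denominator is the number
of contributing peptides (not total residues), which is what statements
like "32% of peptides have His at position 1" require. Peptides shorter
than 5 residues are excluded from positional analysis (both windows would
otherwise overlap more than one residue) and counted, never silently
dropped; for a length-5 peptide the middle residue contributes to both N3
and C3, the two windows being computed independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, PeptidePopulation, require_nonempty

__all__ = [
    "POSITION_LABELS",
    "CompositionProfile",
    "BackgroundProfile",
    "PositionalMatrix",
    "global_composition",
    "enrichment_ratio",
    "positional_matrix",
    "positional_matrix_by_condition",
    "load_background",
    "rice_bran_background",
    "plot_positional_heatmap",
]

POSITION_LABELS: tuple[str, ...] = ("N1", "N2", "N3", "C3", "C2", "C1")
MIN_POSITIONAL_LENGTH = 5


@dataclass(frozen=True)
class CompositionProfile:
    """Percent of each residue among all residues of a population."""

    percent: pd.Series  # index: 20 residues alphabetical; sums to 100
    total_residues: int

    def __post_init__(self) -> None:
        assert abs(self.percent.sum() - 100.0) < 1e-6


@dataclass(frozen=True)
class BackgroundProfile:
    """A user-supplied reference composition (percent per residue)."""

    percent: pd.Series
    name: str = "background"


@dataclass(frozen=True)
class PositionalMatrix:
    """20 x 6 percent-frequency matrix over terminal positions.

    ``matrix`` rows are the 20 residues (alphabetical), columns
    N1, N2, N3, C3, C2, C1; every column sums to 100. ``n_peptides`` is
    the number of peptides contributing to each column and ``n_excluded``
    how many were below the minimum length for positional analysis.
    """

    matrix: pd.DataFrame
    n_peptides: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=0).to_numpy()
        assert np.all(np.abs(sums - 100.0) < 1e-6), "columns must sum to 100"


def global_composition(pop: PeptidePopulation) -> CompositionProfile:
    """Pooled residue counts over all peptides, as percent of all residues."""
    require_nonempty(pop)
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    for p in pop:
        for aa in p.sequence:
            counts[aa] += 1
    total = int(counts.sum())
    return CompositionProfile(percent=counts / total * 100.0, total_residues=total)


def enrichment_ratio(observed: CompositionProfile,
                     background: BackgroundProfile) -> pd.Series:
    """Per-residue observed% / background%.

    Residues with zero (or missing) background percent get NaN, the
    undefined marker, rather than infinity.
    """
    bg = background.percent.reindex(observed.percent.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed.percent / bg
    return ratio.where((bg > 0) & bg.notna())


def _positional_counts(sequences: Sequence[str]) -> pd.DataFrame:
    counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(POSITION_LABELS))
    for seq in sequences:
        counts.loc[seq[0], "N1"] += 1
        counts.loc[seq[1], "N2"] += 1
        counts.loc[seq[2], "N3"] += 1
        counts.loc[seq[-3], "C3"] += 1
        counts.loc[seq[-2], "C2"] += 1
        counts.loc[seq[-1], "C1"] += 1
    return counts


def positional_matrix(pop: PeptidePopulation,
                      min_length: int = MIN_POSITIONAL_LENGTH) -> PositionalMatrix:
    """Position-specific amino-acid frequencies for the two terminal windows."""
    require_nonempty(pop)
    seqs = [p.sequence for p in pop if len(p.sequence) >= min_length]
    n_excluded = len(pop) - len(seqs)
    if not seqs:
        raise ValueError(
            f"no peptides of length >= {min_length} for positional analysis "
            f"({n_excluded} excluded)"
        )
    counts = _positional_counts(seqs)
    return PositionalMatrix(matrix=counts / len(seqs) * 100.0,
                            n_peptides=len(seqs), n_excluded=n_excluded)


def positional_matrix_by_condition(
    pop: PeptidePopulation,
    conditions: Optional[Sequence[str]] = None,
    min_length: int = MIN_POSITIONAL_LENGTH,
) -> dict[str, PositionalMatrix]:
    """Per-condition positional matrices plus the pooled matrix.

    Returns a mapping with one entry per condition and a ``"pooled"``
    entry of identical layout. Requesting a condition not present raises,
    listing the labels actually seen.
    """
    require_nonempty(pop)
    seen = sorted(pop.conditions())
    wanted = list(conditions) if conditions is not None else seen
    unknown = sorted(set(wanted) - set(seen))
    if unknown:
        raise ValueError(f"unknown condition label(s) {unknown}; labels seen: {seen}")
    out: dict[str, PositionalMatrix] = {}
    for cond in wanted:
        out[cond] = positional_matrix(
            pop.subset(lambda p, c=cond: p.condition == c, label=cond), min_length)
    out["pooled"] = positional_matrix(pop, min_length)
    return out


def load_background(path) -> BackgroundProfile:
    """Load a background profile from a two-column TSV (residue, percent)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ser = pd.Series(df["percent"].to_numpy(dtype=float),
                    index=df["residue"].astype(str).to_numpy())
    ser = ser.reindex(list(AMINO_ACIDS)).fillna(0.0)
    return BackgroundProfile(percent=ser, name=Path(str(path)).stem)


def rice_bran_background() -> BackgroundProfile:
    """The shipped example background: literature-informed typical rice
    bran protein amino-acid abundances (percent)."""
    from importlib.resources import files

    return load_background(files("cupep.data") / "rice_bran_background_example.tsv")


def plot_positional_heatmap(pm: PositionalMatrix, path, title: str = "") -> None:
    """Optional rendering of a positional matrix as a viridis heat map.

    The canonical artifact is the TSV matrix; this is a convenience view.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 7))
    im = ax.imshow(pm.matrix.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(pm.matrix.columns)), pm.matrix.columns)
    ax.set_yticks(range(len(pm.matrix.index)), pm.matrix.index)
    ax.set_xlabel("position")
    fig.colorbar(im, ax=ax, label="% of peptides")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
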