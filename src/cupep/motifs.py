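"""Sliding-window motif extraction and cross-condition comparison.

Every contiguous length-``N`` window of every peptide is appended to a
per-condition catalog (with multiplicity by default; a per-peptide-unique
mode exists). Catalogs are filtered by pooled frequency, and the most
frequent motifs of each condition are compared pairwise across conditions
by normalized Hamming distance — the fraction of differing positions of
two equal-length strings, a metric on fixed-length sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .core import Peptide, PeptidePopulation, require_nonempty

__all__ = [
    "MotifCatalog",
    "MotifPair",
    "generate_windows",
    "build_catalog",
    "normalized_hamming",
    "cross_condition_compare",
    "shared_cores",
]


def generate_windows(peptide, n: int) -> list[str]:
    """The L - N + 1 contiguous length-``n`` substrings, N- to C-terminal.

    ``n`` must be between 1 and the peptide length: windows longer than
    the peptide are undefined.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else str(peptide)
    if n < 1:
        raise ValueError(f"window length must be >= 1, got {n}")
    if n > len(seq):
        raise ValueError(
            f"window length {n} exceeds peptide length {len(seq)} ({seq!r})")
    return [seq[i:i + n] for i in range(len(seq) - n + 1)]


@dataclass
class MotifCatalog:
    """Per-condition window counts at a fixed window length.

    ``counts`` maps condition -> motif -> count; ``provenance`` maps each
    motif to the indices (into the source population) of the peptides that
    contributed it. ``min_count`` is the pooled-frequency filter applied.
    """

    n: int
    counts: dict[str, Counter] = field(default_factory=dict)
    provenance: dict[str, list[int]] = field(default_factory=dict)
    min_count: int = 1

    def conditions(self) -> list[str]:
        return sorted(self.counts)

    def pooled(self) -> Counter:
        pooled: Counter = Counter()
        for c in self.counts.values():
            pooled.update(c)
        return pooled

    def top_motifs(self, condition: str, k: int) -> list[tuple[str, int]]:
        """Top-``k`` motifs of a condition by count, ties broken
        lexicographically."""
        items = sorted(self.counts[condition].items(), key=lambda kv: (-kv[1], kv[0]))
        return items[:k]


def build_catalog(pop: PeptidePopulation, n: int, min_count: int = 2,
                  per_peptide_unique: bool = False) -> MotifCatalog:
    """Pool length-``n`` windows per condition and filter by pooled count.

    Windows from one peptide are counted with multiplicity unless
    ``per_peptide_unique``. Peptides shorter than ``n`` contribute no
    windows. Motifs whose pooled (all-condition) count falls below
    ``min_count`` are removed.
    """
    require_nonempty(pop)
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, Counter] = {}
    provenance: dict[str, list[int]] = {}
    for idx, p in enumerate(pop):
        if len(p.sequence) < n:
            continue
        windows = generate_windows(p, n)
        if per_peptide_unique:
            windows = sorted(set(windows))
        cond_counter = counts.setdefault(p.condition, Counter())
        for w in windows:
            cond_counter[w] += 1
            provenance.setdefault(w, []).append(idx)
    pooled: Counter = Counter()
    for c in counts.values():
        pooled.update(c)
    keep = {m for m, c in pooled.items() if c >= min_count}
    counts = {cond: Counter({m: c for m, c in ctr.items() if m in keep})
              for cond, ctr in counts.items()}
    provenance = {m: ids for m, ids in provenance.items() if m in keep}
    return MotifCatalog(n=n, counts=counts, provenance=provenance, min_count=min_count)


def normalized_hamming(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length motifs differ."""
    if len(a) != len(b):
        raise ValueError(
            f"Hamming distance undefined for unequal lengths {len(a)} and {len(b)}")
    if not a:
        raise ValueError("Hamming distance undefined for empty strings")
    return sum(x != y for x, y in zip(a, b)) / len(a)


@dataclass(frozen=True)
class MotifPair:
    condition_a: str
    motif_a: str
    condition_b: str
    motif_b: str
    distance: float


def cross_condition_compare(cat: MotifCatalog, top_k: int = 50,
                            max_distance: float = 0.4) -> list[MotifPair]:
    """All close pairs between the top-``top_k`` motifs of each condition.

    For every unordered pair of conditions, every (motif_A, motif_B) pair
    with normalized Hamming distance <= ``max_distance`` is reported,
    sorted by distance then lexicographically.
    """
    conds = cat.conditions()
    if len(conds) < 2:
        raise ValueError(
            f"cross-condition comparison needs >= 2 conditions, got {conds}")
    pairs: list[MotifPair] = []
    for i, ca in enumerate(conds):
        for cb in conds[i + 1:]:
            for ma, _ in cat.top_motifs(ca, top_k):
                for mb, _ in cat.top_motifs(cb, top_k):
                    d = normalized_hamming(ma, mb)
                    if d <= max_distance:
                        pairs.append(MotifPair(ca, ma, cb, mb, d))
    pairs.sort(key=lambda p: (p.distance, p.condition_a, p.motif_a,
                              p.condition_b, p.motif_b))
    return pairs


def shared_cores(pop_a: PeptidePopulation, pop_b: PeptidePopulation,
                 n: int) -> set[str]:
    """Length-``n`` motifs present (count >= 1) in both populations."""
    require_nonempty(pop_a, "population A")
    require_nonempty(pop_b, "population B")

    def windows_of(pop: PeptidePopulation) -> set[str]:
        out: set[str] = set()
        for p in pop:
            if len(p.sequence) >= n:
                out.update(generate_windows(p, n))
        return out

    return windows_of(pop_a) & windows_of(pop_b)
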