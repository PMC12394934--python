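"""Synthetic peptide populations with the structure the analysis assumes.

Two layers:

1. A random proteome generator drawing residues from a configurable
   composition (default: the shipped rice-bran-like background), digested
   in silico under the two study schemes — sequential pepsin→trypsin, or
   papain — with peptide lengths bounded to 5–30.
2. A simulated Cu(II)–IMAC retention step. Each peptide is independently
   retained with a logistic probability over simple coordination-relevant
   features: histidine count, His at N-terminal positions 1 and 2 (the
   ATCUN / pseudo-ATCUN architecture), and glycine / proline fractions.
   A closed-form calibration routine sets the His-at-N1 weight so that the
   *retained* population hits a requested His-at-N1 frequency (e.g. 0.32)
   in expectation, given the empirical base rate of the input population.

Retention is sampled independently per peptide — no resin-capacity
competition — and the whole step is a deterministic function of the model
seed, so retained ∪ flow-through is always an exact, reproducible
partition of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import AMINO_ACIDS, Peptide, PeptidePopulation, require_nonempty
from .digestion import PAPAIN, PEPSIN, TRYPSIN, CleavageRule, digest, sequential_digest

# Re-exported here so the synthetic-data surface carries the hydrolysis
# arithmetic alongside the generators that emulate the digests.
from .assays import AssayMeasurement, degree_of_hydrolysis  # noqa: F401

__all__ = [
    "EnrichmentModel",
    "random_proteins",
    "digest_proteome",
    "tryptic_population",
    "study_populations",
    "simulate_enrichment",
    "calibrate_his_n1",
    "his_n1_frequency",
    "AssayMeasurement",
    "degree_of_hydrolysis",
    "DEFAULT_LENGTH_BOUNDS",
]

#: Simulated peptide length bounds (residues).
DEFAULT_LENGTH_BOUNDS = (5, 30)


def _background_frequencies() -> tuple[np.ndarray, list[str]]:
    from .profiles import rice_bran_background

    bg = rice_bran_background().percent
    freqs = bg.to_numpy(dtype=float)
    return freqs / freqs.sum(), list(bg.index)


def random_proteins(
    n_proteins: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (200, 400),
    frequencies: Optional[Sequence[float]] = None,
) -> list[tuple[str, str]]:
    """Random (id, sequence) pairs with residues drawn i.i.d. from a
    composition (default: the rice-bran-like background)."""
    if frequencies is None:
        freqs, alphabet = _background_frequencies()
    else:
        freqs = np.asarray(frequencies, dtype=float)
        freqs = freqs / freqs.sum()
        alphabet = list(AMINO_ACIDS)
    lo, hi = length_range
    out = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=freqs))
        out.append((f"synthetic_protein_{i + 1}", seq))
    return out


def digest_proteome(
    proteins: Sequence[tuple[str, str]],
    scheme: str,
    max_missed: int = 2,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> PeptidePopulation:
    """Digest a proteome under one of the study schemes.

    ``scheme`` is ``"pep_tryp"`` (sequential pepsin then trypsin) or
    ``"papain"``.
    """
    lo, hi = length_bounds
    peptides: list[Peptide] = []
    if scheme == "pep_tryp":
        second = TRYPSIN.with_bounds(lo, hi).with_missed(max_missed)
        for pid, seq in proteins:
            peptides.extend(sequential_digest(seq, PEPSIN, second,
                                              protein_id=pid, condition="pep_tryp"))
    elif scheme == "papain":
        rule = PAPAIN.with_bounds(lo, hi).with_missed(max_missed)
        for pid, seq in proteins:
            peptides.extend(digest(seq, rule, protein_id=pid, condition="papain"))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'pep_tryp' or 'papain'")
    return PeptidePopulation(peptides, scheme)


def tryptic_population(
    n_peptides: int,
    seed: int,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    max_missed: int = 0,
) -> PeptidePopulation:
    """A tryptic peptide population of exactly ``n_peptides`` from a random
    proteome (generating proteins until enough peptides accumulate)."""
    rng = np.random.default_rng(seed)
    rule = TRYPSIN.with_bounds(*length_bounds).with_missed(max_missed)
    peptides: list[Peptide] = []
    batch = 0
    while len(peptides) < n_peptides:
        for pid, seq in random_proteins(50, rng):
            peptides.extend(digest(seq, rule, protein_id=pid, condition="pep_tryp"))
        batch += 1
        if batch > 200:  # ~10k proteins; never reached at sane sizes
            raise RuntimeError("failed to accumulate requested peptide count")
    return PeptidePopulation(peptides[:n_peptides], "tryptic_synthetic")


def study_populations(
    n_proteins: int,
    seed: int,
    max_missed: int = 2,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> dict[str, PeptidePopulation]:
    """Both digestion-scheme populations from one random proteome."""
    rng = np.random.default_rng(seed)
    proteins = random_proteins(n_proteins, rng)
    return {
        "pep_tryp": digest_proteome(proteins, "pep_tryp", max_missed, length_bounds),
        "papain": digest_proteome(proteins, "papain", max_missed, length_bounds),
    }


@dataclass(frozen=True)
class EnrichmentModel:
    """Logistic retention model of the Cu(II)–IMAC step.

    Retention probability = sigmoid(intercept + w · features) with
    features (His count, His at position 1, His at position 2, Gly
    fraction, Pro fraction). Finite weights keep the probability strictly
    inside (0, 1), so both output fractions are reachable.
    """

    w_his_count: float = 0.0
    w_his_n1: float = 0.0
    w_his_n2: float = 0.0
    w_gly_frac: float = 0.0
    w_pro_frac: float = 0.0
    intercept: float = 0.0
    seed: int = 0

    def features(self, sequence: str) -> np.ndarray:
        L = len(sequence)
        return np.array([
            sequence.count("H"),
            1.0 if sequence[0] == "H" else 0.0,
            1.0 if L > 1 and sequence[1] == "H" else 0.0,
            sequence.count("G") / L,
            sequence.count("P") / L,
        ])

    def retention_probability(self, sequence: str) -> float:
        w = np.array([self.w_his_count, self.w_his_n1, self.w_his_n2,
                      self.w_gly_frac, self.w_pro_frac])
        z = self.intercept + float(w @ self.features(sequence))
        return 1.0 / (1.0 + math.exp(-z))


#: Default model: qualitative bias toward His-rich, Gly/Pro-rich peptides
#: with N-terminal His architecture, mimicking Cu(II)–IMAC selectivity.
DEFAULT_ENRICHMENT = EnrichmentModel(
    w_his_count=1.0, w_his_n1=2.0, w_his_n2=1.0,
    w_gly_frac=3.0, w_pro_frac=3.0, intercept=-3.0,
)


def simulate_enrichment(
    pop: PeptidePopulation, model: EnrichmentModel,
) -> tuple[PeptidePopulation, PeptidePopulation]:
    """Partition a population into (retained, flow-through).

    Each peptide is retained independently with its model probability;
    the same seed and inputs give a bit-identical partition. Retained
    peptides are relabelled fraction ``E``, flow-through ``FT``.
    """
    require_nonempty(pop)
    rng = np.random.default_rng(model.seed)
    probs = np.array([model.retention_probability(p.sequence) for p in pop])
    draws = rng.random(len(pop))
    retained, flow = [], []
    for p, u, pr in zip(pop, draws, probs):
        (retained if u < pr else flow).append(p.with_fraction("E" if u < pr else "FT"))
    return (PeptidePopulation(retained, f"{pop.label}_E"),
            PeptidePopulation(flow, f"{pop.label}_FT"))


def his_n1_frequency(pop: PeptidePopulation) -> float:
    """Fraction of peptides with histidine as the first residue."""
    require_nonempty(pop)
    return sum(p.sequence[0] == "H" for p in pop) / len(pop)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def calibrate_his_n1(
    pop: PeptidePopulation,
    target: float,
    seed: int = 0,
    baseline_retention: float = 0.3,
    max_retention: float = 0.95,
) -> EnrichmentModel:
    """Closed-form calibration of the His-at-N1 weight to a retained-
    population target frequency.

    With base rate ``q`` of His-at-N1 in the input and retention
    probabilities ``p1`` (His at N1) and ``p0`` (otherwise), the expected
    retained-population frequency is ``q p1 / (q p1 + (1-q) p0)``, so the
    required odds ratio is ``r = (t/(1-t)) · ((1-q)/q)``. The baseline
    ``p0`` is lowered from ``baseline_retention`` when needed to keep
    ``p1 = r p0 <= max_retention``.
    """
    require_nonempty(pop)
    if not (0.0 < target < 1.0):
        raise ValueError(f"target frequency {target} outside (0, 1)")
    q = his_n1_frequency(pop)
    if q == 0.0 or q == 1.0:
        raise ValueError(
            f"cannot calibrate: His-at-N1 base rate is {q} in the input population")
    r = (target / (1.0 - target)) * ((1.0 - q) / q)
    p0 = min(baseline_retention, max_retention / r)
    p1 = r * p0
    return EnrichmentModel(w_his_n1=_logit(p1) - _logit(p0),
                           intercept=_logit(p0), seed=seed)
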