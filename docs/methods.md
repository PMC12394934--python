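# Methods

This note documents the models, defaults and numerical choices behind
`cupep`, and what its synthetic data do and do not emulate.

## Digestion model

Digestion is purely positional: an enzyme is a P1 residue set, and a cut
occurs on the C-terminal side of every P1 residue (never after the last
residue of the chain). Fragments are the maximal runs between adjacent
cuts; a peptide with *m* missed cleavages is the concatenation of *m*+1
consecutive fragments, and length bounds are applied after missed-cleavage
expansion (as a search engine filters candidates). Kinetics, pH
dependence and enzyme concentration are not modelled.

Defaults:

| rule | P1 set | rationale |
|---|---|---|
| trypsin | K, R | canonical specificity |
| pepsin | F, W, Y, L | the enzyme is promiscuous toward aromatic/hydrophobic residues; the set is configurable and this default is the common minimal choice |
| papain | K, R, H, L, V, I, F, W, A | "basic or hydrophobic" P1 preference; configurable |

`max_missed_cleavages` defaults to 2 (the usual search-engine setting for
these data), simulated peptide lengths are bounded to 5–30 residues
(matching the observed 5–30+ range of IMAC-enriched hydrolysate
peptides), and no cleave-before-proline exception is applied by default
(available as `restrict_p1_prime={"P"}`).

Sequential (pepsin→trypsin) digestion runs the first enzyme to
completion — its fragments are intermediates, so its length bounds and
missed-cleavage allowance are not applied — and digests each fragment
with the second rule. With zero missed cleavages this equals one
digestion at the union of the two site sets, which the tests verify.

## Enrichment simulator

The Cu(II)-IMAC step is a per-peptide independent Bernoulli retention
with logistic probability

    P(retained) = sigmoid(b + w · x),
    x = (His count, 1[His at N1], 1[His at N2], Gly fraction, Pro fraction)

The features are the coordination-relevant properties IMAC enrichment is
known to select on: overall imidazole content, N-terminal His placement
(ATCUN and pseudo-ATCUN architectures), and the Gly/Pro backbone
flexibility signal. There is no resin-capacity competition and no
modelling of ultra-tight chelators stripping Cu(II) off the resin and
escaping into the flow-through; retention is i.i.d. given the sequence.
The partition retained ∪ flow-through is exhaustive and disjoint, and a
fixed model seed makes it bit-identical across runs.

**Calibration.** For a binary feature with base rate *q* in the input
(His at N1 on tryptic peptides: ~2–3% under the default background), the
expected retained-population frequency is `q·p1 / (q·p1 + (1−q)·p0)`
where `p1`, `p0` are the retention probabilities with/without the
feature. Hitting a target *t* therefore requires the odds ratio
`r = (t/(1−t))·((1−q)/q)`; `calibrate_his_n1` fixes the baseline
retention `p0 = min(0.3, 0.95/r)` (lowered when needed so `p1 = r·p0`
stays ≤ 0.95) and sets the N1-His weight to `logit(p1) − logit(p0)`.
This is exact in expectation; sampling noise in the retained population
is approximately binomial, which is what the recovery checks use
(the central 95% acceptance region of Binomial(n_retained, t)).

**Synthetic proteome.** Proteins (default 200–400 residues) draw
residues i.i.d. from the shipped rice-bran-like background composition.
Real proteomes have domain structure, homology and non-uniform local
composition; none of that is emulated, so passing tests demonstrate the
correctness of the analysis arithmetic and the calibration logic, not
that real hydrolysates will show any particular motif content. Residue
*frequencies*, digestion-scheme length differences, and the enriched
N1-His architecture are reproduced; peptide-level correlations with real
protein families are not.

## Physicochemical properties

- **GRAVY** is the plain Kyte–Doolittle mean. Table display uses
  half-away-from-zero rounding at 2 decimals, computed in exact decimal
  arithmetic (the scale carries one decimal place, so the mean is a
  rational with an exact decimal expansion — binary round-off cannot
  flip a boundary case like −0.4875 → −0.49).
- **Net charge** uses the Henderson–Hasselbalch site sum with the EMBOSS
  pKa set (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5,
  K 10.8, R 12.5). The pKa set is a named, configurable parameter
  recorded in output metadata; published peptide-population analyses
  frequently omit which set they used, so agreement with external pI
  values is only expected set-for-set. Cys and Tyr are included as
  ionisable, following standard practice.
- **pI** is found by bisection on (0, 14). The site sum is strictly
  decreasing in pH and changes sign over that interval, so the root is
  unique. Bisection runs to interval convergence (10⁻¹⁰ pH) rather than
  stopping at a charge tolerance: near-neutral peptides have a very flat
  charge curve, and a |z| < 10⁻⁴ stop alone can leave the root several
  thousandths of a pH unit off the true zero.
- **Net charge bins** for histograms round half-away-from-zero to the
  nearest integer, since reported charge distributions ("+1 to −2") are
  integer-binned.
- **Monoisotopic mass** is the pyteomics residue-mass sum plus water.

One published reference value is knowingly not reproduced: the GRAVY
score printed for VPSGHPI (0.26). The residue sum is 1.1 over 7 residues
= 0.157 → 0.16 under any rounding; that row is excluded from the
golden-value set and the discrepancy is asserted in the tests.

## Composition and positional profiling

Global composition is residue counts over all residues × 100. Enrichment
ratios divide observed percent by a background percent; zero backgrounds
yield NaN (undefined), never infinity. The shipped background file is a
literature-informed example for rice bran protein (Gly 6.5%, Pro 9.0%,
His 2.0%, Ala 6.0%, Ser 8.5%, remainder from typical cereal seed-protein
tables, scaled to 100) — it is a config input, replaceable per study.

Positional matrices use the number of contributing peptides as the
denominator, so a cell reads "x% of peptides have residue r at this
position". Peptides shorter than 5 are excluded (each terminal window
needs 3 positions) and counted in the output metadata. For a length-5
peptide the middle residue is counted in both N3 and C3: the windows are
defined independently, and the choice is flagged in output metadata.

## Motifs

Catalogs count every window with multiplicity (a repeated window within
one peptide counts each time); a per-peptide-unique mode exists. The
window length *N* sweeps {5, 6, 7} by default — the conserved cores this
kind of analysis surfaces are 5–7 residues — and the pooled-frequency
filter defaults to `min_count = 2`; both are exposed parameters recorded
in output metadata, since neither has a canonical value. "Most frequent"
is bounded by `top_k` (default 50) with lexicographic tie-breaks, and
cross-condition comparison is restricted to equal-*N* catalogs because
the normalized Hamming distance is undefined otherwise.

## Statistics

Both tests are two-sided (no direction is assumed). Mann–Whitney U uses
the exact distribution when the pooled sample is tie-free and
n_A + n_B ≤ 16, else the tie-corrected normal approximation without
continuity correction (so identical samples give p = 1 exactly); the
method used is recorded per result. The degenerate all-tied case (zero
variance) reports p = 1. KS uses the asymptotic two-sided p. No
multiple-testing correction is applied by default — per-property raw
p-values are the reporting convention here — with a Bonferroni flag
available.

## Assay arithmetic

Chelation percent subtracts the sample+copper background from the full
(sample+copper+chelator) reading before comparing to the no-sample
control; negative percentages are reported with a warning, not clipped,
because they carry information (a sample raising apparent free copper).
AUC uses the trapezoidal rule — exact for piecewise-linear signals —
with the window edge linearly interpolated; whether a plate-reader
export is integrated trapezoidally or by raw summation is recorded in
output metadata as the trapezoidal choice. Replicates aggregate as
mean ± SEM with n.

## Problem sizes

Default verification sizes: 100 random proteins (≤ 50 residues) × 3
enzymes × 0–2 missed cleavages against the brute-force enumerator; 1000
random peptides for pI/charge consistency and motif algebra; 10⁴ random
triples for the metric axioms; a 2000-peptide tryptic population with
100 replicates per calibration target. These sizes give the binomial
checks comfortable power while keeping the full suite around ten
seconds.

## Known limitations

- The retention model is feature-linear and independent across peptides;
  saturation, competition and resin stripping are out of scope.
- pI/charge values depend on the pKa set; no attempt is made to model
  sequence-dependent pKa shifts or Cu(II)-bound species.
- GRAVY ignores sequence order, so it cannot reproduce HPLC elution
  ordering — a known, expected divergence.
- The statistics module reports tests, not effect sizes.
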