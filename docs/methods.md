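# Methods

## Library design model

The design unit is the unique C-terminal L-mer (default L = 9). A protein
of length n contributes its last L residues iff at least one validated
Ser/Thr phosphosite annotation falls within them; the site at 1-based
position q maps to the C-anchored coordinate p = q − n (p0 is the
C-terminal residue, p−k lies k residues upstream). Identical C-termini
from different proteins are merged: their site sets are unioned and all
accessions retained, so the design counts unique peptides, not proteins.
Annotations whose residue disagrees with the sequence are rejected with a
log record; proteins shorter than L, or with ambiguous residues (X) in
the terminal window, are skipped because they cannot be deterministically
reverse-translated.

A peptide with k sites expands into 2^k entries — the wild type plus
every subset of sites mutated S/T→E (the phosphomimetic approximating the
phosphate's charge). k is capped at 8 by default; above that the
expansion is refused rather than truncated, since silently dropping
combinations would bias downstream pair statistics. Sites exactly at p0
are kept when annotated; the mimetic then rewrites p0 and with it the
motif class, which the design table records via the per-entry class
column.

PDZ-binding-motif classes are a pure function of p0 and p−2: a
hydrophobic p0 (Φ) is required for any class; then S/T at p−2 → class I,
Φ → class II, D/E → class III. Φ defaults to {A,V,I,L,M,F,W,Y,C}; the
config refuses a Φ overlapping {S,T,D,E} so the classes stay mutually
exclusive. A direct consequence asserted in the tests: an E mutation at
p−2 converts a class I peptide into a class III one.

Reverse translation uses the single most frequent codon per amino acid
from a bundled E. coli K-12 usage table — deterministic, no sampling — so
the nucleotide design is reproducible byte for byte. Oligos are
`flank5 + insert + flank3`; the default flanks are placeholder annealing
sequences (the 3' flank opens with tandem stops so the displayed peptide
ends at p0) and are expected to be replaced by the vector's real
annealing sites via config. Any forbidden restriction motif (default SmaI
`CCCGGG`, needed free for the cloning step that destroys undigested
wild-type vector) overlapping the insert or a flank junction is removed
by swapping the leftmost overlapping codon for its next-ranked synonym,
retrying boundedly and failing loudly if no synonymous recoding works.

## Read deconvolution

Reads are assumed single-end and insert-covering:
`barcode + flank5 + insert + flank3`. Demultiplexing matches the forward
barcode at a configurable offset (default 0) with a configurable mismatch
tolerance (default 0 — exact); with tolerance > 0, a read tying two
barcodes at the minimal distance is discarded as ambiguous. An optional
reverse-barcode check (reverse complement at the read tail) and whole-read
reverse-complement mode cover the opposite sequencing orientation.

Per read, after barcode stripping: (1) the insert is located by anchoring
the 5' flank at the read start within ≤ 1 mismatch — unlocatable anchors
are ledgered `unmapped`; (2) the Phred quality aggregated over the insert
(mean by default, `min` by flag) must reach Q30 — "discarding sequences"
below a quality reads most naturally as a per-read aggregate, and the
mean mode is the default for that reason; (3) the insert is mapped to the
unique design entry at minimal Hamming distance ≤ m (default m = 2), ties
discarded as `ambiguous` — deterministic and conservative where an
aligner's tie-breaking would be reporting-mode dependent; (4) reads whose
surviving mismatches change the translated peptide are ledgered
`nonsynonymous`, so accepted counts represent exactly the designed
peptide. Indels are not modeled; mapping is ungapped by construction.

The index pairs an exact-match hash with a pigeonhole partition of the
insert into m + 1 segments: any query within m mismatches of an entry
matches at least one segment exactly, so candidate generation provably
loses nothing relative to a linear Hamming scan (the suite checks this
against a vectorized exhaustive oracle). Per sample the ledger satisfies
`reads_in == mapped + Σ discards` identically; a violation raises.

## Scoring model

Sequencing depth differs between pools, so all statistics run on
within-pool count fractions f = c / Σc. For each single-site peptide the
wild type and its mimetic form a pair; in replicate r the pair score is
s_r = m_r/(w_r + m_r), defined only when w_r + m_r > 0. s = 0 iff the
mimetic was absent while the wild type persisted (disabling), s = 1 for
the converse (enabling). Multi-site peptides are excluded from pair and
position statistics — their variants confound positions — but remain in
the count tables. The pair-level test is a two-sided two-sample t-test of
the wt vs mimetic fraction vectors across replicates (equal-variance by
default, Welch by flag), significance at α = 0.05.

The position matrix aggregates pairs per (bait, p-index): the cell mean
weights pairs equally (a count-weighted mean would let one abundant
ligand dominate a position); the cell p-value is a two-sided one-sample
t-test of the per-replicate position means against the neutral 0.5;
q-values are Benjamini–Hochberg within each bait's testable cells and a
cell is called enabling/disabling at q ≤ 0.025. Cells observed only as
wild type or only as mimetic, or with < 2 replicate means or zero
variance, are untestable — reported with their mean but no call, never an
infinite t statistic.

PWMs are built from C-anchored peptides, one vote per unique peptide by
default (count-weighting by flag); column information content is
IC = log2 20 − H in bits, no pseudocount or small-sample correction, so a
single-sequence column reaches log2 20 ≈ 4.32 bits and a uniform column 0.

Affinity utilities: fold change K_D(a)/K_D(b) with a nearest-integer
presentation helper, and ΔΔG = RT·ln(K_D ratio) with
R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ (T defaults to 298.15 K). Kinase
enrichment tests each kinase category's frequency among a bait's binders
against the design background with a one-sided Fisher exact test,
Holm-adjusted across kinases; the binder set must be a subset of the
background. The naive-library bias check reports the Pearson correlation
(raw or log1p by flag) between selection counts and naive counts of
selected entries, plus a Mann–Whitney comparison of naive counts for
selected vs unselected entries — the sensitivity-vs-strength distinction:
well-represented peptides are likelier to be detected at all, but their
selection strength should not track input abundance.

## Synthetic-data model

Selection is modeled as weight exponentiation: after t rounds (default 3,
matching a selection that saturates by round three) entry e is sampled
with probability ∝ π_e·λ_e^t, and a pool of depth N (default 50,000) is
drawn multinomially. This skips explicit phage population dynamics — λ
absorbs display level, binding, and amplification per round — which is
sufficient to exercise counting and scoring with closed-form
expectations: at equal naive frequency a mimetic/wt weight ratio of 4
over 3 rounds gives an expected pair score of 4³/(1+4³) = 0.9846.
Substitution errors are i.i.d. at rate ε = 0.002 per base, uniform over
the three alternatives, applied downstream of the barcode (error-free
barcodes keep demultiplexing conservation exact — a simplification);
quality strings are per-base normal (mean 35, SD 3) clamped to [2, 41],
Phred+33. Indels, PCR bias, and chimeras are not modeled, so passing
recovery tests demonstrates correctness of the deconvolution and scoring
machinery, not robustness to those real-data artifacts.

Toy proteomes realize a motif plan (so many C-termini per class, sites at
stated p-indices) over a neutral residue alphabet that cannot collide
with class-defining positions; infeasible plans (an S/T site at p−2 of a
class II terminus, a site at a hydrophobic p0) raise instead of silently
bending the plan. The scenario fixtures plant enabling switches at p−3
and disabling at p−2 with λ-ratio 4 (defaults: 6 peptides per position
group, 3 replicates), and the `pre_phospho_shift` scenario plants one
wild-type entry with a threefold expected fraction shift between
conditions; expected scores and folds are computed from the truth model,
not hard-coded.

All randomness flows from one integer seed through per-sample
`numpy` generators, so identical seed and configuration reproduce FASTQ
byte-identically.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at 50,000
reads × 3 replicates on designs of ~25 peptides (~48 entries), and check
the mismatch index against an exhaustive oracle on 1,000 entries × 10,000
queries at m = 3 — sizes chosen so the statistical claims (3-SE
multinomial bounds, chi-square goodness of fit at α = 0.01, recovery
thresholds 0.75/0.25) are comfortably powered while a complete run stays
in tens of seconds. Fraction sums are checked to 1e-12; t-tests on
zero-variance data return untestable flags rather than propagating
division by zero; BH q-values are computed per bait only over testable
cells.

## Known limitations

- Ungapped mapping cannot rescue reads with indels; they fall into
  `unmapped`/`nonsynonymous`.
- Paired-end merging, adapter trimming beyond flank anchoring, UMIs, and
  quality recalibration are out of scope.
- The single-codon reverse translation optimizes reproducibility, not
  expression (no GC balancing or secondary-structure screening).
- Class fractions of a real design depend on the configured Φ set; the
  default is one conventional hydrophobic alphabet and is exposed in the
  config precisely because the literature does not fix it.
- Logo rendering is a probability heatmap plus IC bars; the PWM TSVs
  carry everything a dedicated logo tool needs.
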