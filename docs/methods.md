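# Methods

This note records the models, conventions and numerical choices behind
`plastcub`, and what the synthetic-data experiments do and do not show.

## Genetic code and CDS filtering

All statistics use NCBI translation table 11 (bacterial/plastid), whose
synonymous-family structure coincides with the standard code: nine 2-fold
families, Ile as the only 3-fold family, five 4-fold families, three
6-fold families (Leu, Ser, Arg), and the single-codon Met and Trp.
Alternative start codons (GTG, TTG, …) are accepted as starts and
translated as Met.

A CDS is retained only if it is pure A/C/G/T, length-divisible by 3, at
least two codons, starts with a start codon, ends with a stop codon, and
has no internal stop. Ambiguous sequences are dropped whole rather than
masked, because every downstream count assumes a four-letter alphabet.
Genes annotated twice (e.g. duplicated in the two large structural IR
regions of a plastome) are kept as separate records with suffixed
identifiers; no deduplication is attempted. Coordinates are 1-based
inclusive everywhere a position is reported.

## Compositional conventions

Stop codons are excluded from every coding-sequence aggregate. GC1/GC2/GC3
are plain per-position G+C fractions over sense codons. The synonymous
third-position statistics follow the codonW convention: X3s has as
numerator the synonymous codons (families of size ≥ 2; Met/Trp/stops
excluded) ending in X, and as denominator the synonymous codons whose
family *contains* an X-ending member. The denominator differs per base, so
A3s+T3s+G3s+C3s generally exceeds 1; GC3s is the plain share of G/C-ending
synonymous codons. Pooled (genome-level) profiles pool codons rather than
averaging per-gene values; the PR2 genome summary is the exception — it is
an unweighted mean of per-gene coordinates, since that is how per-genome
PR2 values are conventionally reported. Dinucleotides are counted within
genes (never across gene boundaries), and their expectation is the product
of mononucleotide fractions of the same sequence set.

## Index definitions and edge cases

**RSCU** is n_j X_ij / Σ X_ij per family; empty families give missing
values, not zeros. **CAI** is the geometric mean of w_i = RSCU_i /
RSCU_i,max over a gene's codons, excluding Met, Trp and stops (single-codon
families carry no choice information); codons absent from the reference set
get w = 0.01, the standard guard against log 0 and smaller than any
observed w. **RCB** compares a codon's frequency with the product of its
positional base frequencies, both computed over the same sense-codon set
(genome-pooled by default; a per-gene mode exists). **MRCBS** mirrors CAI
with RCBS = 1 + RCB normalised by the family maximum, same eligibility
rules, same floor.

**Wright's NC** averages the family homozygosity F = (m Σ p_i² − 1)/(m − 1)
within each degeneracy class, using only families with m ≥ 2 occurrences.
A missing 3-fold class (Ile unused) is imputed as (F̄₂+F̄₄)/2; a missing
2-, 4- or 6-fold class, or a class mean of 0 (ultra-short genes), makes NC
undefined (reported missing, never guessed). The result is capped to
[20, 61] — only at the ends; no internal cap. The expected curve is
NC(S) = 2 + S + 29/(S² + (1−S)²), defined on [0, 1].

CAI values are comparable only under a common reference. Within one genome
the reference is the pooled CDS set of that genome. When genomes are ranked
against each other — as in the bias-strength recovery experiment — all
gene sets are scored against a single reference pooled across the whole
collection. Self-referenced per-genome CAI is provably non-monotone in the
generator's bias strength (the preferred codon inflates the family RSCU
maximum and devalues the null's remaining A/T-ending codons), which is a
property of the index, not of the implementation.

## Diagnostics

The neutrality fit is ordinary least squares of GC12 on GC3s (the source
analyses report only a "regression line"; OLS is the standard reading),
with slope×100 read as the mutation-pressure share and 100 − slope×100 as
selective constraint — the two always sum to 100 by construction. PHE
calling standardises CAI across genes and labels z > 2 as predicted highly
expressed, z < −2 as predicted low; the same threshold rule can be applied
to MRCBS (`phe_call(..., column="mrcbs")`), an extension the package
documents rather than inherits. PR2 uses all synonymous codons (not only
4-fold families), consistent with the X3s statistics feeding the same
plots.

## Correspondence analysis

Classical CA: correspondence matrix P = X/n, margins r and c, standardised
residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD, principal coordinates
scaled by singular values. Total inertia equals the chi-square statistic of
the table over its grand total (checked in tests to 1e-9). The input is the
raw gene × codon count matrix over the 59 sense codons of degenerate
families — classical CA is defined on counts and 59 is the dimensionality
of that codon space — with an RSCU-matrix mode behind a flag for
sensitivity analysis. Singular values below 1e-12 are treated as zero; SVD
signs are arbitrary, so axes are optionally sign-fixed to make GC3s
correlate non-positively with axis 1, and tests compare |r| wherever a sign
is not pinned.

## Repeat model

A hit is an even-length window scored by its symmetric base pairs
(i, L−1−i): a perfect palindrome has every pair Watson–Crick
complementary; a degenerate palindrome (reported as an inverted repeat)
tolerates at most `max_mismatch` non-complementary pairs, the two central
bases forming an ordinary pair that may consume budget. Each reported hit
is maximal — no one-pair extension on both sides stays within the budget
and the sequence — and overlapping maximal hits from distinct centres are
all reported, since no principled suppression rule exists. Windows touching
an N never match. Defaults for reporting mirror the published tables:
perfect palindromes at > 30 bp, inverted repeats at > 40 bp with 1–2
mismatched pairs. The five published plastome repeat rows validate the
model: the two perfect palindromes (48, 40 bp) have zero mismatched pairs,
and the three printed inverted repeats (56, 58, 48 bp) have exactly 2, 2
and 1 — an arm-plus-spacer model is not needed to reproduce them. Circular
genomes are scanned with a wrap-around window (default twice the minimum
length) so origin-spanning hits are seen once, with modular coordinates;
hits longer than the wrap window would be truncated at the artificial
boundary, so the wrap should be set to twice the longest expected hit.

## Synthetic genomes: what they emulate

`sample_cds` draws amino-acid sequences from a fixed Leu-rich, Cys-poor
composition (the qualitative plastid profile) and, per codon, uses the
family's preferred A/T-ending codon with probability θ, otherwise a
third-position-tilted null whose G+C probability at the third base equals
`gc3_target` (default 0.26, the AT-rich plastid regime). θ = 0 is the
selection-free null; θ = 1 forces one codon per family (NC = 20). Gene
lengths are normal around `mean_len` (sd 0.25·mean, floor 50 codons);
genes run ATG … TAA.

`sample_cds_neutral` models directional mutation pressure instead: codons
are drawn in proportion to the product of positional base probabilities
with the same G+C probability at *all three* positions, restricted to
sense codons, so the amino-acid composition itself drifts with the
pressure. This is the regime a neutrality plot reads as
mutation-dominated; a per-gene GC gradient under this sampler recovers a
slope near 1 (measured 0.945 at 50 genes × 300 codons), while a θ-gradient
under `sample_cds` with fixed `gc3_target` gives a slope near 0 (measured
0.180). A tilt confined to third positions cannot produce a slope near 1,
because GC12 is pinned by the fixed amino-acid composition — hence the two
separate samplers.

`build_genome` lays genes head-to-tail on the plus strand with random
AT-rich spacers (80–200 bp), optionally splits genes into two-exon CDS
with annotated introns, and plants repeat sequences into chosen intergenic
gaps. The pre-plant scaffold is verified to contain no hit ≥ 30 bp at ≤ 2
mismatches (spacers are resampled until clean), and each planted sequence
is wrapped in a non-complementary A·A guard pair so the planted hit is
maximal and recovered at exactly its ledger coordinates. Everything is
deterministic given the seed.

What passing these experiments does *not* show: the generator has no
IR_A/IR_B structural duplication, no strand asymmetry, no RNA editing, no
realistic gene order or length/expression correlation, and its codons are
i.i.d. within a gene. Recovery of θ or of the mutation/selection regime on
this data demonstrates the estimators' correctness under their own model
assumptions, not their behaviour on real plastomes.

## Problem sizes

The shipped experiments use 50–60 genes of ~300 codons per regime (one
plastome's worth), 2-kb sequences for the scanner/oracle comparison, and
10⁵-codon gene sets for law-of-large-numbers checks — sizes chosen so each
driver and the whole test suite run in well under a minute while keeping
multinomial sampling error far below the effect sizes being asserted.

## Known limitations

GenBank input only (no GFF); one record per file; compound locations are
normalised to a single strand (mixed-strand trans-spliced genes, e.g.
rps12, are not reconstructed); no tAI/Fop/CBI indices; no gapped
(arm-spacer) inverted repeats; NC is undefined rather than estimated for
genes missing a degeneracy class, which biases genome NC means upward for
very short gene sets.
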