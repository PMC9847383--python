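# plastcub

Codon usage bias, compositional diagnostics and palindrome/inverted-repeat
detection for plastid (chloroplast) genomes.

Chloroplast genomes are small, AT-rich and gene-dense, and the choice among
synonymous codons in their protein-coding genes carries the joint signature
of directional mutation pressure and translational selection. This package
implements the full analysis chain a plastome codon-usage study needs —
from an annotated GenBank record to publication-style tables — for people
working on organelle genomics, codon optimisation for chloroplast
transformation, or molecular evolution of plastid genes.

## What it computes

**CDS extraction** (`plastcub.seqio`). GenBank parsing via Biopython with
1-based inclusive coordinates; a CDS is retained only if it is pure
A/C/G/T, length-divisible by 3, starts with a start codon, ends with a stop
codon and has no internal stop (translation table 11). Rejections are
logged with the failing rule.

**Compositional statistics** (`plastcub.composition`). Base fractions,
positional GC (GC1, GC2, GC3, GC12 = (GC1+GC2)/2), and the synonymous
third-position statistics A3s/T3s/G3s/C3s in the codonW convention
(numerator: synonymous codons ending in the base; denominator: synonymous
codons whose family contains a codon ending in that base — the four values
may sum to more than 1). Dinucleotide observed/expected tables, amino-acid
usage, and the protein Gravy (mean Kyte–Doolittle hydropathy) and Aroma
(F+Y+W fraction) scores.

**Codon-bias indices** (`plastcub.indices`), for a gene or a pooled set:

- RSCU_i = X_ij / ((1/n_j) Σ_i X_ij) — usage of codon *i* of amino acid
  *j* relative to its family mean;
- relative adaptiveness w_i = RSCU_i / RSCU_i,max and
  CAI = (Π w_i)^(1/N) over a gene's codons (Sharp & Li; Met, Trp and
  stops excluded, absent reference codons floored at w = 0.01);
- RCB_xyz = f_xyz / (f(x)₁ f(y)₂ f(z)₃) − 1 — codon frequency against
  the positional-independence expectation; RCBS = 1 + RCB;
  MRCBS = (Π RCBS_i / RCBS_i,max)^(1/N), a CAI-like expressivity score;
- Wright's effective number of codons
  NC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with per-family
  F = (m Σ p_i² − 1)/(m − 1), capped to [20, 61], and the
  mutation-only expectation NC(S) = 2 + S + 29/(S² + (1−S)²) at S = GC3s;
- codon classes: optimal (RSCU > 1 and RCB > 0), rare (RSCU < 0.5 and
  RCB < 0), preferred (RSCU > 1), over-represented (RCB > 0).

**Diagnostics** (`plastcub.bias`). PR2 plot coordinates A3/(A3+T3) vs
G3/(G3+C3); neutrality regression of GC12 on GC3s (slope×100 = mutation
share); NC-plot deviations from the expected curve; pairwise Pearson
correlations; PHE (predicted highly expressed) calling at CAI z-score > 2.

**Correspondence analysis** (`plastcub.correspondence`). Classical
chi-square-metric CA of the gene × 59-sense-codon count matrix by SVD,
with axis inertias, gene/codon principal coordinates and axis–covariate
correlations.

**Repeat scanning** (`plastcub.repeats`). Exact and mismatch-tolerant
reverse-complement palindromes: every maximal even-length window whose
symmetric base pairs are Watson–Crick complementary up to a mismatch
budget, with feature-context annotation (gene, "gene (intron)", or
"geneA-geneB" for intergenic hits) and circular-genome wrap-around.

**Synthetic genomes** (`plastcub.synthetic`). Annotated circular genomes
with tunable per-gene bias strength θ, third-position GC target, planted
repeats with a truth ledger, and a mutational-equilibrium sampler for
neutrality-regime data — so every stage is testable without downloads.

## Worked example

```python
from plastcub.synthetic import sample_cds, build_genome
from plastcub.metrics import gene_metrics
from plastcub import bias, scan

genes, _ = sample_cds(60, mean_len=300, theta=0.3, gc3_target=0.26,
                      seed=2022)
metrics = gene_metrics(genes)          # NC, CAI, MRCBS, GC3s, PR2 ... per gene
print(round(metrics["nc"].mean(), 2), round(metrics["cai"].mean(), 3))

fit = bias.neutrality_fit(metrics)
print(round(fit.slope, 3), round(fit.selection_pct, 1))

phe = bias.phe_call(metrics)
print(round(phe.threshold_cai, 3), (phe.per_gene["label"] == "PHE").sum())
```

prints

```
40.67 0.625
-0.39 139.0
0.683 2
```

a moderately biased gene set: mean NC ≈ 40.7 (weak-to-moderate bias), a
neutrality slope near zero (GC12 does not track GC3s, so the third-position
composition is shaped by selection, not genome-wide mutation pressure —
slopes slightly below 0 happen when preferred-codon use anti-correlates
with GC3), a CAI threshold of 0.683 and 2 predicted highly expressed genes.

The numbered drivers under `analysis/` run the full study on synthetic
data: `01_simulate.py` (genomes and regimes), `02_codon_bias_indices.py`,
`03_selection_diagnostics.py`, `04_correspondence.py`, `05_repeats.py`.
Each writes its tables under `results/analysis/` and prints what it found.
The same stages run on real GenBank records via the CLI:

```bash
plastcub report my_plastome.gb --outdir results/my_plastome
```

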