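"""Compositional statistics of coding sequences.

Positional GC (GC1/GC2/GC3, GC12), synonymous third-position composition
(A3s/T3s/G3s/C3s, GC3s), dinucleotide observed/expected tables, amino-acid
usage, and the protein-level Gravy (mean Kyte-Doolittle hydropathy) and
Aroma (aromatic residue fraction) scores.

Two third-position conventions coexist here and must not be confused:

* ``GC3`` is the G+C fraction at the third position of *all* codons.
* The ``X3s`` statistics follow the codonW convention: the numerator
  counts synonymous codons (degenerate families only; Met, Trp and stops
  excluded) ending in base X, while the denominator counts synonymous
  codons whose *family* contains an X-ending member.  Because a codon's
  family can offer several alternative third bases, the four X3s values
  sum to more than 1.  ``GC3s`` uses the plain share: G+C-ending
  synonymous codons over all synonymous codons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from plastcub.genetics import AROMATIC, BASES, KYTE_DOOLITTLE, genetic_code
from plastcub.seqio import GeneRecord


@dataclass(frozen=True)
class CompositionProfile:
    a: float
    c: float
    g: float
    t: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    c3s: float
    g3s: float
    t3s: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ProteinProfile:
    gravy: float
    aroma: float
    aa_usage: dict[str, float]


def _as_list(genes) -> list[GeneRecord]:
    return [genes] if isinstance(genes, GeneRecord) else list(genes)


def composition_profile(genes, code: int = 11) -> CompositionProfile:
    """Pooled compositional profile of one gene or a gene set.

    Stop codons are excluded from every aggregate (positional GC and the
    synonymous statistics); overall base fractions are computed over the
    same sense-codon nucleotides.  Undefined synonymous statistics (no
    synonymous codon able to end in X) come back as NaN, never 0.
    """
    gc = genetic_code(code)
    pos_counts = [Counter(), Counter(), Counter()]
    syn_third = Counter()            # X3s numerators
    syn_possible = Counter()         # X3s denominators
    n_syn = 0
    syn_gc3 = 0
    family_third_bases = {
        aa: frozenset(c[2] for c in codons)
        for aa, codons in gc.families.items()
    }
    for gene in _as_list(genes):
        for codon in gene.codons:
            if codon in gc.stop_codons:
                continue
            for k in range(3):
                pos_counts[k][codon[k]] += 1
            aa = gc.forward[codon]
            if len(gc.families[aa]) >= 2:
                n_syn += 1
                syn_third[codon[2]] += 1
                if codon[2] in "GC":
                    syn_gc3 += 1
                for base in family_third_bases[aa]:
                    syn_possible[base] += 1
    total = sum(pos_counts[0].values()) * 3
    if total == 0:
        raise ValueError("no sense codons in input")
    overall = Counter()
    for k in range(3):
        overall.update(pos_counts[k])
    frac = {b: overall[b] / total for b in BASES}
    n_codons = total // 3

    def gc_at(k: int) -> float:
        return (pos_counts[k]["G"] + pos_counts[k]["C"]) / n_codons

    def x3s(base: str) -> float:
        if syn_possible[base] == 0:
            return math.nan
        return syn_third[base] / syn_possible[base]

    gc1, gc2, gc3 = gc_at(0), gc_at(1), gc_at(2)
    return CompositionProfile(
        a=frac["A"], c=frac["C"], g=frac["G"], t=frac["T"],
        gc=frac["G"] + frac["C"],
        gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2,
        gc3s=(syn_gc3 / n_syn) if n_syn else math.nan,
        a3s=x3s("A"), c3s=x3s("C"), g3s=x3s("G"), t3s=x3s("T"),
    )


def third_position_counts(gene: GeneRecord, code: int = 11) -> dict[str, int]:
    """Third-position base counts over the gene's synonymous codons."""
    gc = genetic_code(code)
    counts = {b: 0 for b in BASES}
    for codon in gene.codons:
        if codon in gc.stop_codons:
            continue
        if len(gc.family_of(codon)) >= 2:
            counts[codon[2]] += 1
    return counts


def dinucleotide_stats(genes) -> pd.DataFrame:
    """Observed vs expected dinucleotide frequencies of a CDS set.

    Overlapping dinucleotides are counted within each gene (never across
    gene boundaries); the expectation is the product of the mononucleotide
    fractions of the same sequence set.  Returns a 16-row frame indexed by
    dinucleotide with columns observed, expected, odds_ratio.
    """
    din = Counter()
    mono = Counter()
    for gene in _as_list(genes):
        seq = gene.nucleotide_sequence
        mono.update(seq)
        for i in range(len(seq) - 1):
            din[seq[i : i + 2]] += 1
    n_din = sum(din.values())
    n_mono = sum(mono.values())
    if n_din == 0:
        raise ValueError("total sequence length must be at least 2")
    rows = []
    for x in BASES:
        for y in BASES:
            obs = din[x + y] / n_din
            exp = (mono[x] / n_mono) * (mono[y] / n_mono)
            rows.append(
                {
                    "dinucleotide": x + y,
                    "observed": obs,
                    "expected": exp,
                    "odds_ratio": obs / exp if exp > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows).set_index("dinucleotide")


def protein_profile(protein: str) -> ProteinProfile:
    if not protein:
        raise ValueError("empty protein")
    unknown = set(protein) - set(KYTE_DOOLITTLE)
    if unknown:
        raise ValueError(f"unknown residue(s): {sorted(unknown)}")
    usage = Counter(protein)
    n = len(protein)
    return ProteinProfile(
        gravy=sum(KYTE_DOOLITTLE[r] for r in protein) / n,
        aroma=sum(1 for r in protein if r in AROMATIC) / n,
        aa_usage={aa: usage[aa] / n for aa in sorted(usage)},
    )


def amino_acid_usage(genes, code: int = 11) -> dict[str, float]:
    """Amino-acid frequencies over all non-stop codons of a gene set."""
    gc = genetic_code(code)
    counts = Counter()
    for gene in _as_list(genes):
        for codon in gene.codons:
            if codon not in gc.stop_codons:
                counts[gc.forward[codon]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sense codons in input")
    return {aa: counts[aa] / total for aa in sorted(counts)}
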