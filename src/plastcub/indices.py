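"""Codon-bias indices.

Implements, for a gene or genome-pooled codon count table:

* RSCU_ij = X_ij / ((1/n_j) * sum_i X_ij): observed count of codon i of
  amino acid j over the family mean; 1 means unbiased usage.
* relative adaptiveness w_i = RSCU_i / RSCU_max(family) and
  CAI = geometric mean of w_i over a gene's codons (Sharp & Li).
* RCB_xyz = f_xyz / (f(x)1 f(y)2 f(z)3) - 1: codon frequency against the
  positional-independence expectation; RCBS = 1 + RCB; MRCBS = geometric
  mean of RCBS_i / RCBS_max(family) over a gene (an expressivity score on
  the same scale as CAI).
* Wright's effective number of codons
  NC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with per-family homozygosity
  F = (m * sum p_i^2 - 1) / (m - 1), averaged within each degeneracy
  class; range [20, 61], and its GC3s-parameterised expectation
  NC(S) = 2 + S + 29 / (S^2 + (1-S)^2).
* the codon classification used for optimal/rare calling:
  optimal = RSCU > 1 and RCB > 0; rare = RSCU < 0.5 and RCB < 0;
  preferred = RSCU > 1; over-represented = RCB > 0.

Single-codon families (Met, Trp) and stop codons never enter the CAI /
MRCBS geometric means, and stop codons are excluded from every count
aggregate (they are tallied in a separate ledger).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from plastcub.genetics import BASES, genetic_code
from plastcub.seqio import GeneRecord

#: floor used for the relative adaptiveness of codons absent from the
#: reference set, the standard guard against log(0) in CAI.
W_FLOOR = 0.01


@dataclass(frozen=True)
class CodonCountTable:
    """Sense-codon counts plus the positional base counts they imply."""

    code: int
    counts: dict[str, int] = field(repr=False)          # sense codons only
    stop_counts: dict[str, int] = field(repr=False)
    positional: tuple[dict[str, int], ...] = field(repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        gc = genetic_code(self.code)
        return sum(self.counts[c] for c in gc.families[aa])


@dataclass(frozen=True)
class CodonIndexTable:
    """Per-codon index table for one reference set (usually a genome)."""

    code: int
    rscu: dict[str, float] = field(repr=False)
    rcb: dict[str, float] = field(repr=False)
    w: dict[str, float] = field(repr=False)              # relative adaptiveness
    classes: dict[str, frozenset[str]] = field(repr=False)

    def rcbs(self, codon: str) -> float:
        return 1.0 + self.rcb[codon]

    def to_frame(self) -> pd.DataFrame:
        gc = genetic_code(self.code)
        rows = []
        for codon in gc.sense_codons:
            rows.append(
                {
                    "amino_acid": gc.forward[codon],
                    "codon": codon,
                    "rcb": self.rcb[codon],
                    "rscu": self.rscu[codon],
                    "w": self.w[codon],
                    "class": ",".join(sorted(self.classes[codon])) or "none",
                }
            )
        return pd.DataFrame(rows).sort_values(["amino_acid", "codon"]).reset_index(drop=True)


def count_codons(genes, code: int = 11) -> CodonCountTable:
    """Tally codons of one gene or a pooled gene set.

    Stop codons go to a separate ledger and are excluded from the family
    structure and from the positional base counts.
    """
    gc = genetic_code(code)
    if isinstance(genes, GeneRecord):
        genes = [genes]
    counts = Counter()
    stops = Counter()
    positional = [Counter(), Counter(), Counter()]
    for gene in genes:
        for codon in gene.codons:
            if codon in gc.stop_codons:
                stops[codon] += 1
                continue
            counts[codon] += 1
            for k in range(3):
                positional[k][codon[k]] += 1
    if sum(counts.values()) == 0:
        raise ValueError("no sense codons in input")
    return CodonCountTable(
        code=code,
        counts={c: counts[c] for c in gc.sense_codons},
        stop_counts=dict(stops),
        positional=tuple({b: p[b] for b in BASES} for p in positional),
    )


def rscu(table: CodonCountTable) -> dict[str, float]:
    """RSCU per sense codon; zero-total families give NaN, not 0."""
    gc = genetic_code(table.code)
    out = {}
    for aa, codons in gc.families.items():
        total = sum(table.counts[c] for c in codons)
        n_j = len(codons)
        for c in codons:
            out[c] = (n_j * table.counts[c] / total) if total else math.nan
    return out


def rcb_table(table: CodonCountTable) -> dict[str, float]:
    """RCB per sense codon from the table's own positional base frequencies."""
    total = table.total
    pos_freq = [
        {b: table.positional[k][b] / total for b in BASES} for k in range(3)
    ]
    out = {}
    for codon, count in table.counts.items():
        expected = (
            pos_freq[0][codon[0]] * pos_freq[1][codon[1]] * pos_freq[2][codon[2]]
        )
        if expected == 0:
            if count > 0:
                raise ValueError(
                    f"codon {codon} observed but its expected frequency is 0 "
                    "(inconsistent table)"
                )
            out[codon] = math.nan
        else:
            out[codon] = (count / total) / expected - 1.0
    return out


def classify_codons(
    rscu_values: dict[str, float], rcb_values: dict[str, float]
) -> dict[str, frozenset[str]]:
    out = {}
    for codon in rscu_values:
        flags = set()
        r, b = rscu_values[codon], rcb_values[codon]
        if not (math.isnan(r) or math.isnan(b)):
            if r > 1:
                flags.add("preferred")
            if b > 0:
                flags.add("over_represented")
            if r > 1 and b > 0:
                flags.add("optimal")
            if r < 0.5 and b < 0:
                flags.add("rare")
        out[codon] = frozenset(flags)
    return out


def index_table(table: CodonCountTable) -> CodonIndexTable:
    """Build the full per-codon index table for a reference count table."""
    gc = genetic_code(table.code)
    rscu_v = rscu(table)
    rcb_v = rcb_table(table)
    w = {}
    for aa, codons in gc.families.items():
        family_max = max((rscu_v[c] for c in codons
                          if not math.isnan(rscu_v[c])), default=math.nan)
        for c in codons:
            if math.isnan(rscu_v[c]) or table.counts[c] == 0 or family_max <= 0:
                w[c] = W_FLOOR
            else:
                w[c] = rscu_v[c] / family_max
    return CodonIndexTable(
        code=table.code,
        rscu=rscu_v,
        rcb=rcb_v,
        w=w,
        classes=classify_codons(rscu_v, rcb_v),
    )


def _eligible_codons(gene: GeneRecord, code: int) -> list[str]:
    """Gene codons that enter the CAI/MRCBS geometric means."""
    gc = genetic_code(code)
    return [
        c
        for c in gene.codons
        if c not in gc.stop_codons and len(gc.family_of(c)) >= 2
    ]


def cai(gene: GeneRecord, reference: CodonIndexTable) -> float:
    """Codon Adaptation Index of a gene against a reference index table."""
    codons = _eligible_codons(gene, reference.code)
    if not codons:
        raise ValueError(f"gene {gene.gene_id}: no codons eligible for CAI")
    log_sum = sum(math.log(max(reference.w[c], W_FLOOR)) for c in codons)
    return math.exp(log_sum / len(codons))


def mrcbs(gene: GeneRecord, genome_rcbs: CodonIndexTable) -> float:
    """Modified relative codon bias strength of a gene.

    Geometric mean over the gene's codons of RCBS_i / RCBS_max(family),
    with the same codon-eligibility rules as CAI.  Codons absent from the
    reference (RCBS <= 0) contribute the same floor CAI uses.
    """
    gc = genetic_code(genome_rcbs.code)
    codons = _eligible_codons(gene, genome_rcbs.code)
    if not codons:
        raise ValueError(f"gene {gene.gene_id}: no codons eligible for MRCBS")
    family_max = {
        aa: max(genome_rcbs.rcbs(c) for c in fam
                if not math.isnan(genome_rcbs.rcb[c]))
        for aa, fam in gc.families.items()
        if any(not math.isnan(genome_rcbs.rcb[c]) for c in fam)
    }
    log_sum = 0.0
    for c in codons:
        fmax = family_max.get(gc.forward[c], math.nan)
        value = genome_rcbs.rcbs(c)
        ratio = value / fmax if (fmax and fmax > 0 and value > 0) else W_FLOOR
        log_sum += math.log(max(ratio, W_FLOOR))
    return math.exp(log_sum / len(codons))


def nc_wright(gene: GeneRecord, code: int = 11) -> float:
    """Wright's effective number of codons for one gene.

    Families with fewer than 2 occurrences are uninformative.  The 3-fold
    class (Ile alone in the standard structure) is imputed as the mean of
    the 2-fold and 4-fold class values when missing; a missing 2-, 4- or
    6-fold class makes NC undefined (NaN).  The result is capped to
    [20, 61].
    """
    gc = genetic_code(code)
    counts = Counter(c for c in gene.codons if c not in gc.stop_codons)
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in gc.families.items():
        k = len(codons)
        if k < 2:
            continue
        m = sum(counts[c] for c in codons)
        if m < 2:
            continue
        sum_p2 = sum((counts[c] / m) ** 2 for c in codons)
        class_f[k].append((m * sum_p2 - 1) / (m - 1))

    def mean(vals: list[float]) -> float:
        return sum(vals) / len(vals) if vals else math.nan

    f2, f3, f4, f6 = (mean(class_f[k]) for k in (2, 3, 4, 6))
    if math.isnan(f3) and not (math.isnan(f2) or math.isnan(f4)):
        f3 = (f2 + f4) / 2
    if any(math.isnan(f) or f <= 0 for f in (f2, f3, f4, f6)):
        return math.nan
    nc = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
    return min(61.0, max(20.0, nc))


def expected_nc(gc3s: float) -> float:
    """Expected NC from GC3s under pure mutational pressure:
    NC(S) = 2 + S + 29 / (S^2 + (1-S)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {gc3s}")
    return 2 + gc3s + 29 / (gc3s**2 + (1 - gc3s) ** 2)
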