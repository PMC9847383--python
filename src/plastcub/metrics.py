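"""Per-gene scalar metrics: one row per gene, the substrate of every
diagnostic plot (PR2, neutrality, NC-plot, correlations, CA covariates)."""

from __future__ import annotations

import math

import pandas as pd

from plastcub.composition import (
    composition_profile,
    protein_profile,
    third_position_counts,
)
from plastcub.indices import (
    CodonIndexTable,
    cai,
    count_codons,
    index_table,
    mrcbs,
    nc_wright,
)
from plastcub.seqio import GeneRecord

METRIC_COLUMNS = [
    "gene_id", "length_codons", "gc", "gc1", "gc2", "gc3", "gc12", "gc3s",
    "a3s", "c3s", "g3s", "t3s", "gc3_skew", "nc", "cai", "mrcbs",
    "gravy", "aroma", "pr2_at", "pr2_gc",
]


def gene_metrics(
    genes: list[GeneRecord],
    reference: CodonIndexTable | None = None,
    code: int = 11,
) -> pd.DataFrame:
    """Compute the full per-gene metrics table.

    ``reference`` is the codon index table CAI and MRCBS are scored
    against; by default it is built from the pooled input set itself
    (CAI "in reference to all protein-coding genes").
    """
    if reference is None:
        reference = index_table(count_codons(genes, code))
    rows = []
    for gene in genes:
        prof = composition_profile(gene, code)
        third = third_position_counts(gene, code)
        at = third["A"] + third["T"]
        gcc = third["G"] + third["C"]
        protein = protein_profile(gene.aa_sequence) if gene.aa_sequence else None
        rows.append(
            {
                "gene_id": gene.gene_id,
                "length_codons": gene.length_codons,
                "gc": prof.gc,
                "gc1": prof.gc1,
                "gc2": prof.gc2,
                "gc3": prof.gc3,
                "gc12": prof.gc12,
                "gc3s": prof.gc3s,
                "a3s": prof.a3s,
                "c3s": prof.c3s,
                "g3s": prof.g3s,
                "t3s": prof.t3s,
                "gc3_skew": ((third["G"] - third["C"]) / gcc) if gcc else math.nan,
                "nc": nc_wright(gene, code),
                "cai": cai(gene, reference),
                "mrcbs": mrcbs(gene, reference),
                "gravy": protein.gravy if protein else math.nan,
                "aroma": protein.aroma if protein else math.nan,
                "pr2_at": (third["A"] / at) if at else math.nan,
                "pr2_gc": (third["G"] / gcc) if gcc else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
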