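#!/usr/bin/env python
"""Compositional statistics and codon-bias indices of the study genome.

Emits the composition profile, the dinucleotide table, the per-codon
RSCU/RCB/classification table and the amino-acid usage, and prints the
headline numbers.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study import study_genes

from plastcub.composition import (
    amino_acid_usage,
    composition_profile,
    dinucleotide_stats,
)
from plastcub.indices import count_codons, index_table

RESULTS = Path("results/analysis")


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    genes, _ = study_genes()

    prof = composition_profile(genes).as_dict()
    pd.DataFrame({"statistic": list(prof), "value": list(prof.values())}).to_csv(
        RESULTS / "02_composition.tsv", sep="\t", index=False,
        float_format="%.4f",
    )
    dinucleotide_stats(genes).to_csv(
        RESULTS / "02_dinucleotides.tsv", sep="\t", float_format="%.4f"
    )
    ref = index_table(count_codons(genes))
    table = ref.to_frame()
    table.to_csv(RESULTS / "02_codon_indices.tsv", sep="\t", index=False,
                 float_format="%.4f")
    usage = amino_acid_usage(genes)
    pd.DataFrame({"amino_acid": list(usage), "frequency": list(usage.values())}).to_csv(
        RESULTS / "02_amino_acid_usage.tsv", sep="\t", index=False,
        float_format="%.4f",
    )

    optimal = table[table["class"].str.contains("optimal")]
    print(f"coding GC {prof['gc']:.4f}; GC1/GC2/GC3 "
          f"{prof['gc1']:.4f}/{prof['gc2']:.4f}/{prof['gc3']:.4f}; "
          f"GC3s {prof['gc3s']:.4f}")
    print(f"{len(optimal)} optimal codons (RSCU>1 and RCB>0), "
          f"{(table['class'].str.contains('rare')).sum()} rare codons")
    at_ending = (optimal["codon"].str[2].isin(list("AT"))).mean()
    print(f"{at_ending:.0%} of optimal codons end in A or T")
    top_aa = max(usage, key=usage.get)
    print(f"most-used amino acid: {top_aa} ({usage[top_aa]:.2%})")


if __name__ == "__main__":
    main()
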