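#!/usr/bin/env python
"""Generate the study's synthetic genomes and gene sets.

Writes the annotated genome (GenBank + CDS FASTA + truth ledger) under
scratch/ (bulky, regenerable) and a small design summary under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study import STUDY_SEED, neutral_genes, selection_gradient_genes, study_genome

from plastcub.seqio import write_cds_fasta, write_genbank, extract_cds

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome, truth = study_genome()
    write_genbank(genome, SCRATCH / "synplast1.gb")
    truth.to_json(SCRATCH / "synplast1_truth.json")
    genes, rejections = extract_cds(genome)
    write_cds_fasta(genes, SCRATCH / "synplast1_cds.fasta")

    neutral, _ = neutral_genes()
    write_cds_fasta(neutral, SCRATCH / "neutral_cds.fasta")
    selected, _ = selection_gradient_genes()
    write_cds_fasta(selected, SCRATCH / "selection_cds.fasta")

    design = pd.DataFrame(
        [
            {"dataset": "synplast1", "n_genes": len(genes),
             "length_bp": genome.length, "planted_repeats": len(truth.repeats),
             "seed": STUDY_SEED},
            {"dataset": "neutral_gradient", "n_genes": len(neutral),
             "length_bp": sum(3 * g.length_codons for g in neutral),
             "planted_repeats": 0, "seed": STUDY_SEED + 1},
            {"dataset": "selection_gradient", "n_genes": len(selected),
             "length_bp": sum(3 * g.length_codons for g in selected),
             "planted_repeats": 0, "seed": STUDY_SEED + 2},
        ]
    )
    design.to_csv(RESULTS / "01_datasets.tsv", sep="\t", index=False)
    print(f"synplast1: {genome.length} bp, {len(genes)} CDS retained, "
          f"{len(rejections)} rejected, {len(truth.repeats)} planted repeats")
    print(f"neutral gradient: {len(neutral)} genes; "
          f"selection gradient: {len(selected)} genes")
    print(f"artifacts in {SCRATCH}, design table in {RESULTS}/01_datasets.tsv")


if __name__ == "__main__":
    main()
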