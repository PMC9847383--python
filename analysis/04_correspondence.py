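#!/usr/bin/env python
"""Correspondence analysis of the study genome's codon usage.

CA on the gene x 59-sense-codon count matrix: axis inertias, gene and
codon coordinates, and the axis-covariate correlation table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import study_genes

from plastcub.correspondence import (
    axis_covariate_correlations,
    ca,
    codon_matrix,
    orient_axes,
)
from plastcub.metrics import gene_metrics

RESULTS = Path("results/analysis")


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    genes, truth = study_genes()
    metrics = gene_metrics(genes)
    result = orient_axes(ca(codon_matrix(genes), n_axes=4), metrics)

    result.inertia_frame().to_csv(RESULTS / "04_ca_inertia.tsv", sep="\t",
                                  index=False, float_format="%.4f")
    result.row_coords.to_csv(RESULTS / "04_ca_genes.tsv", sep="\t",
                             float_format="%.4f")
    result.col_coords.to_csv(RESULTS / "04_ca_codons.tsv", sep="\t",
                             float_format="%.4f")
    corr = axis_covariate_correlations(result, metrics)
    corr.to_csv(RESULTS / "04_ca_correlations.tsv", sep="\t", index=False,
                float_format="%.4f")

    pct = result.inertia_pct
    print(f"axis 1 carries {pct[0]:.2f}% of total inertia, axis 2 "
          f"{pct[1]:.2f}% (total inertia {result.total_inertia:.4f})")
    top = corr.loc[corr["pearson_r"].abs().idxmax()]
    print(f"strongest axis-covariate correlation: axis {int(top['axis'])} "
          f"vs {top['covariate']} (r = {top['pearson_r']:.3f})")


if __name__ == "__main__":
    main()
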