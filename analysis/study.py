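"""Shared study conditions for the analysis drivers.

One synthetic plastid-like genome under moderate translational selection
is the running example; a neutral (mutation-gradient) gene set and a
bias-gradient gene set supply the two regimes the diagnostics separate.
All seeds are fixed so every driver is reproducible stand-alone.
"""

from __future__ import annotations

import numpy as np

from plastcub.synthetic import build_genome, sample_cds, sample_cds_neutral

STUDY_SEED = 2022

# Published plastome repeats used as planting material.
PALINDROME_48 = "AGTTGAAGTACTGAGCCTCCCGATATCGGGAGGCTCAGTACTTCAACT"
IR_56 = "TATAAGTGAACTAGATAAAGCGGAATCAAGATTCCGTTTTATCTAGTTCACTTATA"


def study_genes(n_genes: int = 60):
    """Moderately selected, AT-rich gene set (the study's main conditions)."""
    return sample_cds(n_genes, mean_len=300, theta=0.3, gc3_target=0.26,
                      seed=STUDY_SEED)


def study_genome():
    """The main annotated genome: study genes plus two planted repeats and
    one intron-bearing gene."""
    genes, _ = study_genes()
    return build_genome(
        genes,
        repeats_spec=[(PALINDROME_48, 20), (IR_56, 40)],
        seed=STUDY_SEED,
        intron_genes={10: 120},
        accession="SYNPLAST1",
    )


def neutral_genes(n_genes: int = 50):
    """Mutation-gradient regime: per-gene G+C pressure on all positions."""
    gradient = np.linspace(0.2, 0.6, n_genes)
    return sample_cds_neutral(n_genes, mean_len=300, gc_target=gradient,
                              seed=STUDY_SEED + 1)


def selection_gradient_genes(n_genes: int = 50):
    """Selection-gradient regime: per-gene bias strength, fixed GC3 target."""
    theta = np.linspace(0.0, 1.0, n_genes)
    return sample_cds(n_genes, mean_len=300, theta=theta, gc3_target=0.3,
                      seed=STUDY_SEED + 2)
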