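from __future__ import annotations

import pytest

from plastcub.seqio import GeneRecord
from plastcub.synthetic import build_genome, sample_cds

PALINDROME_48 = "AGTTGAAGTACTGAGCCTCCCGATATCGGGAGGCTCAGTACTTCAACT"
PALINDROME_40 = "TTACTTTTTTTATTTAGAAATTTCTAAATAAAAAAAGTAA"


def make_gene(codons, gene_id="g1", aa_sequence=""):
    """Construct a GeneRecord directly from a codon list (test helper)."""
    return GeneRecord(gene_id=gene_id, codons=tuple(codons),
                      aa_sequence=aa_sequence)


@pytest.fixture(scope="session")
def small_gene_set():
    """20 moderately biased genes, deterministic."""
    genes, _ = sample_cds(20, mean_len=200, theta=0.3, gc3_target=0.26,
                          seed=11)
    return genes


@pytest.fixture(scope="session")
def planted_genome():
    """Synthetic circular genome with two planted palindromes."""
    genes, _ = sample_cds(8, mean_len=120, theta=0.2, seed=7)
    genome, truth = build_genome(
        genes,
        repeats_spec=[(PALINDROME_48, 2), (PALINDROME_40, 6)],
        seed=7,
    )
    return genome, truth
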