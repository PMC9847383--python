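"""Genetic-code structure shared by every module.

Wraps :mod:`Bio.Data.CodonTable` and precomputes the synonymous-family
structure (amino acid -> codon set, degeneracy classes) that the codon-bias
indices need.  The default is NCBI translation table 11 (bacterial /
plastid), the appropriate code for chloroplast protein-coding genes; its
synonymous families coincide with those of the standard code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

#: Kyte-Doolittle hydropathy index, one value per standard residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


@dataclass(frozen=True)
class GeneticCode:
    """Synonymous-family view of an NCBI translation table."""

    table_id: int
    forward: dict[str, str] = field(repr=False)          # sense codon -> aa
    stop_codons: frozenset[str] = field(repr=False)
    start_codons: frozenset[str] = field(repr=False)
    families: dict[str, tuple[str, ...]] = field(repr=False)  # aa -> codons

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(self.forward)

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """Codons of degenerate families (degeneracy >= 2)."""
        return tuple(
            c for c in self.forward if len(self.families[self.forward[c]]) >= 2
        )

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.forward[codon]]

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Map family size k -> amino acids with exactly k codons."""
        out: dict[int, list[str]] = {}
        for aa, codons in self.families.items():
            out.setdefault(len(codons), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in out.items()}


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(sorted(table.forward_table.items()))
    families: dict[str, list[str]] = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        forward=forward,
        stop_codons=frozenset(table.stop_codons),
        start_codons=frozenset(table.start_codons),
        families={aa: tuple(cs) for aa, cs in families.items()},
    )
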