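"""Reading annotated genomes, CDS filtering and codon-level records.

GenBank parsing is delegated to Biopython; this module converts features to
1-based inclusive coordinates (the convention used for all reported
locations), applies the CDS retention filters, and exposes clean
codon-level :class:`GeneRecord` objects for the downstream statistics.

Retention rules for a CDS: pure {A,C,G,T} sequence, length divisible by 3,
at least two codons, a start codon first, a stop codon last, and no
internal stop.  Failing features are reported with the failing rule, never
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from plastcub.genetics import genetic_code

_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}


@dataclass(frozen=True)
class FeatureSpan:
    """One annotated feature, 1-based inclusive coordinates."""

    kind: str                      # CDS | tRNA | rRNA | intron | other
    gene_name: str
    start: int
    end: int
    strand: str                    # '+' or '-'
    parts: tuple[tuple[int, int], ...] = ()   # exons for compound locations

    def __post_init__(self):
        parts = self.parts or ((self.start, self.end),)
        object.__setattr__(self, "parts", tuple(parts))
        for s, e in self.parts:
            if s > e:
                raise ValueError(f"feature part {s}-{e}: start > end")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)


@dataclass(frozen=True)
class GenomeRecord:
    accession: str
    sequence: str
    features: tuple[FeatureSpan, ...]
    topology: str = "linear"       # 'circular' or 'linear'

    def __post_init__(self):
        for f in self.features:
            if f.start < 1 or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.gene_name} ({f.start}-{f.end}) outside "
                    f"genome of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """One retained CDS split into codons."""

    gene_id: str
    codons: tuple[str, ...]
    aa_sequence: str
    source_span: FeatureSpan | None = None

    @property
    def length_codons(self) -> int:
        return len(self.codons)

    @property
    def nucleotide_sequence(self) -> str:
        return "".join(self.codons)


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    reason: str


class GenBankParseError(ValueError):
    pass


class InternalStopError(ValueError):
    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon {codon} at codon index {codon_index}")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    Coordinates are converted from Biopython's 0-based half-open to
    1-based inclusive; compound (joined) locations keep their parts.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:   # Biopython raises bare ValueError with context
        raise GenBankParseError(f"cannot parse {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise GenBankParseError(f"{path}: record {record.id} has no sequence")
    features = []
    for feat in record.features:
        if feat.type == "source":
            continue
        kind = _FEATURE_KINDS.get(feat.type, "other")
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        loc = feat.location
        if loc is None:
            continue
        parts = sorted(
            (int(p.start) + 1, int(p.end)) for p in loc.parts
        )
        strand = "-" if loc.strand == -1 else "+"
        features.append(
            FeatureSpan(
                kind=kind,
                gene_name=name,
                start=parts[0][0],
                end=parts[-1][1],
                strand=strand,
                parts=tuple(parts),
            )
        )
    topology = record.annotations.get("topology", "linear")
    return GenomeRecord(
        accession=record.id or record.name,
        sequence=seq,
        features=tuple(features),
        topology=topology,
    )


def feature_sequence(genome: GenomeRecord, span: FeatureSpan) -> str:
    """Spliced, strand-corrected nucleotide sequence of a feature."""
    joined = "".join(genome.sequence[s - 1 : e] for s, e in span.parts)
    return _revcomp(joined) if span.strand == "-" else joined


def extract_cds(
    genome: GenomeRecord, code: int = 11
) -> tuple[list[GeneRecord], list[Rejection]]:
    """Apply the CDS retention filters and split retained genes into codons.

    Returns (retained genes, rejections).  Duplicate gene names (e.g. genes
    duplicated in the two IR regions of a plastome) are kept as separate
    records with ``name``, ``name_2``, ... identifiers.
    """
    gc = genetic_code(code)
    genes: list[GeneRecord] = []
    rejections: list[Rejection] = []
    seen: dict[str, int] = {}
    for span in genome.features:
        if span.kind != "CDS":
            continue
        n = seen.get(span.gene_name, 0) + 1
        seen[span.gene_name] = n
        gene_id = span.gene_name if n == 1 else f"{span.gene_name}_{n}"
        seq = feature_sequence(genome, span)
        reason = None
        if any(b not in "ACGT" for b in seq):
            reason = "ambiguous base"
        elif len(seq) % 3 != 0:
            reason = "length not divisible by 3"
        elif len(seq) < 6:
            reason = "fewer than two codons"
        if reason is None:
            codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
            if codons[0] not in gc.start_codons:
                reason = "missing start codon"
            elif codons[-1] not in gc.stop_codons:
                reason = "missing stop codon"
            else:
                internal = [
                    i for i, c in enumerate(codons[:-1]) if c in gc.stop_codons
                ]
                if internal:
                    reason = f"internal stop codon at codon {internal[0]}"
        if reason is not None:
            rejections.append(Rejection(gene_id, reason))
            continue
        record = GeneRecord(gene_id=gene_id, codons=codons, aa_sequence="",
                            source_span=span)
        record = replace(record, aa_sequence=translate(record, code))
        genes.append(record)
    return genes, rejections


def translate(gene: GeneRecord, code: int = 11) -> str:
    """Translate a retained CDS; one residue per non-stop codon.

    The initiator codon is rendered as Met when it is a start codon of the
    table (GTG/TTG starts are translated by initiator tRNA-fMet).  A stop
    codon before the final position raises :class:`InternalStopError`.
    """
    gc = genetic_code(code)
    codons = gene.codons
    if codons and codons[-1] in gc.stop_codons:
        codons = codons[:-1]
    residues = []
    for i, codon in enumerate(codons):
        if codon in gc.stop_codons:
            raise InternalStopError(i, codon)
        if i == 0 and codon in gc.start_codons:
            residues.append("M")
        else:
            residues.append(gc.forward[codon])
    return "".join(residues)


# ---------------------------------------------------------------------------
# FASTA round-trip and output tables

def write_cds_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    """One CDS per record, header ``gene_id|start-end|strand``."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.source_span
            coord = f"{span.start}-{span.end}|{span.strand}" if span else "?-?|+"
            fh.write(f">{g.gene_id}|{coord}\n")
            seq = g.nucleotide_sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_cds_fasta(path: str | Path, code: int = 11) -> list[GeneRecord]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        gene_id = fields[0]
        span = None
        if len(fields) >= 3 and "-" in fields[1]:
            s, _, e = fields[1].partition("-")
            if s.isdigit() and e.isdigit():
                span = FeatureSpan("CDS", gene_id, int(s), int(e), fields[2])
        seq = str(rec.seq).upper()
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        gene = GeneRecord(gene_id=gene_id, codons=codons, aa_sequence="",
                          source_span=span)
        genes.append(replace(gene, aa_sequence=translate(gene, code)))
    return genes


def write_rejections(rejections: list[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for r in rejections:
            fh.write(f"{r.gene_id}\t{r.reason}\n")


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Emit a GenBank flat file (used by the synthetic generator)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.replace(".", "_")[:16],
        description="synthetic plastid-like genome",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
        },
    )
    for span in genome.features:
        strand = -1 if span.strand == "-" else 1
        locs = [
            SimpleLocation(s - 1, e, strand=strand) for s, e in span.parts
        ]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = span.kind if span.kind != "other" else "misc_feature"
        record.features.append(
            SeqFeature(loc, type=ftype, qualifiers={"gene": [span.gene_name]})
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")
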