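"""Synthetic annotated genomes with known codon-bias structure.

The generator emulates the study conditions of a plastid genome analysis:
tens of protein-coding genes a few hundred codons long, AT-rich codon
usage, a tunable strength of translational selection, and intergenic
spacers into which reverse-complement palindromes can be planted at known
coordinates.

Two gene samplers model the two forces the diagnostics are meant to
separate:

* :func:`sample_cds` — translational-selection mixture.  Amino-acid
  sequences come from a fixed composition (Leu-rich, Cys-poor, the
  qualitative profile of plastid proteomes); each codon is, with
  probability ``theta``, the family's preferred codon (A/T-ending, as in
  plastid genomes), otherwise a draw from a third-position-tilted null
  whose G+C probability at the third base equals ``gc3_target``.
  ``theta = 0`` is the selection-free null, ``theta = 1`` maximal bias
  (NC -> 20).

* :func:`sample_cds_neutral` — directional mutation pressure.  Codons are
  drawn in proportion to the product of positional base probabilities
  with G+C probability ``gc_target`` at *all three* positions (restricted
  to sense codons), the mutational-equilibrium model under which GC12
  tracks GC3s and a neutrality regression recovers a slope near 1.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from plastcub.genetics import BASES, genetic_code
from plastcub.repeats import _pair_ok, scan
from plastcub.seqio import FeatureSpan, GeneRecord, GenomeRecord, translate

#: Default amino-acid composition: the qualitative plastid profile
#: (leucine-rich, cysteine-poor).  Values are frequencies; they sum to 1.
DEFAULT_AA_COMPOSITION = {
    "L": 0.106, "I": 0.083, "S": 0.078, "G": 0.070, "F": 0.066,
    "R": 0.057, "A": 0.058, "V": 0.059, "T": 0.054, "E": 0.051,
    "K": 0.049, "N": 0.047, "P": 0.044, "D": 0.040, "Q": 0.039,
    "Y": 0.035, "M": 0.024, "W": 0.018, "H": 0.021, "C": 0.011,
}

#: Preferred (A/T-ending) codon per amino acid, mirroring the optimal-codon
#: profile of plastid genomes.
PREFERRED_CODONS = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAT", "I": "ATT",
    "L": "TTA", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

START_CODON = "ATG"
STOP_CODON = "TAA"


@dataclass(frozen=True)
class PlantedRepeat:
    sequence: str
    start: int                     # 1-based inclusive genome coordinates
    end: int
    mismatches: int


@dataclass(frozen=True)
class SyntheticTruth:
    seed: int
    theta: tuple[float, ...] = ()           # per-gene bias strength
    gc3_target: tuple[float, ...] = ()      # per-gene third-position target
    preferred: dict[str, str] = field(default_factory=dict)
    repeats: tuple[PlantedRepeat, ...] = ()
    length_params: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _normalise(freqs: dict[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    return {k: v / total for k, v in freqs.items()}


def _family_third_distribution(code, aa: str, gc3_target: float) -> tuple[list[str], list[float]]:
    """Codon distribution within one family with P(G/C third base) = target."""
    codons = list(code.families[aa])
    gc_end = [c for c in codons if c[2] in "GC"]
    at_end = [c for c in codons if c[2] in "AT"]
    probs = []
    for c in codons:
        if gc_end and at_end:
            p_class = gc3_target if c[2] in "GC" else 1.0 - gc3_target
            group = gc_end if c[2] in "GC" else at_end
        else:
            p_class, group = 1.0, codons
        probs.append(p_class / len(group))
    return codons, probs


def _gene_lengths(rng, n_genes: int, mean_len: float, len_sd: float) -> np.ndarray:
    lengths = rng.normal(mean_len, len_sd, size=n_genes)
    return np.maximum(50, np.round(lengths)).astype(int)


def sample_cds(
    n_genes: int,
    mean_len: int = 300,
    theta: float | np.ndarray = 0.0,
    gc3_target: float | np.ndarray = 0.26,
    seed: int = 0,
    aa_freqs: dict[str, float] | None = None,
    len_sd: float | None = None,
    code: int = 11,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Sample CDS under the translational-selection mixture model.

    ``theta`` and ``gc3_target`` may be scalars or per-gene arrays.  The
    default ``gc3_target`` of 0.26 matches the AT-rich third positions of
    plastid genomes.  Genes begin with ATG and end with TAA; ``mean_len``
    counts the interior (amino-acid) codons.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_len < 50:
        raise ValueError("mean_len must be >= 50 codons")
    theta_arr = np.broadcast_to(np.asarray(theta, dtype=float), (n_genes,))
    gc3_arr = np.broadcast_to(np.asarray(gc3_target, dtype=float), (n_genes,))
    if ((theta_arr < 0) | (theta_arr > 1)).any():
        raise ValueError("theta must lie in [0, 1]")
    if ((gc3_arr < 0) | (gc3_arr > 1)).any():
        raise ValueError("gc3_target must lie in [0, 1]")
    gc = genetic_code(code)
    aa_freqs = _normalise(aa_freqs or DEFAULT_AA_COMPOSITION)
    aa_names = list(aa_freqs)
    aa_probs = np.array([aa_freqs[a] for a in aa_names])
    if len_sd is None:
        len_sd = 0.25 * mean_len
    rng = np.random.default_rng(seed)
    lengths = _gene_lengths(rng, n_genes, mean_len, len_sd)
    genes = []
    for i in range(n_genes):
        th, g3 = float(theta_arr[i]), float(gc3_arr[i])
        dists = {
            aa: _family_third_distribution(gc, aa, g3) for aa in aa_names
        }
        aas = rng.choice(aa_names, size=lengths[i], p=aa_probs)
        codons = [START_CODON]
        use_preferred = rng.random(lengths[i]) < th
        for aa, pref in zip(aas, use_preferred):
            if pref:
                codons.append(PREFERRED_CODONS[aa])
            else:
                fam, probs = dists[aa]
                codons.append(fam[rng.choice(len(fam), p=probs)])
        codons.append(STOP_CODON)
        gene = GeneRecord(
            gene_id=f"synth{i + 1:03d}", codons=tuple(codons), aa_sequence=""
        )
        genes.append(
            GeneRecord(
                gene_id=gene.gene_id,
                codons=gene.codons,
                aa_sequence=translate(gene, code),
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        theta=tuple(theta_arr.tolist()),
        gc3_target=tuple(gc3_arr.tolist()),
        preferred=dict(PREFERRED_CODONS),
        length_params={"mean_len": float(mean_len), "len_sd": float(len_sd)},
    )
    return genes, truth


def sample_cds_neutral(
    n_genes: int,
    mean_len: int = 300,
    gc_target: float | np.ndarray = 0.4,
    seed: int = 0,
    len_sd: float | None = None,
    code: int = 11,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Sample CDS at mutational equilibrium with per-gene G+C pressure.

    Codons are drawn i.i.d. with probability proportional to the product
    of positional base probabilities (G and C each ``gc_target / 2``),
    restricted to sense codons, so all three codon positions feel the same
    directional pressure — the regime a neutrality plot reads as
    mutation-dominated (slope near 1).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gc_arr = np.broadcast_to(np.asarray(gc_target, dtype=float), (n_genes,))
    if ((gc_arr <= 0) | (gc_arr >= 1)).any():
        raise ValueError("gc_target must lie in (0, 1)")
    gc = genetic_code(code)
    sense = list(gc.sense_codons)
    if len_sd is None:
        len_sd = 0.25 * mean_len
    rng = np.random.default_rng(seed)
    lengths = _gene_lengths(rng, n_genes, mean_len, len_sd)
    genes = []
    for i in range(n_genes):
        g = float(gc_arr[i])
        p = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
        weights = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in sense])
        weights /= weights.sum()
        draws = rng.choice(len(sense), size=lengths[i], p=weights)
        codons = (START_CODON, *(sense[j] for j in draws), STOP_CODON)
        gene = GeneRecord(gene_id=f"neut{i + 1:03d}", codons=codons,
                          aa_sequence="")
        genes.append(
            GeneRecord(gene_id=gene.gene_id, codons=codons,
                       aa_sequence=translate(gene, code))
        )
    truth = SyntheticTruth(
        seed=seed,
        theta=tuple([0.0] * n_genes),
        gc3_target=tuple(gc_arr.tolist()),
        preferred={},
        length_params={"mean_len": float(mean_len), "len_sd": float(len_sd)},
    )
    return genes, truth


def _count_mismatches(seq: str) -> int:
    L = len(seq)
    return sum(
        0 if _pair_ok(seq[i], seq[L - 1 - i]) else 1 for i in range(L // 2)
    )


def _random_spacer(rng, length: int) -> str:
    # AT-rich like plastid intergenic DNA
    return "".join(
        rng.choice(list(BASES), size=length, p=[0.32, 0.18, 0.18, 0.32])
    )


def build_genome(
    genes: list[GeneRecord],
    repeats_spec: list[tuple[str, int]] | None = None,
    seed: int = 0,
    spacer_len: tuple[int, int] = (80, 200),
    intron_genes: dict[int, int] | None = None,
    check_min_len: int = 30,
    check_max_mismatch: int = 2,
    accession: str | None = None,
    max_tries: int = 50,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Assemble genes into an annotated circular genome.

    Genes are laid head-to-tail on the plus strand with random AT-rich
    spacers; ``repeats_spec`` plants sequences into the middle of chosen
    intergenic gaps (gap i precedes gene i; gap ``len(genes)`` is the
    terminal spacer) and records their coordinates in the truth ledger.
    ``intron_genes`` maps gene index -> intron length; those genes become
    two-exon CDS features with an annotated intron between the exons.
    The pre-plant scaffold is verified to contain no hit of length
    >= ``check_min_len`` at ``check_max_mismatch`` mismatches; spacers are
    resampled until it is clean (an unlucky palindrome inside a gene
    raises after ``max_tries``).
    """
    repeats_spec = list(repeats_spec or [])
    intron_genes = dict(intron_genes or {})
    n_gaps = len(genes) + 1
    gap_of = {}
    for seqr, gap in repeats_spec:
        if not 0 <= gap < n_gaps:
            raise ValueError(f"gap index {gap} out of range (0..{n_gaps - 1})")
        if gap in gap_of:
            raise ValueError(f"planting collision: two repeats in gap {gap}")
        gap_of[gap] = seqr.upper()
    rng = np.random.default_rng(seed)

    for attempt in range(max_tries):
        spacers = [
            _random_spacer(rng, int(rng.integers(*spacer_len)))
            for _ in range(n_gaps)
        ]
        introns = {
            i: _random_spacer(rng, length) for i, length in intron_genes.items()
        }
        segments = []
        features: list[FeatureSpan] = []
        pos = 0                      # 0-based running offset
        for i, gene in enumerate(genes):
            segments.append(spacers[i])
            pos += len(spacers[i])
            seq = gene.nucleotide_sequence
            if i in introns:
                half = (len(seq) // 6) * 3   # split at a codon boundary
                exon1, exon2 = seq[:half], seq[half:]
                s1 = pos + 1
                e1 = pos + len(exon1)
                s2 = e1 + len(introns[i]) + 1
                e2 = s2 + len(exon2) - 1
                segments.extend([exon1, introns[i], exon2])
                features.append(
                    FeatureSpan("CDS", gene.gene_id, s1, e2, "+",
                                parts=((s1, e1), (s2, e2)))
                )
                features.append(
                    FeatureSpan("intron", gene.gene_id, e1 + 1, s2 - 1, "+")
                )
                pos = e2
            else:
                start = pos + 1
                end = pos + len(seq)
                segments.append(seq)
                features.append(FeatureSpan("CDS", gene.gene_id, start, end, "+"))
                pos = end
        segments.append(spacers[-1])
        pos += len(spacers[-1])
        scaffold = "".join(segments)
        if not scan(scaffold, min_len=check_min_len,
                    max_mismatch=check_max_mismatch):
            break
    else:
        raise RuntimeError(
            f"could not assemble a repeat-free scaffold in {max_tries} tries "
            "(a gene itself may contain a long palindrome)"
        )

    # plant repeats by insertion into the middle of their spacers
    ledger = []
    if gap_of:
        # recompute insertion offsets gap by gap, left to right
        final = scaffold
        shift = 0
        gap_bounds = []
        pos = 0
        for i in range(len(genes)):
            gap_bounds.append((pos, pos + len(spacers[i])))
            pos += len(spacers[i])
            gene_len = sum(
                e - s + 1 for s, e in features[_feature_index(features, i)].parts
            )
            pos += gene_len + (len(introns[i]) if i in introns else 0)
        gap_bounds.append((pos, pos + len(spacers[-1])))
        for gap in sorted(gap_of):
            ins_seq = gap_of[gap]
            lo, hi = gap_bounds[gap]
            insert_at = shift + (lo + hi) // 2
            # guard bases (A..A, a non-complementary pair) stop the planted
            # hit from extending into the spacer, so recovery is exact
            guarded = "A" + ins_seq + "A"
            final = final[:insert_at] + guarded + final[insert_at:]
            ledger.append(
                PlantedRepeat(
                    sequence=ins_seq,
                    start=insert_at + 2,
                    end=insert_at + 1 + len(ins_seq),
                    mismatches=_count_mismatches(ins_seq),
                )
            )
            # shift all downstream features
            features = [
                _shift_span(f, len(guarded), insert_at) for f in features
            ]
            shift += len(guarded)
        scaffold = final

    genome = GenomeRecord(
        accession=accession or f"SYNTH{seed}",
        sequence=scaffold,
        features=tuple(features),
        topology="circular",
    )
    truth = SyntheticTruth(
        seed=seed,
        preferred=dict(PREFERRED_CODONS),
        repeats=tuple(sorted(ledger, key=lambda r: r.start)),
        length_params={"spacer_min": spacer_len[0], "spacer_max": spacer_len[1]},
    )
    return genome, truth


def theta_grid_recovery(
    grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_genes: int = 50,
    mean_len: int = 300,
    gc3_target: float = 0.26,
    seed: int = 0,
    code: int = 11,
):
    """Parameter-recovery experiment over a grid of bias strengths.

    Samples one gene set per theta, scores every arm's genes for NC and
    for CAI against a single reference pooled across the whole grid (CAI
    values under different references are not comparable, so a common
    reference is required to rank genomes by bias strength), and returns
    a DataFrame with one row per theta: mean NC and mean CAI.
    """
    import pandas as pd

    from plastcub.indices import cai, count_codons, index_table, nc_wright

    arms = {
        float(th): sample_cds(n_genes, mean_len, theta=th,
                              gc3_target=gc3_target, seed=seed + i)[0]
        for i, th in enumerate(grid)
    }
    pooled = [g for genes in arms.values() for g in genes]
    reference = index_table(count_codons(pooled, code))
    rows = []
    for th, genes in arms.items():
        nc_values = [nc_wright(g, code) for g in genes]
        nc_values = [v for v in nc_values if v == v]
        rows.append(
            {
                "theta": th,
                "mean_nc": float(np.mean(nc_values)),
                "mean_cai": float(np.mean([cai(g, reference) for g in genes])),
            }
        )
    return pd.DataFrame(rows)


def _feature_index(features: list[FeatureSpan], gene_index: int) -> int:
    count = -1
    for j, f in enumerate(features):
        if f.kind == "CDS":
            count += 1
            if count == gene_index:
                return j
    raise IndexError(gene_index)


def _shift_span(span: FeatureSpan, by: int, after: int) -> FeatureSpan:
    """Shift a span right by ``by`` if it starts beyond 0-based offset ``after``."""
    if span.start - 1 < after:
        return span
    return FeatureSpan(
        kind=span.kind,
        gene_name=span.gene_name,
        start=span.start + by,
        end=span.end + by,
        strand=span.strand,
        parts=tuple((s + by, e + by) for s, e in span.parts),
    )
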