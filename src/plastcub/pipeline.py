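"""End-to-end orchestration: run every stage for one or more genomes and
emit the publication-style tables.

Output layout (per genome, under ``outdir/<accession>/``):

* composition.tsv, dinucleotides.tsv — compositional statistics
* codon_indices.tsv — amino acid, codon, RCB, RSCU, class
* gene_metrics.tsv — one row per gene, every scalar index
* summary.tsv — genome summary (NC, Aroma, Gravy, GC, GC3s, CAI; mean +/- sd)
* correlations.tsv — Gravy/Aroma x synonymous-composition Pearson table
* index_correlations.tsv — CAI/NC/GC3s cross-correlations
* pr2.tsv, pr2_summary.tsv, neutrality.tsv, nc_plot.tsv, phe.tsv
* ca_inertia.tsv, ca_genes.tsv, ca_codons.tsv, ca_correlations.tsv
* palindromes.tsv, inverted_repeats.tsv, rejections.tsv
* summary.json — full-precision machine-readable sidecar

Tables are written at 4 decimal places; the JSON sidecar keeps full
precision.  A combined cross-genome summary lands in the run root.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from plastcub import bias, correspondence
from plastcub.composition import composition_profile, dinucleotide_stats
from plastcub.indices import count_codons, index_table
from plastcub.metrics import gene_metrics
from plastcub.repeats import annotate_hits, scan
from plastcub.seqio import (
    GenomeRecord,
    extract_cds,
    read_genbank,
    write_cds_fasta,
    write_rejections,
)

FLOAT_FORMAT = "%.4f"

INDEX_PAIRS = [
    ("cai", "nc"), ("cai", "gc3s"), ("cai", "gc"),
    ("cai", "a3s"), ("cai", "t3s"), ("cai", "g3s"), ("cai", "c3s"),
    ("mrcbs", "cai"), ("nc", "gc3s"),
]

PROTEIN_PAIRS = [
    (p, x) for p in ("gravy", "aroma") for x in ("a3s", "c3s", "g3s", "t3s")
]


@dataclass
class RunConfig:
    inputs: list                      # paths to GenBank files or GenomeRecords
    outdir: str | Path = "results/run"
    code: int = 11
    min_len_palindrome: int = 32      # printed palindromes are > 30 bp
    min_len_ir: int = 42              # printed inverted repeats are > 40 bp
    max_mismatch: int = 2
    ca_axes: int = 4
    ca_use_rscu: bool = False
    seed: int = 0
    log: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.min_len_palindrome <= 0 or self.min_len_ir <= 0:
            raise ValueError("repeat length thresholds must be positive")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def analyze_genome(genome: GenomeRecord, config: RunConfig, outdir: Path) -> dict:
    """Run every stage for one genome; returns the summary dict."""
    outdir.mkdir(parents=True, exist_ok=True)
    log = config.log or sys.stderr
    timings = {}

    def stage(name):
        timings[name] = time.perf_counter()
        print(f"[plastcub] {genome.accession}: {name}", file=log)

    stage("extract")
    genes, rejections = extract_cds(genome, config.code)
    if not genes:
        raise RuntimeError(f"stage extract: no CDS retained in {genome.accession}")
    write_cds_fasta(genes, outdir / "cds.fasta")
    write_rejections(rejections, outdir / "rejections.tsv")

    stage("composition")
    prof = composition_profile(genes, config.code)
    _write(
        pd.DataFrame({"statistic": list(prof.as_dict()),
                      "value": list(prof.as_dict().values())}),
        outdir / "composition.tsv",
    )
    _write(dinucleotide_stats(genes), outdir / "dinucleotides.tsv", index=True)

    stage("indices")
    table = count_codons(genes, config.code)
    ref = index_table(table)
    _write(ref.to_frame(), outdir / "codon_indices.tsv")
    metrics = gene_metrics(genes, reference=ref, code=config.code)
    _write(metrics, outdir / "gene_metrics.tsv")

    stage("diagnostics")
    pr2 = bias.pr2_summary(metrics)
    _write(pr2.per_gene, outdir / "pr2.tsv")
    _write(
        pd.DataFrame([{"mean_at_bias": pr2.mean_at, "mean_gc_bias": pr2.mean_gc,
                       "quadrant": pr2.quadrant}]),
        outdir / "pr2_summary.tsv",
    )
    fit = bias.neutrality_fit(metrics)
    _write(
        pd.DataFrame([{
            "slope": fit.slope, "intercept": fit.intercept,
            "pearson_r": fit.pearson_r, "mutation_pct": fit.mutation_pct,
            "selection_pct": fit.selection_pct, "n_genes": fit.n_genes,
        }]),
        outdir / "neutrality.tsv",
    )
    ncdev = bias.nc_deviation(metrics)
    _write(ncdev, outdir / "nc_plot.tsv")
    phe = bias.phe_call(metrics)
    _write(phe.per_gene, outdir / "phe.tsv")
    _write(bias.correlation_matrix(metrics, PROTEIN_PAIRS),
           outdir / "correlations.tsv")
    _write(bias.correlation_matrix(metrics, INDEX_PAIRS),
           outdir / "index_correlations.tsv")

    stage("correspondence")
    matrix = correspondence.codon_matrix(genes, config.code,
                                         use_rscu=config.ca_use_rscu)
    ca_res = correspondence.ca(matrix, n_axes=config.ca_axes)
    ca_res = correspondence.orient_axes(ca_res, metrics)
    _write(ca_res.inertia_frame(), outdir / "ca_inertia.tsv")
    _write(ca_res.row_coords, outdir / "ca_genes.tsv", index=True)
    _write(ca_res.col_coords, outdir / "ca_codons.tsv", index=True)
    _write(correspondence.axis_covariate_correlations(ca_res, metrics),
           outdir / "ca_correlations.tsv")

    stage("repeats")
    circular = genome.topology == "circular"
    palindromes = [
        h for h in scan(genome.sequence, config.min_len_palindrome, 0,
                        circular=circular)
    ]
    irs = [
        h for h in scan(genome.sequence, config.min_len_ir,
                        config.max_mismatch, circular=circular)
        if h.mismatches >= 1
    ]
    for name, hits in (("palindromes.tsv", palindromes),
                       ("inverted_repeats.tsv", irs)):
        hits = annotate_hits(hits, genome)
        _write(
            pd.DataFrame(
                [{"genome": genome.accession, "sequence": h.sequence,
                  "length": h.length, "mismatches": h.mismatches,
                  "start": h.start, "end": h.end, "region": h.region}
                 for h in hits]
                or [],
                columns=["genome", "sequence", "length", "mismatches",
                         "start", "end", "region"],
            ),
            outdir / name,
        )

    summary = {
        "accession": genome.accession,
        "genome_length_bp": genome.length,
        "n_genes": len(genes),
        "n_rejected": len(rejections),
        "gc_coding": prof.gc,
        "gc1": prof.gc1, "gc2": prof.gc2, "gc3": prof.gc3,
        "gc3s": prof.gc3s,
        "nc_mean": float(metrics["nc"].mean()),
        "nc_sd": float(metrics["nc"].std(ddof=1)),
        "cai_mean": float(metrics["cai"].mean()),
        "cai_sd": float(metrics["cai"].std(ddof=1)),
        "mrcbs_mean": float(metrics["mrcbs"].mean()),
        "gravy_mean": float(metrics["gravy"].mean()),
        "aroma_mean": float(metrics["aroma"].mean()),
        "cai_phe_threshold": phe.threshold_cai,
        "neutrality_slope": fit.slope,
        "mutation_pct": fit.mutation_pct,
        "selection_pct": fit.selection_pct,
        "pr2_mean_at": pr2.mean_at,
        "pr2_mean_gc": pr2.mean_gc,
        "ca_axis1_pct": float(ca_res.inertia_pct[0]) if len(ca_res.inertia) else 0.0,
        "ca_axis2_pct": float(ca_res.inertia_pct[1]) if len(ca_res.inertia) > 1 else 0.0,
        "n_palindromes": len(palindromes),
        "n_inverted_repeats": len(irs),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    _write(
        pd.DataFrame({"statistic": list(summary), "value": list(summary.values())}),
        outdir / "summary.tsv",
    )
    start = min(timings.values())
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"plastcub run for {genome.accession}\n")
        fh.write(f"config: {config!r}\n")
        for name, t in timings.items():
            fh.write(f"stage {name} started at +{t - start:.3f}s\n")
        fh.write(f"finished at +{time.perf_counter() - start:.3f}s\n")
    return summary


def run_report(config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline for every input; returns the combined summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for item in config.inputs:
        genome = item if isinstance(item, GenomeRecord) else read_genbank(item)
        sub = outdir / genome.accession if len(config.inputs) > 1 else outdir
        summaries.append(analyze_genome(genome, config, sub))
    combined = pd.DataFrame(summaries)
    if len(config.inputs) > 1:
        _write(combined, outdir / "combined_summary.tsv")
    return combined
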