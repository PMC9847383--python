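"""Reverse-complement palindromes and mismatch-tolerant inverted repeats.

A DNA segment of even length L is scored by its symmetric base pairs
(i, L-1-i): the segment is a perfect reverse-complement palindrome when
every pair is Watson-Crick complementary, and a degenerate palindrome
(reported here as an inverted repeat) when at most ``max_mismatch`` pairs
are not.  Every even-length segment has a unique centre between two bases;
for each centre the scanner extends symmetrically until the mismatch
budget or the sequence boundary stops it, so each reported hit is maximal:
no one-pair extension on both sides stays within the budget and the
sequence.  Overlapping maximal hits from distinct centres are all
reported.  Windows touching an N never match.

Coordinates are 1-based inclusive throughout.  Circular sequences are
scanned with a wrap-around window so origin-spanning hits are found;
their coordinates are reported modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from plastcub.seqio import GenomeRecord

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_COMPLEMENT_TR = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA character(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TR)[::-1]


@dataclass(frozen=True)
class RepeatHit:
    sequence: str
    start: int                     # 1-based inclusive
    end: int
    mismatches: int
    region: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def kind(self) -> str:
        return "palindrome" if self.mismatches == 0 else "inverted_repeat"


def _pair_ok(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def scan(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 0,
    circular: bool = False,
    wrap: int | None = None,
) -> list[RepeatHit]:
    """All maximal even-length (degenerate) palindromes of length >= min_len.

    For circular sequences a copy of the first ``wrap`` bases (default
    2 * min_len) is appended so hits spanning the origin are seen once;
    their coordinates wrap modulo the sequence length.
    """
    if min_len < 4 or min_len % 2 != 0:
        raise ValueError("min_len must be even and >= 4")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA character(s): {sorted(bad)}")
    n = len(seq)
    scan_seq = seq
    if circular and n > min_len:
        w = min(wrap if wrap is not None else 2 * min_len, n - 1)
        scan_seq = seq + seq[:w]
    m = len(scan_seq)
    hits = []
    for center in range(1, m):          # centre between center-1 and center
        if circular and center > n:
            break                        # origin-spanning centres only
        left, right = center - 1, center
        mismatches = 0
        best = None
        while left >= 0 and right < m:
            a, b = scan_seq[left], scan_seq[right]
            if a == "N" or b == "N":
                break
            if not _pair_ok(a, b):
                mismatches += 1
                if mismatches > max_mismatch:
                    break
            best = (left, right, mismatches)
            left -= 1
            right += 1
        if best is None:
            continue
        lo, hi, mm = best
        length = hi - lo + 1
        if length < min_len:
            continue
        start, end = lo + 1, hi + 1
        if circular and n > 0:
            if start > n:                # entirely inside the wrap copy: dup
                continue
            end = end if end <= n else ((end - 1) % n) + 1
        hits.append(
            RepeatHit(sequence=scan_seq[lo : hi + 1], start=start, end=end,
                      mismatches=mm)
        )
    # a hit is duplicated when the circular wrap re-finds a linear hit
    unique = {}
    for h in hits:
        unique.setdefault((h.start, h.end, h.sequence), h)
    return sorted(unique.values(), key=lambda h: (h.start, h.end))


def annotate_hits(
    hits: list[RepeatHit], genome: GenomeRecord
) -> list[RepeatHit]:
    """Attach a feature-context label to each hit.

    Inside an exon of a named feature -> the gene name; inside a feature's
    span but between its parts -> "name (intron)"; intergenic -> the names
    of the nearest flanking features as "left-right".
    """
    named = [
        f for f in genome.features if f.kind in ("CDS", "tRNA", "rRNA")
    ]
    out = []
    n = genome.length
    for hit in hits:
        if hit.start < 1 or hit.end > n or (hit.end < hit.start and genome.topology != "circular"):
            raise ValueError(
                f"hit {hit.start}-{hit.end} outside genome of length {n}"
            )
        label = None
        for feat in named:
            if feat.start <= hit.start and hit.end <= feat.end:
                in_exon = any(
                    s <= hit.start and hit.end <= e for s, e in feat.parts
                )
                label = feat.gene_name if in_exon else f"{feat.gene_name} (intron)"
                break
        if label is None:
            left = [f for f in named if f.end < hit.start]
            right = [f for f in named if f.start > hit.end]
            left_name = max(left, key=lambda f: f.end).gene_name if left else None
            right_name = min(right, key=lambda f: f.start).gene_name if right else None
            if genome.topology == "circular" and named:
                left_name = left_name or max(named, key=lambda f: f.end).gene_name
                right_name = right_name or min(named, key=lambda f: f.start).gene_name
            if left_name and right_name:
                label = f"{left_name}-{right_name}"
            else:
                label = left_name or right_name or "intergenic"
        out.append(replace(hit, region=label))
    return out
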