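"""Independent oracles used to cross-check the package implementations.

These deliberately take different computational routes from the library:
the palindrome oracle scores every even-length substring via dynamic
programming on the full pair matrix (the scanner expands per centre), and
the NC oracle enumerates the synonymous families from a literal table.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_BIG = 10**6

# Standard-code synonymous families, written out literally.
FAMILIES = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}
STOPS = {"TAA", "TAG", "TGA"}


def pair_mismatch_matrix(seq: str) -> np.ndarray:
    """D[i, j] = mismatched symmetric pairs of the window i..j (j-i odd),
    built by dynamic programming along anti-diagonals; windows touching an
    N get a huge count so they can never match."""
    L = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        comp[ord(a)] = ord(b)
    pair_bad = (comp[codes][:, None] != codes[None, :]).astype(np.int64)
    is_n = codes == ord("N")
    pair_bad[is_n, :] = _BIG
    pair_bad[:, is_n] = _BIG
    D = np.zeros((L, L), dtype=np.int64)
    for t in range(1, L, 2):
        i = np.arange(L - t)
        inner = D[i + 1, i + t - 1] if t >= 3 else 0
        D[i, i + t] = pair_bad[i, i + t] + inner
    return D


def brute_scan(seq: str, min_len: int, max_mismatch: int):
    """All maximal even-length degenerate palindromes, by testing every
    even-length substring.  Returns sorted (start, end, mismatches),
    1-based inclusive."""
    seq = seq.upper()
    L = len(seq)
    D = pair_mismatch_matrix(seq)
    hits = []
    for t in range(min_len - 1, L, 2):
        s = np.arange(L - t)
        m = D[s, s + t]
        ok = m <= max_mismatch
        can_extend = np.zeros(L - t, dtype=bool)
        interior = (s >= 1) & (s + t <= L - 2)
        si = s[interior]
        if len(si):
            can_extend[interior] = D[si - 1, si + t + 1] <= max_mismatch
        for start in s[ok & ~can_extend]:
            hits.append((int(start) + 1, int(start) + t + 1, int(m[start])))
    return sorted(hits)


def nc_oracle(codons) -> float:
    """Wright's NC by explicit family enumeration from the literal table."""
    counts = Counter(c for c in codons if c not in STOPS)
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for fam in FAMILIES.values():
        m = sum(counts[c] for c in fam)
        if m < 2:
            continue
        s = sum((counts[c] / m) ** 2 for c in fam)
        by_class[len(fam)].append((m * s - 1.0) / (m - 1.0))
    means = {
        k: (sum(v) / len(v) if v else math.nan) for k, v in by_class.items()
    }
    if math.isnan(means[3]) and not (
        math.isnan(means[2]) or math.isnan(means[4])
    ):
        means[3] = (means[2] + means[4]) / 2.0
    if any(math.isnan(means[k]) or means[k] <= 0 for k in (2, 3, 4, 6)):
        return math.nan
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(61.0, max(20.0, nc))


def pearson_oracle(x, y) -> float:
    """Pearson r from the covariance definition, no library call."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
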