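"""Correspondence analysis of the gene x codon usage table.

Classical (chi-square metric) CA: the correspondence matrix P = X / n is
centred by the outer product of its margins, standardised to
S = Dr^-1/2 (P - r c^T) Dc^-1/2, and decomposed by SVD.  Axis k carries
inertia sigma_k^2; total inertia equals the table's chi-square statistic
over its grand total.  Row (gene) and column (codon) principal
coordinates are returned.

The analysis runs on the raw count matrix over the 59 sense codons
(Met, Trp and stops excluded), matching the dimensionality of a
59-axis codon-usage space; an RSCU-matrix mode is available for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plastcub.genetics import genetic_code
from plastcub.indices import count_codons, rscu
from plastcub.seqio import GeneRecord


@dataclass(frozen=True)
class CAResult:
    inertia: np.ndarray            # absolute inertia per axis (all axes)
    total_inertia: float
    row_coords: pd.DataFrame       # genes x axes (principal coordinates)
    col_coords: pd.DataFrame       # codons x axes

    @property
    def inertia_pct(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return 100.0 * self.inertia / self.total_inertia

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.inertia_pct)

    def inertia_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, len(self.inertia) + 1),
                "inertia": self.inertia,
                "pct": self.inertia_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )


def codon_matrix(
    genes: list[GeneRecord], code: int = 11, use_rscu: bool = False
) -> pd.DataFrame:
    """Gene x codon matrix over the 59 sense codons of degenerate families."""
    gc = genetic_code(code)
    columns = [c for c in gc.sense_codons if len(gc.family_of(c)) >= 2]
    rows = []
    for gene in genes:
        table = count_codons(gene, code)
        if use_rscu:
            values = rscu(table)
            rows.append([np.nan_to_num(values[c]) for c in columns])
        else:
            rows.append([table.counts[c] for c in columns])
    return pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=columns)


def ca(matrix: pd.DataFrame, n_axes: int = 4) -> CAResult:
    """Classical correspondence analysis of a non-negative matrix.

    All-zero rows/columns are dropped with a warning.  A matrix with no
    row variation yields zero total inertia and zero axes (no error).
    """
    X = matrix.to_numpy(dtype=float)
    if X.min() < 0:
        raise ValueError("CA input must be non-negative")
    row_keep = X.sum(axis=1) > 0
    col_keep = X.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn(
            f"dropping {int((~row_keep).sum())} all-zero rows and "
            f"{int((~col_keep).sum())} all-zero columns",
            stacklevel=2,
        )
    matrix = matrix.loc[row_keep, col_keep]
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("CA needs at least 2 non-empty rows and columns")
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    rank = min(X.shape) - 1
    sigma = sigma[:rank]
    # numerical noise below machine-scale singular values is not signal
    sigma = np.where(sigma < 1e-12, 0.0, sigma)
    U, Vt = U[:, :rank], Vt[:rank]
    k = min(n_axes, rank)
    row = (U * sigma) / np.sqrt(r)[:, None]
    col = (Vt.T * sigma) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(k)]
    return CAResult(
        inertia=sigma**2,
        total_inertia=float((sigma**2).sum()),
        row_coords=pd.DataFrame(row[:, :k], index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col[:, :k], index=matrix.columns, columns=axes),
    )


def orient_axes(result: CAResult, metrics: pd.DataFrame,
                covariate: str = "gc3s", axis: str = "axis1") -> CAResult:
    """Fix the arbitrary SVD signs so ``covariate`` correlates non-positively
    with ``axis`` (a reporting convention; inertias are unaffected)."""
    merged = metrics.set_index("gene_id").join(result.row_coords, how="inner")
    flip = {}
    for ax in result.row_coords.columns:
        r = merged[covariate].corr(merged[ax])
        flip[ax] = -1.0 if (ax == axis and r > 0) else 1.0
    row = result.row_coords.mul(pd.Series(flip))
    col = result.col_coords.mul(pd.Series(flip))
    return CAResult(
        inertia=result.inertia,
        total_inertia=result.total_inertia,
        row_coords=row,
        col_coords=col,
    )


def axis_covariate_correlations(
    result: CAResult,
    metrics: pd.DataFrame,
    covariates: list[str] | None = None,
    axes: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Pearson r between gene coordinates on each axis and each covariate."""
    from scipy import stats

    if covariates is None:
        covariates = ["gc3s", "a3s", "g3s", "cai", "gravy", "aroma", "gc",
                      "gc3_skew"]
    coords = result.row_coords
    meta = metrics.set_index("gene_id")
    missing = coords.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"metrics missing for genes: {sorted(missing)}")
    meta = meta.loc[coords.index]
    rows = []
    for ax in axes:
        name = f"axis{ax}"
        if name not in coords.columns:
            continue
        for cov in covariates:
            sub = pd.DataFrame({"x": coords[name], "y": meta[cov]}).dropna()
            if len(sub) < 3 or sub["y"].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub["x"], sub["y"])
            rows.append(
                {"axis": ax, "covariate": cov, "pearson_r": float(r),
                 "p_value": float(p), "n": len(sub)}
            )
    return pd.DataFrame(rows)
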