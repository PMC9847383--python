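"""Diagnostic analyses built on the per-gene metrics table.

* PR2 plot summary: per-gene A3/(A3+T3) vs G3/(G3+C3), genome means and
  the bias quadrant they fall in.
* Neutrality fit: OLS of GC12 on GC3s; the slope is read as the share of
  directional mutation pressure ("relative neutrality"), 1 - slope as the
  share of selective constraint.
* NC deviation: per-gene NC minus the GC3s-expected curve; genes well
  below the curve indicate selection beyond mutational pressure.
* Pairwise Pearson correlations with two-sided p-values (significance at
  p < 0.01).
* PHE calling: z-score of CAI across genes; z > 2 is called predicted
  highly expressed, z < -2 predicted low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plastcub.indices import expected_nc


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    n_genes: int

    @property
    def mutation_pct(self) -> float:
        return self.slope * 100.0

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


@dataclass(frozen=True)
class Pr2Summary:
    per_gene: pd.DataFrame          # gene_id, pr2_at, pr2_gc
    mean_at: float
    mean_gc: float
    quadrant: str                   # e.g. "T/C bias"


@dataclass(frozen=True)
class PheCall:
    per_gene: pd.DataFrame          # gene_id, cai, z, label
    threshold_cai: float
    mean: float
    sd: float


def pr2_summary(metrics: pd.DataFrame) -> Pr2Summary:
    """Genome PR2 summary; genome means are unweighted over genes."""
    sub = metrics[["gene_id", "pr2_at", "pr2_gc"]].copy()
    mean_at = float(sub["pr2_at"].mean(skipna=True))
    mean_gc = float(sub["pr2_gc"].mean(skipna=True))
    vertical = "A" if mean_at > 0.5 else "T"
    horizontal = "G" if mean_gc > 0.5 else "C"
    return Pr2Summary(
        per_gene=sub,
        mean_at=mean_at,
        mean_gc=mean_gc,
        quadrant=f"{vertical}/{horizontal} bias",
    )


def neutrality_fit(metrics: pd.DataFrame) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3s."""
    sub = metrics[["gc3s", "gc12"]].dropna()
    if len(sub) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if np.isclose(sub["gc3s"].var(ddof=0), 0.0):
        raise ValueError("GC3s has zero variance; slope undefined")
    fit = stats.linregress(sub["gc3s"], sub["gc12"])
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_genes=len(sub),
    )


def nc_deviation(metrics: pd.DataFrame) -> pd.DataFrame:
    """Signed per-gene deviation NC - NC_expected(GC3s).

    The returned frame carries a ``below_curve`` flag; the fraction of
    genes below the curve summarises selective constraint.
    """
    out = metrics[["gene_id", "nc", "gc3s"]].copy()
    out["nc_expected"] = [
        expected_nc(s) if not math.isnan(s) else math.nan for s in out["gc3s"]
    ]
    out["deviation"] = out["nc"] - out["nc_expected"]
    out["below_curve"] = out["deviation"] < 0
    return out


def correlation_matrix(
    metrics: pd.DataFrame, pairs: list[tuple[str, str]], alpha: float = 0.01
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with two-sided p-values."""
    rows = []
    for x, y in pairs:
        sub = metrics[[x, y]].dropna()
        if len(sub) < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(sub[x], sub[y])
        rows.append(
            {
                "x": x,
                "y": y,
                "pearson_r": float(r),
                "p_value": float(p),
                "n": len(sub),
                "significant": bool(p < alpha) if not math.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


def phe_call(metrics: pd.DataFrame, column: str = "cai") -> PheCall:
    """Call predicted highly expressed genes by the z-score of an
    expressivity index (CAI by default; MRCBS via ``column='mrcbs'``)."""
    values = metrics[["gene_id", column]].dropna().copy()
    if len(values) < 3:
        raise ValueError("PHE calling needs at least 3 genes")
    mean = float(values[column].mean())
    sd = float(values[column].std(ddof=1))
    if sd == 0 or math.isnan(sd):
        values["z"] = 0.0
        values["label"] = "typical"
        return PheCall(per_gene=values, threshold_cai=mean, mean=mean, sd=0.0)
    values["z"] = (values[column] - mean) / sd
    values["label"] = np.select(
        [values["z"] > 2.0, values["z"] < -2.0], ["PHE", "low"], "typical"
    )
    return PheCall(
        per_gene=values,
        threshold_cai=mean + 2.0 * sd,
        mean=mean,
        sd=sd,
    )
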