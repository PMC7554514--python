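"""Count-matrix normalization and differential expression screening.

Covers the arithmetic around a genes x samples readcount matrix:

* RPKM — reads per kilobase of transcript per million mapped reads,
  RPKM_gs = counts_gs * 1e9 / (length_g * total_s).
* Median-of-ratios scaling factors (one scaling normalization factor per
  sample against the gene-wise geometric-mean reference profile).
* log2 fold change between two group means, rounded half-away-from-zero
  to two decimals for report tables.
* A DEG screen at p_adj < 0.05 and |log2FC| > 1. The per-gene p-value
  comes from the two-library exact Poisson test applied to scaling-
  normalized, group-summed counts — a deliberately simple stand-in for a
  full negative-binomial GLM, sharing the thresholds and the fold-change
  arithmetic the screen is defined by.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tag_dge

__all__ = [
    "CountMatrix",
    "rpkm",
    "scaling_factors",
    "log2fc",
    "round_half_away",
    "de_screen",
    "read_count_matrix",
]


@dataclass
class CountMatrix:
    """Readcounts (genes x samples) with per-gene transcript lengths.

    ``counts`` is a DataFrame indexed by gene_id with one column per
    sample; ``lengths`` a Series of transcript lengths in bp on the same
    index; ``groups`` maps sample -> group label.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths index must match counts index")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def group_samples(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for s in self.counts.columns:
            out.setdefault(self.groups[s], []).append(s)
        return out


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series, library_totals=None) -> pd.DataFrame:
    """RPKM matrix: counts * 1e9 / (length_bp * library_total).

    ``library_totals`` defaults to the column sums. For every sample the
    identity sum_g RPKM_gs * length_g(kb) = 1e6 holds when totals are the
    column sums.
    """
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    library_totals = pd.Series(library_totals, index=counts.columns, dtype=float)
    if (library_totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.div(gene_lengths, axis=0).div(library_totals, axis=1) * 1e9


def scaling_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios scaling factors, geometric mean 1.

    Each sample's factor is the median over genes of counts_gs / ref_g,
    where ref_g is the geometric mean of gene g across samples; genes
    with a zero in any sample are excluded. Falls back to library-size
    factors (with a warning) when no gene is all-positive.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warnings.warn(
            "no gene with all-positive counts; using library-size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        factors = mat.sum(axis=0)
    else:
        sub = mat[allpos]
        log_ref = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def log2fc(mean_a: float, mean_b: float, pseudocount: float = 0.0) -> float:
    """log2 of the ratio of two (positive) group means."""
    a, b = mean_a + pseudocount, mean_b + pseudocount
    if a <= 0 or b <= 0:
        raise ValueError("means must be positive (or use a pseudocount)")
    return float(np.log2(a / b))


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def de_screen(
    matrix: CountMatrix,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Two-group DEG screen at p_adj < alpha and |log2FC| > min_abs_lfc.

    Counts are divided by the median-of-ratios factors, summed within each
    group and rounded; the exact two-library test then yields per-gene
    p-values, BH-adjusted. Fold change is group A (first label in column
    order) over group B. Returns gene_id, mean_a, mean_b, log2_fold_change,
    p_value, p_adj, is_deg, direction.
    """
    groups = matrix.group_samples()
    if len(groups) != 2:
        raise ValueError("de_screen requires exactly two groups")
    (ga, samples_a), (gb, samples_b) = groups.items()
    if not samples_a or not samples_b:
        raise ValueError("each group needs at least one sample")
    factors = scaling_factors(matrix.counts)
    norm = matrix.counts.div(factors, axis=1)
    sum_a = norm[samples_a].sum(axis=1)
    sum_b = norm[samples_b].sum(axis=1)
    xa = np.rint(sum_a.to_numpy()).astype(int)
    xb = np.rint(sum_b.to_numpy()).astype(int)
    n_a, n_b = int(xa.sum()), int(xb.sum())
    pvals = np.array([tag_dge.two_sided_p(b, a, n_b, n_a) for a, b in zip(xa, xb)])
    mean_a = sum_a / len(samples_a)
    mean_b = sum_b / len(samples_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(
            (mean_a.to_numpy() + pseudocount) / (mean_b.to_numpy() + pseudocount)
        )
    res = pd.DataFrame(
        {
            "gene_id": matrix.counts.index,
            "mean_" + ga: mean_a.to_numpy(),
            "mean_" + gb: mean_b.to_numpy(),
            "log2_fold_change": lfc,
            "p_value": pvals,
            "p_adj": tag_dge.bh_fdr(pvals),
        }
    ).reset_index(drop=True)
    finite = np.isfinite(res["log2_fold_change"].to_numpy())
    res["is_deg"] = (
        (res["p_adj"] < alpha)
        & (res["log2_fold_change"].abs() > min_abs_lfc)
        & finite
    )
    res["direction"] = np.where(
        res["is_deg"] & (res["log2_fold_change"] > 0),
        "up",
        np.where(res["is_deg"], "down", ""),
    )
    return res


def read_count_matrix(path, groups: dict[str, str]) -> CountMatrix:
    """Read a TSV of gene_id, length_bp, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.iloc[:, 0].astype(float)
    counts = df.iloc[:, 1:].astype(float)
    return CountMatrix(counts, lengths, groups)
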