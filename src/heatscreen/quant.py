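"""Relative qPCR quantification, heat-injury index and replicate stats.

The 2^-ddCt method quantifies a target transcript relative to a reference
(housekeeping) gene and a calibrator sample:

    dCt_s  = mean Ct_target,s - mean Ct_reference,s
    ddCt_s = dCt_s - dCt_calibrator
    RQ_s   = 2^-ddCt_s            (RQ_calibrator = 1 by construction)

The heat injury index aggregates ordinal injury scores of a plant cohort
(level 0 = no leaf curling ... level 3 = whole plant wilted) into a
percentage:

    HII(%) = sum(plants_at_level * level) * 100 / (max_level * n_plants)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct",
    "heat_injury_index",
    "replicate_summary",
    "read_ct_table",
    "read_injury_tally",
]


def ddct(
    table: pd.DataFrame,
    calibrator: str,
    target: str = "target",
    reference: str = "reference",
) -> pd.Series:
    """Per-sample relative quantity 2^-ddCt.

    ``table`` has columns sample, gene, ct (one row per replicate well);
    replicate Ct values are averaged per (sample, gene) before dCt.
    """
    for col in ("sample", "gene", "ct"):
        if col not in table.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    mean_ct = table.groupby(["sample", "gene"])["ct"].mean().unstack()
    if reference not in mean_ct.columns:
        raise ValueError(f"reference gene {reference!r} missing from table")
    if target not in mean_ct.columns:
        raise ValueError(f"target gene {target!r} missing from table")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} missing from table")
    if mean_ct[[target, reference]].isna().any().any():
        raise ValueError("every sample needs Ct values for target and reference")
    dct = mean_ct[target] - mean_ct[reference]
    ddct_vals = dct - dct.loc[calibrator]
    rq = np.power(2.0, -ddct_vals)
    rq.name = "relative_quantity"
    return rq


def heat_injury_index(counts, max_level: int | None = None) -> float:
    """Heat injury index (percent) of a cohort of ordinally scored plants.

    ``counts[level]`` is the number of plants scored at that level,
    levels 0..max_level. ``max_level`` defaults to len(counts) - 1.
    """
    counts = np.asarray(counts, dtype=float)
    if max_level is None:
        max_level = len(counts) - 1
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if len(counts) != max_level + 1:
        raise ValueError("counts must cover levels 0..max_level")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cohort has zero plants")
    levels = np.arange(max_level + 1)
    return float((counts * levels).sum() * 100.0 / (max_level * total))


def replicate_summary(
    values_a,
    values_b,
    alpha_levels: tuple[float, float] = (0.05, 0.01),
    equal_var: bool = True,
) -> dict:
    """Mean +- SD per group, two-sided t-test p, and a star label.

    Student's (equal-variance) two-sample t by default; Welch via
    ``equal_var=False``. Stars: '**' below the stricter alpha, '*' below
    the looser, '' otherwise. Two identical constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    loose, strict = max(alpha_levels), min(alpha_levels)
    stars = "**" if p < strict else ("*" if p < loose else "")
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "p": p,
        "stars": stars,
    }


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample, group, gene, rep, ct."""
    return pd.read_csv(path, sep="\t")


def read_injury_tally(path) -> np.ndarray:
    """Read a tally TSV (level, count) into a dense level-indexed array."""
    df = pd.read_csv(path, sep="\t")
    max_level = int(df["level"].max())
    counts = np.zeros(max_level + 1, dtype=int)
    for level, count in zip(df["level"], df["count"]):
        counts[int(level)] = int(count)
    return counts
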