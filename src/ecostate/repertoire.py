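"""Clonotype diversity: Shannon entropy and group comparison.

Clonotype counts (TRUST4-style TCR/BCR tables, or motif-cluster sizes) are
normalized to frequencies and summarized by Shannon entropy, in nats by
default. Groups are compared with a two-sided Wilcoxon rank-sum test, exact
for small tie-free samples and normal-approximated with tie correction
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "shannon_entropy",
    "diversity_table",
    "RankSumResult",
    "compare_entropy_groups",
]


def shannon_entropy(counts, base: str = "nats") -> float:
    """H = -sum p log p with p = count/total; 'nats' or 'bits'."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 1):
        raise ValueError("counts must be positive (>= 1 read per clonotype)")
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base == "bits":
        return h / math.log(2)
    if base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return h


def diversity_table(clonotypes: pd.DataFrame, base: str = "nats") -> pd.DataFrame:
    """Per (sample, chain): entropy, clonotype count, and total reads."""
    required = {"sample_id", "chain", "clonotype_id", "count"}
    if not required.issubset(clonotypes.columns):
        raise ValueError(f"clonotype table needs columns {sorted(required)}")
    dup = clonotypes.duplicated(["sample_id", "chain", "clonotype_id"])
    if dup.any():
        raise ValueError("duplicate (sample, chain, clonotype) rows")
    rows = []
    for (s, ch), grp in clonotypes.groupby(["sample_id", "chain"], sort=True):
        h = shannon_entropy(grp["count"].to_numpy(), base=base)
        rows.append((s, ch, h, len(grp), int(grp["count"].sum())))
    return pd.DataFrame(
        rows, columns=["sample_id", "chain", "entropy", "n_clonotypes", "total_reads"]
    )


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


def compare_entropy_groups(values, labels) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two groups of entropies.

    Exact distribution when both groups have <= 20 observations and no ties;
    tie-corrected normal approximation otherwise.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = v[lab == groups[0]]
    b = v[lab == groups[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    has_ties = len(np.unique(v)) < len(v)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n1=len(a),
        n2=len(b),
    )
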