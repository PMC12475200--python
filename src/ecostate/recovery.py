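"""Recovery of frozen cell-state and ecotype models in new cohorts.

Bulk recovery maps a held-out cohort's imputed cell type expression through
the exact transform frozen at discovery (same genes, log2, per-gene
standardization with the discovery means/stds, posneg) and solves the state
coefficients per sample by non-negative least squares against the frozen
basis. Single-cell recovery scores each annotated cell against the state
bases and tests whether within-type mean scores exceed a label-permutation
null, combining per-sample z-scores by Stouffer's method (z > 1.65,
one-sided P < 0.05, deemed significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .ecotypes import EcotypeResults
from .states import CellStateResults, posneg_transform

__all__ = [
    "StateRecovery",
    "recover_states_bulk",
    "recover_ecotypes",
    "sc_state_scores",
    "stouffer_meta_z",
    "sc_recovery_significance",
    "SIGNIFICANCE_Z",
]

#: one-sided P < 0.05
SIGNIFICANCE_Z = 1.65


@dataclass
class StateRecovery:
    """Recovered state coefficients for one cell type in a new cohort."""

    cell_type: str
    H_new: pd.DataFrame
    state_abundance: pd.DataFrame
    total_weight: pd.Series
    low_weight_flag: pd.Series


def recover_states_bulk(
    new_gep: pd.DataFrame,
    frozen: CellStateResults,
    min_overlap: float = 0.5,
    low_weight_quantile: float = 0.05,
) -> StateRecovery:
    """Solve per-sample state coefficients against the frozen NMF basis.

    Genes missing from the new cohort are dropped from the basis (row
    subset); at least ``min_overlap`` of the discovery genes must be
    present.
    """
    new_upper = new_gep.copy()
    new_upper.index = [str(g).upper() for g in new_gep.index]
    new_upper = new_upper[~new_upper.index.duplicated(keep="first")]
    genes = frozen.genes_used
    idx_map = {str(g).upper(): i for i, g in enumerate(genes)}
    shared = [g for g in new_upper.index if g in idx_map]
    if len(shared) < min_overlap * len(genes):
        missing = [g for g in genes if str(g).upper() not in set(new_upper.index)]
        raise ValueError(
            f"only {len(shared)}/{len(genes)} frozen genes present "
            f"(need >= {min_overlap:.0%}); missing e.g. {missing[:10]}"
        )
    pos = [idx_map[g] for g in shared]
    sub = np.log2(new_upper.loc[shared].to_numpy(dtype=float) + 1.0)
    mu = frozen.gene_means[pos]
    sd = frozen.gene_stds[pos]
    Z = (sub - mu[:, None]) / sd[:, None]
    X = posneg_transform(Z)

    W_full = frozen.W.to_numpy()
    half = len(genes)
    W = np.vstack([W_full[pos, :], W_full[[half + p for p in pos], :]])

    samples = list(new_gep.columns)
    k = W.shape[1]
    H = np.zeros((k, len(samples)))
    for si in range(len(samples)):
        H[:, si], _ = nnls(W, X[:, si])
    total = H.sum(axis=0)
    Hn = H / np.where(total > 0, total, 1.0)
    H_new = pd.DataFrame(Hn, index=frozen.W.columns, columns=samples)
    tw = pd.Series(total, index=samples, name="total_weight")
    thresh = tw.quantile(low_weight_quantile)
    return StateRecovery(
        cell_type=frozen.cell_type,
        H_new=H_new,
        state_abundance=H_new.T.copy(),
        total_weight=tw,
        low_weight_flag=tw <= max(thresh, 1e-9),
    )


def recover_ecotypes(state_abundance: pd.DataFrame, frozen: EcotypeResults):
    """Frozen-mapping ecotype abundance and assignment for a new cohort.

    Identical arithmetic to discovery-time assignment (mean member-state
    abundance renormalized; Welch t-test + BH gate); returns
    (assignments, Q, ecotype_abundance).
    """
    missing = [s for s in frozen.state_to_ecotype if s not in state_abundance.columns]
    if missing:
        raise ValueError(f"state abundances missing frozen states: {missing}")
    if state_abundance.empty:
        ecos = frozen.ecotype_ids
        return (
            pd.Series(dtype=object, name="ecotype"),
            pd.Series(dtype=float, name="Q"),
            pd.DataFrame(columns=ecos),
        )
    return frozen.apply(state_abundance)


def sc_state_scores(cells: pd.DataFrame, frozen: CellStateResults) -> pd.DataFrame:
    """Per-cell state scores: Pearson correlation of each cell's log profile
    with each state's positive-part basis column over shared genes."""
    cells_upper = cells.copy()
    cells_upper.index = [str(g).upper() for g in cells.index]
    cells_upper = cells_upper[~cells_upper.index.duplicated(keep="first")]
    genes = [g for g in frozen.genes_used if str(g).upper() in set(cells_upper.index)]
    if len(genes) < 3:
        raise ValueError("too few shared genes for state scoring")
    idx = [frozen.genes_used.index(g) for g in genes]
    Wpos = frozen.W.to_numpy()[idx, :]
    X = np.log2(cells_upper.loc[[str(g).upper() for g in genes]].to_numpy(dtype=float) + 1.0)
    Xc = X - X.mean(axis=0, keepdims=True)
    Wc = Wpos - Wpos.mean(axis=0, keepdims=True)
    num = Xc.T @ Wc
    den = np.outer(
        np.sqrt((Xc**2).sum(axis=0)), np.sqrt((Wc**2).sum(axis=0))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return pd.DataFrame(corr, index=cells.columns, columns=frozen.W.columns)


def stouffer_meta_z(z_scores) -> float:
    z = np.asarray(z_scores, dtype=float)
    return float(z.sum() / np.sqrt(len(z)))


def sc_recovery_significance(
    scores: pd.DataFrame,
    cell_types: pd.Series,
    target_type: str,
    sample_labels: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    min_cells: int = 100,
) -> pd.DataFrame:
    """Permutation z-scores for state recovery in annotated single cells.

    Observed statistic = mean score of ``target_type`` cells per state and
    sample; the null permutes cell-type labels within each sample. Returns a
    per-state table with one z column per sample, a Stouffer ``meta_z``, and
    a ``significant`` flag (meta_z > 1.65).
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    n_target = int((cell_types == target_type).sum())
    if n_target < min_cells:
        raise ValueError(
            f"only {n_target} cells annotated {target_type!r} (need >= {min_cells})"
        )
    rng = np.random.default_rng(seed)
    samples = sorted(sample_labels.unique())
    zmat = pd.DataFrame(index=scores.columns, columns=samples, dtype=float)
    for smp in samples:
        in_sample = sample_labels == smp
        sc = scores.loc[in_sample.values]
        labels = cell_types.loc[in_sample.values].to_numpy()
        mask = labels == target_type
        if mask.sum() == 0:
            zmat[smp] = np.nan
            continue
        obs = sc.to_numpy()[mask].mean(axis=0)
        null = np.empty((n_permutations, scores.shape[1]))
        vals = sc.to_numpy()
        for b in range(n_permutations):
            perm = rng.permutation(len(labels))
            null[b] = vals[perm[: mask.sum()]].mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        zmat[smp] = (obs - null.mean(axis=0)) / np.where(sd > 0, sd, np.inf)
    out = zmat.copy()
    out["meta_z"] = [
        stouffer_meta_z(row.dropna().to_numpy()) if row.notna().any() else np.nan
        for _, row in zmat.iterrows()
    ]
    out["significant"] = out["meta_z"] > SIGNIFICANCE_Z
    return out
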