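"""Transcriptional cell-state discovery by consensus NMF.

For each cell type, the imputed cell type-specific expression is reduced to
its most dispersed genes, log-transformed, gene-standardized, and split into
stacked positive/negative parts (the "posneg" transform) so NMF can factor a
signed matrix. The number of states is chosen by the stability of consensus
clustering across random restarts (cophenetic coefficient over candidate
ranks, threshold 0.95), and states driven mainly by negative-part features
are removed by an adaptive false-positive index (AFI) filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "select_variable_genes",
    "posneg_transform",
    "posneg_inverse",
    "prepare_nmf_input",
    "nmf_rank_scan",
    "RankSelection",
    "select_rank",
    "fit_states",
    "CellStateNMF",
    "CellStateResults",
    "afi_filter",
]


def select_variable_genes(gep: pd.DataFrame, n: int = 1000) -> list:
    """Top-``n`` genes by coefficient of variation of log2(x+1).

    All-zero genes are excluded; ties are broken lexicographically by gene
    id. If fewer than ``n`` genes remain, all are returned.
    """
    logx = np.log2(gep.to_numpy(dtype=float) + 1.0)
    mean = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=1) if logx.shape[1] > 1 else np.zeros(len(mean))
    nonzero = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(nonzero, sd / np.maximum(mean, 1e-12), -np.inf)
    order = sorted(
        (i for i in range(len(cv)) if nonzero[i]),
        key=lambda i: (-cv[i], str(gep.index[i])),
    )
    if n > len(order):
        warnings.warn(
            f"requested {n} variable genes but only {len(order)} available; using all"
        )
    return [gep.index[i] for i in order[:n]]


def posneg_transform(M) -> np.ndarray:
    """Map each row m to the stacked pair (max(m, 0), max(-m, 0)).

    The first half of the output rows is the positive part, the second half
    the negative part; ``posneg_inverse`` reconstructs the input exactly.
    """
    A = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("posneg input must be finite")
    return np.vstack([np.maximum(A, 0.0), np.maximum(-A, 0.0)])


def posneg_inverse(P: np.ndarray) -> np.ndarray:
    half = P.shape[0] // 2
    return P[:half] - P[half:]


def prepare_nmf_input(gep: pd.DataFrame, n_top_genes: int = 1000):
    """Select dispersed genes, log2(x+1), standardize per gene, posneg.

    Returns (X, genes, gene_means, gene_stds); the means/stds are frozen so
    held-out cohorts can be mapped through the identical transform.
    """
    genes = select_variable_genes(gep, n_top_genes)
    sub = np.log2(gep.loc[genes].to_numpy(dtype=float) + 1.0)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (sub - mu[:, None]) / sd[:, None]
    return posneg_transform(Z), list(genes), mu, sd


def _nmf_fit(X: np.ndarray, k: int, rs: int, max_iter: int, tol: float = 1e-6):
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=rs,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    return W, model.components_, model.reconstruction_err_


def _cophenetic(consensus: np.ndarray) -> float:
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    cond = squareform(D, checks=False)
    if cond.std() < 1e-12:
        return 1.0
    Z = linkage(cond, method="average")
    c, _ = cophenet(Z, cond)
    return float(c) if np.isfinite(c) else 0.0


@dataclass(frozen=True)
class RankStability:
    """Consensus diagnostics for one candidate rank.

    cophenetic : correlation between consensus dissimilarities and the
        dendrogram's cophenetic distances.
    clusters_realized : True when cutting the consensus dendrogram at the
        rank yields that many clusters, each with at least 2 samples.
    min_within_consensus : lowest median co-clustering frequency inside any
        such cluster — 1.0 when every claimed state reproduces in every
        restart (the median is robust to a few stray samples from
        unresolvably rare states). The cophenetic coefficient alone
        saturates once clusters are well separated, so this is what
        distinguishes a rank whose clusters all reproduce from one that
        merely inherits a stable coarser structure.
    """

    cophenetic: float
    clusters_realized: bool
    min_within_consensus: float


def _rank_stability(consensus: np.ndarray, k: int) -> RankStability:
    coph = _cophenetic(consensus)
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    if squareform(D, checks=False).std() < 1e-12:
        return RankStability(coph, k == 1, 1.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    uniq = np.unique(labels)
    ok = len(uniq) == k
    min_wc = 1.0
    for c in uniq:
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            ok = False
            continue
        sub = consensus[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(len(idx), k=1)]
        min_wc = min(min_wc, float(np.median(pairs)))
    return RankStability(coph, ok, min_wc)


def nmf_rank_scan(
    X: np.ndarray,
    ranks=range(2, 21),
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 500,
) -> dict:
    """Consensus stability per candidate rank.

    Per rank, NMF is run from ``n_restarts`` random initializations; samples
    are clustered by their argmax coefficient and the consensus co-cluster
    frequency matrix is summarized as a :class:`RankStability` (cophenetic
    coefficient plus per-cluster reproducibility). Ranks with more clusters
    than samples - 1 are skipped with a warning.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    n_samples = X.shape[1]
    rng = np.random.default_rng(seed)
    out: dict = {}
    for k in ranks:
        if n_samples < k + 1:
            warnings.warn(f"rank {k} skipped: only {n_samples} samples")
            continue
        consensus = np.zeros((n_samples, n_samples))
        for _ in range(n_restarts):
            rs = int(rng.integers(2**31 - 1))
            _, H, _ = _nmf_fit(X, k, rs, max_iter)
            labels = H.argmax(axis=0)
            consensus += labels[:, None] == labels[None, :]
        consensus /= n_restarts
        out[k] = _rank_stability(consensus, k)
    return out


@dataclass
class RankSelection:
    rank: int
    low_confidence: bool = False
    degenerate: bool = False


def select_rank(cophenetic_by_rank: dict, threshold: float = 0.95) -> RankSelection:
    """Largest rank whose consensus is stable at the threshold.

    Values may be plain cophenetic coefficients or :class:`RankStability`
    objects; in the latter case a rank additionally requires every one of
    its consensus clusters to be realized (>= 2 samples each) and internally
    reproducible (mean within-cluster co-clustering >= the same threshold).
    If no rank qualifies, rank 2 is returned flagged low-confidence; if
    every scanned rank qualifies the result is flagged as degenerately
    stable.
    """
    if not cophenetic_by_rank:
        raise ValueError("empty cophenetic curve")

    def _stable(v) -> bool:
        if isinstance(v, RankStability):
            return (
                v.cophenetic >= threshold
                and v.clusters_realized
                and v.min_within_consensus >= threshold
            )
        return v >= threshold

    passing = [k for k, v in cophenetic_by_rank.items() if _stable(v)]
    if not passing:
        return RankSelection(rank=2, low_confidence=True)
    return RankSelection(
        rank=max(passing), degenerate=len(passing) == len(cophenetic_by_rank)
    )


def fit_states(X: np.ndarray, k: int, seed: int = 0, n_restarts: int = 30, max_iter: int = 2000):
    """Best-of-restarts NMF at the selected rank (lowest Frobenius error).

    Returns (W, H) with H columns on the simplex and components ordered by
    total abundance descending.
    """
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        rs = int(rng.integers(2**31 - 1))
        W, H, err = _nmf_fit(X, k, rs, max_iter)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, _ = best
    colsum = H.sum(axis=0)
    colsum = np.where(colsum > 0, colsum, 1.0)
    Hn = H / colsum
    order = np.argsort(-Hn.sum(axis=1), kind="stable")
    return W[:, order], Hn[order], H[order]


@dataclass
class CellStateResults:
    """Fitted cell-state model for one cell type.

    W rows follow the posneg layout (first half positive parts, second half
    negative parts of ``genes_used``); ``state_abundance`` rows are
    simplexes over surviving states S01..S0k.
    """

    cell_type: str
    genes_used: list
    gene_means: np.ndarray
    gene_stds: np.ndarray
    W: pd.DataFrame
    H: pd.DataFrame
    selected_rank: int
    cophenetic_by_rank: dict
    afi_by_state: dict
    dropped_states: list
    state_abundance: pd.DataFrame
    low_confidence: bool = False
    flags: dict = field(default_factory=dict)

    @property
    def state_ids(self) -> list:
        return list(self.state_abundance.columns)

    def summary(self) -> str:
        lines = [
            f"cell states: {self.cell_type}",
            f"  selected rank: {self.selected_rank}"
            + (" (low confidence)" if self.low_confidence else ""),
            f"  surviving states: {', '.join(self.state_ids)}",
            f"  dropped by AFI: {self.dropped_states or 'none'}",
            "  cophenetic by rank: "
            + ", ".join(
                f"{k}:{(c.cophenetic if isinstance(c, RankStability) else c):.3f}"
                for k, c in sorted(self.cophenetic_by_rank.items())
            ),
        ]
        return "\n".join(lines)


class CellStateNMF:
    """statsmodels-style model object: consensus NMF for one cell type.

    Parameters
    ----------
    gep : genes x samples imputed expression for one cell type.
    ranks : candidate ranks for the stability scan (default 2..20).
    n_restarts : random restarts per rank and for the final fit.
    coph_threshold : cophenetic stability threshold for rank selection.
    n_top_genes : number of high-dispersion genes kept for NMF.
    """

    def __init__(
        self,
        gep: pd.DataFrame,
        cell_type: str = "celltype",
        ranks=range(2, 21),
        n_restarts: int = 30,
        coph_threshold: float = 0.95,
        n_top_genes: int = 1000,
        scan_max_iter: int = 500,
        apply_afi: bool = True,
    ):
        self.gep = gep
        self.cell_type = cell_type
        self.ranks = list(ranks)
        self.n_restarts = n_restarts
        self.coph_threshold = coph_threshold
        self.n_top_genes = n_top_genes
        self.scan_max_iter = scan_max_iter
        self.apply_afi = apply_afi

    def fit(self, seed: int = 0) -> CellStateResults:
        X, genes, mu, sd = prepare_nmf_input(self.gep, self.n_top_genes)
        coph = nmf_rank_scan(
            X, self.ranks, n_restarts=self.n_restarts, seed=seed, max_iter=self.scan_max_iter
        )
        sel = select_rank(coph, self.coph_threshold)
        W, Hn, _ = fit_states(X, sel.rank, seed=seed + 1, n_restarts=self.n_restarts)
        samples = list(self.gep.columns)
        state_ids = [f"S{i + 1:02d}" for i in range(sel.rank)]
        rows = [f"{g}__pos" for g in genes] + [f"{g}__neg" for g in genes]
        res = CellStateResults(
            cell_type=self.cell_type,
            genes_used=genes,
            gene_means=mu,
            gene_stds=sd,
            W=pd.DataFrame(W, index=rows, columns=state_ids),
            H=pd.DataFrame(Hn, index=state_ids, columns=samples),
            selected_rank=sel.rank,
            cophenetic_by_rank=coph,
            afi_by_state={},
            dropped_states=[],
            state_abundance=pd.DataFrame(Hn.T, index=samples, columns=state_ids),
            low_confidence=sel.low_confidence,
            flags={"degenerate_stability": sel.degenerate},
        )
        if self.apply_afi:
            res = afi_filter(res)
        return res


def afi_filter(
    res: CellStateResults, top_n_genes: int = 50, max_neg_share: float = 0.5
) -> CellStateResults:
    """Drop states whose top basis loadings come mostly from negative-part
    rows of the posneg transform.

    AFI(state) = share of the state's ``top_n_genes`` largest W loadings
    located in the negative block; states with AFI > ``max_neg_share`` are
    removed and the coefficient matrix renormalized.
    """
    W = res.W.to_numpy()
    half = W.shape[0] // 2
    afi: dict = {}
    keep = []
    for i, s in enumerate(res.W.columns):
        top = np.argsort(-W[:, i], kind="stable")[:top_n_genes]
        afi[s] = float(np.mean(top >= half))
        if afi[s] <= max_neg_share:
            keep.append(s)
    if not keep:
        raise ValueError(f"all states of {res.cell_type!r} dropped by AFI filter")
    dropped = [s for s in res.W.columns if s not in keep]
    H = res.H.loc[keep]
    Hn = H.div(H.sum(axis=0).replace(0.0, 1.0), axis=1)
    return CellStateResults(
        cell_type=res.cell_type,
        genes_used=res.genes_used,
        gene_means=res.gene_means,
        gene_stds=res.gene_stds,
        W=res.W[keep],
        H=Hn,
        selected_rank=res.selected_rank,
        cophenetic_by_rank=res.cophenetic_by_rank,
        afi_by_state=afi,
        dropped_states=res.dropped_states + dropped,
        state_abundance=Hn.T.copy(),
        low_confidence=res.low_confidence,
        flags=dict(res.flags),
    )
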