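"""Ecotype discovery: clustering co-occurring cell states across samples.

Each sample is assigned a dominant state per cell type (abundance >= 33%
and a >= 15% margin over the runner-up). State co-occurrence across samples
is measured by the Jaccard index, gated by an upper-tail hypergeometric
enrichment test, and clustered by average-linkage hierarchical clustering;
candidate partitions must give every cluster at least 4 states and the
number of ecotypes is chosen by silhouette-width maximization. Samples are
assigned to their top-abundance ecotype when a Welch t-test of member versus
non-member state abundances survives Benjamini-Hochberg correction
(Q < 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, ttest_ind
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "assign_dominant_state",
    "build_occurrence",
    "jaccard_matrix",
    "cluster_ecotypes",
    "select_n_ecotypes",
    "assign_samples",
    "EcotypeDiscovery",
    "EcotypeResults",
    "combine_state_abundances",
]

UNASSIGNED = "unassigned"


def assign_dominant_state(abundances, min_abund: float = 0.33, min_margin: float = 0.15):
    """Index of the dominant state, or None when no state qualifies.

    The top state must reach ``min_abund`` and beat the runner-up by at
    least ``min_margin``; exact ties are unassigned.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0:
        return None
    order = np.argsort(-a, kind="stable")
    top = a[order[0]]
    second = a[order[1]] if a.size > 1 else 0.0
    if top < min_abund or (top - second) < min_margin or (a.size > 1 and top == second):
        return None
    return int(order[0])


def combine_state_abundances(state_results: dict) -> pd.DataFrame:
    """Samples x states abundance table over all cell types, with columns
    named '<cell type>_<state id>'."""
    parts = []
    for t, res in state_results.items():
        ab = res.state_abundance if hasattr(res, "state_abundance") else res
        part = ab.copy()
        part.columns = [f"{t}_{s}" for s in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1)


def build_occurrence(
    state_results: dict, min_abund: float = 0.33, min_margin: float = 0.15
) -> pd.DataFrame:
    """Binary states x samples presence matrix from dominant-state calls.

    Per (cell type, sample) at most one state is marked present.
    """
    rows: dict = {}
    samples = None
    for t, res in state_results.items():
        ab = res.state_abundance if hasattr(res, "state_abundance") else res
        if samples is None:
            samples = list(ab.index)
        for s in ab.columns:
            rows[f"{t}_{s}"] = np.zeros(len(samples), dtype=int)
        for si, sample in enumerate(ab.index):
            dom = assign_dominant_state(ab.loc[sample].to_numpy(), min_abund, min_margin)
            if dom is not None:
                rows[f"{t}_{ab.columns[dom]}"][si] = 1
    return pd.DataFrame(rows, index=samples).T


def jaccard_matrix(occ: pd.DataFrame, alpha: float = 0.01):
    """Hypergeometric-gated Jaccard co-occurrence matrix of states.

    J(a,b) = |Sa & Sb| / |Sa | Sb| over the sample sets in which each state
    is dominant; off-diagonal entries whose upper-tail hypergeometric
    enrichment p-value is >= ``alpha`` are set to 0. States dominant in no
    sample are excluded (with a warning). Returns (gated J, raw J, p).
    """
    if occ.shape[0] < 2:
        raise ValueError("need at least two states")
    present = occ.sum(axis=1) > 0
    if not present.all():
        warnings.warn(
            f"dropping states dominant in no sample: {list(occ.index[~present])}"
        )
        occ = occ.loc[present]
        if occ.shape[0] < 2:
            raise ValueError("fewer than two states present in any sample")
    M = occ.to_numpy(dtype=int)
    n_states, n_samples = M.shape
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    P = np.ones((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            if i == j:
                continue
            # P(overlap >= observed) drawing |Sb| from n with |Sa| marked
            P[i, j] = hypergeom.sf(inter[i, j] - 1, n_samples, sizes[i], sizes[j])
    gated = np.where(P < alpha, J, 0.0)
    np.fill_diagonal(gated, 1.0)
    np.fill_diagonal(J, 1.0)
    idx = occ.index
    return (
        pd.DataFrame(gated, index=idx, columns=idx),
        pd.DataFrame(J, index=idx, columns=idx),
        pd.DataFrame(P, index=idx, columns=idx),
    )


def cluster_ecotypes(gated_jaccard: pd.DataFrame, min_states_per_cluster: int = 4) -> list:
    """Candidate state partitions from average-linkage clustering of 1 - J.

    Cuts producing any cluster with fewer than ``min_states_per_cluster``
    states are discarded; raises if no cut survives. States whose gated
    co-occurrence with every other state is zero cannot belong to any
    ecotype and are excluded (with a warning) before clustering.
    """
    J = gated_jaccard.to_numpy()
    if not np.allclose(J, J.T):
        raise ValueError("Jaccard matrix must be symmetric")
    off = J - np.diag(np.diag(J))
    connected = off.sum(axis=1) > 0
    if not connected.all():
        isolated = list(gated_jaccard.index[~connected])
        warnings.warn(f"excluding states with no significant co-occurrence: {isolated}")
        gated_jaccard = gated_jaccard.loc[connected, connected]
        J = gated_jaccard.to_numpy()
    if J.shape[0] < 2 * min_states_per_cluster:
        raise ValueError(
            "too few co-occurring states to form at least two ecotypes of "
            f"{min_states_per_cluster} states"
        )
    D = 1.0 - J
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    n_states = J.shape[0]
    candidates = []
    for n_clust in range(2, n_states // min_states_per_cluster + 1):
        labels = fcluster(Z, t=n_clust, criterion="maxclust")
        _, counts = np.unique(labels, return_counts=True)
        if len(counts) != n_clust or counts.min() < min_states_per_cluster:
            continue
        candidates.append(
            {s: int(l) for s, l in zip(gated_jaccard.index, labels)}
        )
    if not candidates:
        raise ValueError(
            "no clustering cut yields clusters with at least "
            f"{min_states_per_cluster} states each"
        )
    return candidates


def _ecotype_abundance(mapping: dict, state_abundance: pd.DataFrame) -> pd.DataFrame:
    ecos = sorted(set(mapping.values()))
    cols = {}
    for e in ecos:
        members = [s for s, ee in mapping.items() if ee == e and s in state_abundance.columns]
        cols[f"LPE{e}"] = state_abundance[members].mean(axis=1)
    ab = pd.DataFrame(cols, index=state_abundance.index)
    total = ab.sum(axis=1).replace(0.0, 1.0)
    return ab.div(total, axis=0)


def select_n_ecotypes(
    candidates: list, gated_jaccard: pd.DataFrame, state_abundance: pd.DataFrame
):
    """Pick the candidate partition maximizing mean silhouette width of
    states under distance 1 - J (ties -> fewer ecotypes), and compute
    per-sample ecotype abundances (mean of member states, renormalized).

    Returns (mapping, ecotype_abundance, silhouette_by_candidate).
    """
    if not candidates:
        raise ValueError("no candidate partitions")
    clustered = [s for s in gated_jaccard.index if s in candidates[0]]
    sub = gated_jaccard.loc[clustered, clustered]
    D = 1.0 - sub.to_numpy()
    np.fill_diagonal(D, 0.0)
    scored = []
    for mapping in candidates:
        labels = np.array([mapping[s] for s in sub.index])
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        scored.append((sil, len(set(labels)), mapping))
    best_sil = max(s for s, _, _ in scored)
    best = min(
        (c for c in scored if abs(c[0] - best_sil) < 1e-12), key=lambda c: c[1]
    )
    mapping = best[2]
    abundance = _ecotype_abundance(mapping, state_abundance)
    return mapping, abundance, {i: s for i, (s, _, _) in enumerate(scored)}


def assign_samples(
    mapping: dict,
    state_abundance: pd.DataFrame,
    q_max: float = 0.25,
):
    """Assign each sample to its maximum-abundance ecotype when significant.

    Per sample, a Welch t-test compares the abundances of the top ecotype's
    member states against all other states; p-values are Benjamini-Hochberg
    corrected across samples and a sample is assigned only when Q < q_max.
    Returns (assignments Series, Q Series, ecotype_abundance).
    """
    abundance = _ecotype_abundance(mapping, state_abundance)
    ecos = sorted(set(mapping.values()))
    members = {
        e: [s for s, ee in mapping.items() if ee == e and s in state_abundance.columns]
        for e in ecos
    }
    top = abundance.idxmax(axis=1)
    pvals = []
    for sample in state_abundance.index:
        e = int(str(top[sample]).replace("LPE", ""))
        mem = state_abundance.loc[sample, members[e]].to_numpy(dtype=float)
        non = state_abundance.loc[
            sample, [c for c in state_abundance.columns if c not in members[e]]
        ].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = ttest_ind(mem, non, equal_var=False)
        pvals.append(1.0 if not np.isfinite(p) else float(p))
    q = multipletests(pvals, method="fdr_bh")[1]
    assigned = [
        top[sample] if q[i] < q_max else UNASSIGNED
        for i, sample in enumerate(state_abundance.index)
    ]
    return (
        pd.Series(assigned, index=state_abundance.index, name="ecotype"),
        pd.Series(q, index=state_abundance.index, name="Q"),
        abundance,
    )


@dataclass
class EcotypeResults:
    """Fitted ecotype model: state -> ecotype mapping with per-sample
    abundances and assignments; reusable frozen on new cohorts."""

    state_to_ecotype: dict
    n_ecotypes: int
    jaccard: pd.DataFrame
    jaccard_raw: pd.DataFrame
    pvalues: pd.DataFrame
    occurrence: pd.DataFrame
    ecotype_abundance: pd.DataFrame
    assignments: pd.Series
    qvalues: pd.Series
    q_max: float = 0.25
    silhouette_by_candidate: dict = field(default_factory=dict)

    @property
    def ecotype_ids(self) -> list:
        return sorted({f"LPE{e}" for e in self.state_to_ecotype.values()})

    def apply(self, state_abundance: pd.DataFrame):
        """Frozen-model assignment of a new cohort's state abundances."""
        return assign_samples(self.state_to_ecotype, state_abundance, self.q_max)

    def summary(self) -> str:
        counts = self.assignments.value_counts()
        lines = [
            f"ecotype model: {self.n_ecotypes} ecotypes over "
            f"{len(self.state_to_ecotype)} states",
            "  states per ecotype: "
            + ", ".join(
                f"LPE{e}:{sum(1 for v in self.state_to_ecotype.values() if v == e)}"
                for e in sorted(set(self.state_to_ecotype.values()))
            ),
            "  sample assignments: "
            + ", ".join(f"{k}:{v}" for k, v in counts.items()),
        ]
        return "\n".join(lines)


class EcotypeDiscovery:
    """statsmodels-style model: discover ecotypes from fitted cell states.

    Parameters
    ----------
    state_results : dict of cell type -> CellStateResults (or samples x
        states abundance frames).
    alpha : hypergeometric gate on co-occurrence significance.
    min_states_per_cluster : minimum states per ecotype.
    q_max : BH threshold for sample assignment.
    """

    def __init__(
        self,
        state_results: dict,
        alpha: float = 0.01,
        min_states_per_cluster: int = 4,
        q_max: float = 0.25,
        min_abund: float = 0.33,
        min_margin: float = 0.15,
    ):
        self.state_results = state_results
        self.alpha = alpha
        self.min_states_per_cluster = min_states_per_cluster
        self.q_max = q_max
        self.min_abund = min_abund
        self.min_margin = min_margin

    def fit(self) -> EcotypeResults:
        occ = build_occurrence(self.state_results, self.min_abund, self.min_margin)
        gated, raw, pvals = jaccard_matrix(occ, self.alpha)
        candidates = cluster_ecotypes(gated, self.min_states_per_cluster)
        abundance_all = combine_state_abundances(self.state_results)
        abundance_all = abundance_all[[c for c in abundance_all.columns if c in gated.index]]
        mapping, _, sils = select_n_ecotypes(candidates, gated, abundance_all)
        assignments, q, eco_ab = assign_samples(mapping, abundance_all, self.q_max)
        return EcotypeResults(
            state_to_ecotype=mapping,
            n_ecotypes=len(set(mapping.values())),
            jaccard=gated,
            jaccard_raw=raw,
            pvalues=pvals,
            occurrence=occ,
            ecotype_abundance=eco_ab,
            assignments=assignments,
            qvalues=q,
            q_max=self.q_max,
            silhouette_by_candidate=sils,
        )
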