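"""Spatial recovery of cell states and ecotypes with Moran's I.

Per spot, the dominant state of each cell type is set to 1 (others 0),
multiplied by the parent cell-type fraction from spot deconvolution, and
scaled so the 99th percentile within each cell type equals 1 (capped at 1).
Ecotype abundance per spot is the mean of its member states' scaled values.
Spatial aggregation is tested with Moran's I against a label-permutation
null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .ecotypes import assign_dominant_state

__all__ = [
    "spot_state_abundance",
    "spot_ecotype_abundance",
    "build_spatial_weights",
    "MoranResult",
    "morans_i",
]


def spot_state_abundance(
    spot_fractions: pd.DataFrame,
    state_abundance_by_type: dict,
    quantile: float = 99.0,
) -> pd.DataFrame:
    """Scaled per-spot state abundances (spots x states).

    ``spot_fractions`` is the spots x cell-types simplex from deconvolving
    each spot; ``state_abundance_by_type`` maps cell type -> spots x states
    coefficients (from frozen-model recovery on spot expression). Dominant
    state <- 1, others <- 0; multiplied by the parent type fraction; divided
    per type by its 99th-percentile spot value (linear-interpolation
    quantile) and capped at 1.
    """
    spots = list(spot_fractions.index)
    cols = {}
    for t, ab in state_abundance_by_type.items():
        if t not in spot_fractions.columns:
            raise ValueError(f"spot fractions lack cell type {t!r}")
        frac = spot_fractions[t].to_numpy(dtype=float)
        vals = np.zeros((len(spots), ab.shape[1]))
        for si, s in enumerate(spots):
            dom = assign_dominant_state(ab.loc[s].to_numpy(), min_abund=0.0, min_margin=0.0)
            if dom is not None:
                vals[si, dom] = frac[si]
        dominant_value = vals.max(axis=1)
        p99 = float(np.percentile(dominant_value, quantile))
        if p99 <= 0:
            warnings.warn(f"cell type {t!r} has zero abundance across spots")
            scaled = vals
        else:
            scaled = np.minimum(vals / p99, 1.0)
        for j, s in enumerate(ab.columns):
            cols[f"{t}_{s}"] = scaled[:, j]
    return pd.DataFrame(cols, index=spots)


def spot_ecotype_abundance(field: pd.DataFrame, state_to_ecotype: dict) -> pd.DataFrame:
    """Per-spot ecotype abundance = mean of member-state scaled values."""
    missing = [s for s in state_to_ecotype if s not in field.columns]
    if missing:
        raise ValueError(f"state field missing states: {missing}")
    out = {}
    for e in sorted(set(state_to_ecotype.values())):
        members = [s for s, ee in state_to_ecotype.items() if ee == e]
        out[f"LPE{e}"] = field[members].mean(axis=1)
    return pd.DataFrame(out, index=field.index)


def build_spatial_weights(coordinates: pd.DataFrame, neighbor_rule: str = "rook") -> sparse.csr_matrix:
    """Binary spatial weight matrix.

    'rook': 4-neighborhood on integer (row, col) grids; 'hex': Visium array
    neighborhood ((dr, dc) in {(0, +-2), (+-1, +-1)}); 'knn:k': k nearest
    Euclidean neighbors (symmetrized).
    """
    rc = coordinates[["row", "col"]].to_numpy(dtype=float)
    n = len(rc)
    if neighbor_rule.startswith("knn:"):
        k = int(neighbor_rule.split(":", 1)[1])
        d2 = ((rc[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        W = np.zeros((n, n))
        nearest = np.argsort(d2, axis=1)[:, :k]
        for i in range(n):
            W[i, nearest[i]] = 1.0
        W = np.maximum(W, W.T)
        return sparse.csr_matrix(W)
    dr = np.abs(rc[:, None, 0] - rc[None, :, 0])
    dc = np.abs(rc[:, None, 1] - rc[None, :, 1])
    if neighbor_rule == "rook":
        adj = (dr + dc) == 1
    elif neighbor_rule == "hex":
        adj = ((dr == 0) & (dc == 2)) | ((dr == 1) & (dc == 1))
    else:
        raise ValueError(f"unknown neighbor rule {neighbor_rule!r}")
    np.fill_diagonal(adj, False)
    return sparse.csr_matrix(adj.astype(float))


@dataclass
class MoranResult:
    I: float
    p_value: float
    expected: float
    n_spots: int
    n_permutations: int


def morans_i(
    values,
    coordinates: pd.DataFrame,
    neighbor_rule: str = "rook",
    n_permutations: int = 999,
    seed: int = 0,
    weights: sparse.spmatrix | None = None,
) -> MoranResult:
    """Global Moran's I with an upper-tail permutation p-value.

    I = (n / sum(W)) * (z' W z) / (z' z) with z the mean-centered values;
    under no autocorrelation E[I] = -1/(n-1). Raises on constant fields
    (autocorrelation undefined) or fewer than 5 spots.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 spots")
    if np.ptp(z) == 0:
        raise ValueError("undefined autocorrelation: constant field")
    z = z - z.mean()
    W = weights if weights is not None else build_spatial_weights(coordinates, neighbor_rule)
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("weight matrix has no neighbors")
    denom = float((z**2).sum())
    I_obs = float(n / s0 * (z @ (W @ z)) / denom)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        I_p = float(n / s0 * (zp @ (W @ zp)) / denom)
        if I_p >= I_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return MoranResult(
        I=I_obs,
        p_value=p,
        expected=-1.0 / (n - 1),
        n_spots=n,
        n_permutations=n_permutations,
    )
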