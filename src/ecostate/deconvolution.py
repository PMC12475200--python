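"""Digital cytometry: signature matrices, nu-SVR deconvolution, two-tier
composition, lineage pooling, genotype-anchored LP rescaling, and cell
type-specific expression imputation.

Bulk TPM mixtures are deconvolved against a marker-gene signature matrix by
linear-kernel nu-support-vector regression; the rare malignant LP fraction,
systematically inflated in expression space by the LP cells' high per-cell
RNA content, is rescaled using clonal variant allele frequencies
(tumor fraction of a heterozygous clonal mutation = 2 x VAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr
from sklearn.svm import NuSVR

__all__ = [
    "SignatureMatrix",
    "AnchorFit",
    "CellTypeGEP",
    "DEFAULT_LINEAGE_MAP",
    "build_signature_matrix",
    "SupportVectorDeconvolution",
    "DeconvolutionResults",
    "svr_deconvolve",
    "compose_two_tier",
    "pool_lineages",
    "filter_variants",
    "genotype_anchor_scale",
    "impute_celltype_geps",
]

#: fine type -> one of the 14 lineages. For the synthetic panel the fine
#: types already are lineages, so this is the identity; real LM22-style
#: panels supply their own map.
DEFAULT_LINEAGE_MAP = {
    "B": "B", "Dendritic": "Dendritic", "Endothelial": "Endothelial",
    "Fibroblast": "Fibroblast", "Mast": "Mast", "MonoMac": "MonoMac",
    "NK": "NK", "Neutrophil": "Neutrophil", "Plasma": "Plasma",
    "CD4T": "CD4T", "CD8T": "CD8T", "Tfh": "Tfh", "Treg": "Treg", "LP": "LP",
}


@dataclass
class SignatureMatrix:
    """Markers x cell-types signature with its tier ('fine' or 'coarse')."""

    values: pd.DataFrame
    tier: str = "fine"
    markers_by_type: dict = field(default_factory=dict)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values.to_numpy()))


@dataclass
class AnchorFit:
    """Through-origin fit of 2 x median VAF on the estimated LP fraction.

    scale_factor = 1/slope is the factor the LP estimate is divided by; on
    the paper's cohort it was 16.67.
    """

    slope: float
    scale_factor: float
    pairs: pd.DataFrame
    correlation: float

    def __post_init__(self):
        assert self.slope > 0
        assert abs(self.scale_factor * self.slope - 1.0) < 1e-9


@dataclass
class CellTypeGEP:
    """Imputed cell type-specific expression: per type a genes x samples
    table restricted to its imputed genes; types with fewer than
    ``min_genes`` imputed genes are excluded."""

    geps: dict
    imputed_genes: dict
    excluded_types: list
    min_genes: int = 50


def build_signature_matrix(
    reference_profiles: pd.DataFrame,
    max_markers_per_type: int = 50,
    tier: str = "fine",
    min_markers_per_type: int = 10,
) -> SignatureMatrix:
    """Select marker genes per cell type and assemble a signature matrix.

    Candidate markers for a type are genes strictly exceeding every other
    type, ranked by fold-change against the next-highest type. The per-type
    marker count is scanned from ``min_markers_per_type`` to
    ``max_markers_per_type`` and the count minimizing the signature's
    condition number is kept (ties -> fewer markers).
    """
    prof = reference_profiles
    types = list(prof.columns)
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    vals = prof.to_numpy()
    candidates: dict = {}
    for j, t in enumerate(types):
        others = np.delete(vals, j, axis=1).max(axis=1)
        fold = vals[:, j] / np.maximum(others, 1e-12)
        ok = np.where(fold > 1.0)[0]
        if len(ok) < min_markers_per_type:
            raise ValueError(
                f"cell type {t!r} has only {len(ok)} candidate markers "
                f"(need >= {min_markers_per_type})"
            )
        order = ok[np.argsort(-fold[ok], kind="stable")]
        candidates[t] = [prof.index[i] for i in order[:max_markers_per_type]]

    best_m, best_cond = None, np.inf
    max_m = min(max_markers_per_type, max(len(c) for c in candidates.values()))
    for m in range(min_markers_per_type, max_m + 1):
        genes: list = []
        for t in types:
            genes.extend(g for g in candidates[t][:m] if g not in genes)
        cond = float(np.linalg.cond(prof.loc[genes].to_numpy()))
        if np.isfinite(cond) and cond < best_cond:
            best_cond, best_m = cond, m
    if best_m is None:
        raise ValueError("no marker count yields a finite condition number")
    marker_by_type = {t: candidates[t][:best_m] for t in types}
    genes = []
    for t in types:
        genes.extend(g for g in marker_by_type[t] if g not in genes)
    return SignatureMatrix(values=prof.loc[genes].copy(), tier=tier, markers_by_type=marker_by_type)


class SupportVectorDeconvolution:
    """nu-SVR deconvolution of bulk TPM mixtures against a signature.

    Per sample, both the signature and the mixture are z-scored over their
    shared genes (case-insensitive symbol match); a linear-kernel nu-SVR is
    fitted for nu in {0.25, 0.5, 0.75} and the fit with the lowest RMSE is
    kept; negative coefficients are clipped to zero and the rest normalized
    to a simplex.
    """

    NU_GRID = (0.25, 0.5, 0.75)

    def __init__(self, bulk: pd.DataFrame, signature: SignatureMatrix | pd.DataFrame):
        sig = signature.values if isinstance(signature, SignatureMatrix) else signature
        bulk_upper = bulk.copy()
        bulk_upper.index = [str(g).upper() for g in bulk.index]
        bulk_upper = bulk_upper[~bulk_upper.index.duplicated(keep="first")]
        sig_upper = sig.copy()
        sig_upper.index = [str(g).upper() for g in sig.index]
        sig_upper = sig_upper[~sig_upper.index.duplicated(keep="first")]
        shared = [g for g in sig_upper.index if g in set(bulk_upper.index)]
        if len(shared) < 0.5 * sig_upper.shape[0]:
            missing = sorted(set(sig_upper.index) - set(shared))
            raise ValueError(
                f"only {len(shared)}/{sig_upper.shape[0]} signature genes found in "
                f"bulk (need >= 50%); missing e.g. {missing[:10]}"
            )
        self.signature = sig_upper.loc[shared]
        self.bulk = bulk_upper.loc[shared, :]
        self.sample_ids = list(bulk.columns)
        self.cell_types = list(sig_upper.columns)
        self.n_shared_genes = len(shared)

    def fit(self) -> "DeconvolutionResults":
        X = self.signature.to_numpy()
        Xz = (X - X.mean()) / X.std()
        fracs = np.zeros((len(self.sample_ids), len(self.cell_types)))
        rmses, nus = [], []
        for si, s in enumerate(self.sample_ids):
            y = self.bulk[s].to_numpy(dtype=float)
            if not np.any(y > 0):
                raise ValueError(f"sample {s!r} is all zero")
            yz = (y - y.mean()) / y.std()
            best = None
            for nu in self.NU_GRID:
                model = NuSVR(nu=nu, C=1.0, kernel="linear")
                model.fit(Xz, yz)
                rmse = float(np.sqrt(np.mean((model.predict(Xz) - yz) ** 2)))
                if best is None or rmse < best[0]:
                    best = (rmse, nu, model.coef_.ravel().copy())
            rmse, nu, coef = best
            coef = np.clip(coef, 0.0, None)
            total = coef.sum()
            if total <= 0:
                coef = np.full_like(coef, 1.0 / len(coef))
            else:
                coef = coef / total
            fracs[si] = coef
            rmses.append(rmse)
            nus.append(nu)
        fractions = pd.DataFrame(fracs, index=self.sample_ids, columns=self.cell_types)
        return DeconvolutionResults(
            model=self,
            fractions=fractions,
            rmse=pd.Series(rmses, index=self.sample_ids, name="rmse"),
            nu_selected=pd.Series(nus, index=self.sample_ids, name="nu"),
        )


@dataclass
class DeconvolutionResults:
    model: SupportVectorDeconvolution
    fractions: pd.DataFrame
    rmse: pd.Series
    nu_selected: pd.Series

    def summary(self) -> str:
        lines = [
            "nu-SVR deconvolution",
            f"  samples: {len(self.fractions)}   cell types: {self.fractions.shape[1]}",
            f"  shared signature genes: {self.model.n_shared_genes}",
            f"  median fit RMSE (z-scale): {self.rmse.median():.4f}",
            "  mean fractions:",
        ]
        for t, v in self.fractions.mean().items():
            lines.append(f"    {t:>12s}  {v:.4f}")
        return "\n".join(lines)


def svr_deconvolve(bulk: pd.DataFrame, sig) -> pd.DataFrame:
    """Functional wrapper: bulk (genes x samples) + signature -> samples x
    cell-types fraction simplex."""
    return SupportVectorDeconvolution(bulk, sig).fit().fractions


def compose_two_tier(fine: pd.DataFrame, coarse: pd.DataFrame, immune_label: str = "immune") -> pd.DataFrame:
    """Combine fine-tier (immune + LP) and coarse-tier fractions.

    Every fine-type fraction is multiplied by the coarse immune fraction and
    joined with the remaining coarse fractions; row sums are preserved
    exactly (fine rows are simplexes).
    """
    if list(fine.index) != list(coarse.index):
        raise ValueError("fine and coarse fraction matrices must share sample ids in order")
    if immune_label not in coarse.columns:
        raise ValueError(f"coarse tier lacks {immune_label!r} column")
    out = fine.mul(coarse[immune_label], axis=0)
    for c in coarse.columns:
        if c != immune_label:
            out[c] = coarse[c]
    return out


def pool_lineages(frac: pd.DataFrame, lineage_map: dict) -> pd.DataFrame:
    """Sum fine-type fractions into lineages; row sums are preserved."""
    missing = [t for t in frac.columns if t not in lineage_map]
    if missing:
        raise ValueError(f"lineage map missing fine types: {missing}")
    lineages: dict = {}
    for t in frac.columns:
        lineages.setdefault(lineage_map[t], []).append(t)
    out = pd.DataFrame(
        {lin: frac[cols].sum(axis=1) for lin, cols in lineages.items()},
        index=frac.index,
    )
    return out


def filter_variants(gt: pd.DataFrame) -> pd.DataFrame:
    """Variant-call specificity filters: >= 4 supporting reads, and
    VAF > 3% for tumor or VAF > 0.1% with duplex support for plasma."""
    if "compartment" not in gt.columns:
        raise ValueError("genotype table must carry a 'compartment' column")
    reads_ok = gt["supporting_reads"] >= 4
    tumor_ok = (gt["compartment"] == "tumor") & (gt["vaf"] > 0.03)
    plasma_ok = (
        (gt["compartment"] == "plasma")
        & (gt["vaf"] > 0.001)
        & gt["duplex_support"].astype(bool)
    )
    return gt[reads_ok & (tumor_ok | plasma_ok)].copy()


def genotype_anchor_scale(
    frac: pd.DataFrame,
    gt: pd.DataFrame,
    lp_type: str = "LP",
    min_pairs: int = 3,
):
    """Rescale the systematically inflated LP fraction using clonal VAFs.

    Per anchored sample, the genotype-implied tumor fraction is
    2 x median(VAF) over passing variants. A through-origin least-squares
    fit of that quantity on the estimated LP fraction gives the slope; every
    sample's LP fraction is divided by scale_factor = 1/slope and the
    decrease is met by a symmetric proportional increase of the other cell
    types, so each row sums to 1 and the corrected LP value is exactly the
    rescaled estimate (making one application idempotent under
    re-anchoring). Returns (scaled FractionMatrix, AnchorFit).
    """
    if lp_type not in frac.columns:
        raise ValueError(f"fraction matrix lacks {lp_type!r}")
    med = gt.groupby("sample_id")["vaf"].median()
    pairs = []
    for s in frac.index:
        if s in med.index:
            pairs.append((s, float(frac.loc[s, lp_type]), 2.0 * float(med[s])))
    pairs = pd.DataFrame(pairs, columns=["sample_id", "lp_estimate", "two_median_vaf"])
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} anchor pairs (need >= {min_pairs})")
    x = pairs["lp_estimate"].to_numpy()
    y = pairs["two_median_vaf"].to_numpy()
    slope = float((x * y).sum() / (x * x).sum())
    if slope <= 0:
        raise ValueError(f"non-positive anchor slope {slope}")
    corr = float(pearsonr(x, y)[0]) if len(pairs) > 2 and x.std() > 0 and y.std() > 0 else np.nan
    fit = AnchorFit(slope=slope, scale_factor=1.0 / slope, pairs=pairs, correlation=corr)

    out = frac.copy()
    lp_old = out[lp_type].to_numpy(dtype=float)
    lp_new = lp_old / fit.scale_factor
    others = [c for c in out.columns if c != lp_type]
    with np.errstate(divide="ignore", invalid="ignore"):
        bump = np.where(lp_old < 1.0, (1.0 - lp_new) / (1.0 - lp_old), 1.0)
    out[others] = out[others].mul(bump, axis=0)
    out[lp_type] = lp_new
    return out, fit


def impute_celltype_geps(
    bulk: pd.DataFrame,
    frac: pd.DataFrame,
    sig: SignatureMatrix | None = None,
    r2_min: float = 0.2,
    min_genes: int = 50,
) -> CellTypeGEP:
    """Two-stage imputation of cell type-specific expression from bulk.

    Stage 1 (group): per gene, non-negative least squares of expression
    across samples on the fraction matrix gives a per-type mean expression.
    Stage 2 (per sample): the type-specific value is the group estimate
    scaled by (1 + w * relative residual), where w is the type's share of
    the total fraction of types expressing the gene. A gene is imputed for a
    type when the group fit explains the gene (R^2 >= ``r2_min``) and the
    type expresses it (positive group coefficient); types retaining fewer
    than ``min_genes`` genes are excluded.
    """
    samples = list(bulk.columns)
    if list(frac.index) != samples:
        frac = frac.reindex(samples)
        if frac.isna().any().any():
            raise ValueError("fraction matrix does not cover all bulk samples")
    F = frac.to_numpy()
    types = list(frac.columns)
    nonzero = [j for j in range(len(types)) if F[:, j].max() > 0]
    if np.linalg.matrix_rank(F[:, nonzero]) < len(nonzero):
        raise ValueError(
            "fraction matrix is rank deficient; more samples (or fewer cell "
            "types) are needed for imputation"
        )
    genes = list(bulk.index)
    Y = bulk.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    B = np.zeros((n_genes, len(types)))
    R2 = np.zeros(n_genes)
    resid_rel = np.zeros((n_genes, n_samples))
    for gi in range(n_genes):
        y = Y[gi]
        beta, _ = nnls(F, y)
        B[gi] = beta
        yhat = F @ beta
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot < 1e-12:
            R2[gi] = 1.0 if ss_res < 1e-9 * max(1.0, float((y**2).sum())) else 0.0
        else:
            R2[gi] = 1.0 - ss_res / ss_tot
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(yhat > 1e-12, (y - yhat) / yhat, 0.0)
        resid_rel[gi] = rr

    geps: dict = {}
    imputed: dict = {}
    excluded: list = []
    for j, t in enumerate(types):
        keep = np.where((R2 >= r2_min) & (B[:, j] > 0))[0]
        if len(keep) < min_genes:
            excluded.append(t)
            imputed[t] = [genes[i] for i in keep]
            continue
        vals = np.zeros((len(keep), n_samples))
        for row, gi in enumerate(keep):
            expressing = B[gi] > 0
            denom = F[:, expressing].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(denom > 0, F[:, j] / np.maximum(denom, 1e-12), 0.0)
            vals[row] = np.clip(B[gi, j] * (1.0 + w * resid_rel[gi]), 0.0, None)
        geps[t] = pd.DataFrame(vals, index=[genes[i] for i in keep], columns=samples)
        imputed[t] = [genes[i] for i in keep]
    return CellTypeGEP(geps=geps, imputed_genes=imputed, excluded_types=excluded, min_genes=min_genes)
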