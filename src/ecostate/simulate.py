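"""Synthetic cohorts with planted ground truth.

Every input the pipeline consumes can be generated here: a reference
expression panel with one rare malignant "LP" cell type of elevated per-cell
RNA content, bulk cohorts mixing 14 cell types with 2-4 latent
transcriptional states per type and sample-level ecotypes that induce state
co-occurrence, genotype tables whose clonal variant allele frequencies obey
LP_fraction = 2 x median VAF, spatially clustered ecotype regions on a grid,
clonotype tables with controlled Shannon entropy, and survival times whose
hazard depends on one ecotype's abundance.

The generators are deterministic given their seed, and return the planted
truth alongside the data so every downstream stage can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "CellTypeSpec",
    "ReferencePanel",
    "SyntheticTruth",
    "SpotGrid",
    "generate_reference_panel",
    "default_cell_type_spec",
    "default_ecotype_state_map",
    "generate_bulk_cohort",
    "generate_benign_cohort",
    "generate_celltype_gep",
    "generate_genotype_table",
    "generate_spatial_grid",
    "generate_clonotype_tables",
    "generate_survival",
]

#: the canonical 14 lineages; "LP" is the malignant lymphocyte-predominant type
DEFAULT_LINEAGES = (
    "B",
    "Dendritic",
    "Endothelial",
    "Fibroblast",
    "Mast",
    "MonoMac",
    "NK",
    "Neutrophil",
    "Plasma",
    "CD4T",
    "CD8T",
    "Tfh",
    "Treg",
    "LP",
)


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: its name, number of latent states, and relative
    per-cell RNA content (LP is much greater than 1)."""

    name: str
    k_states: int
    rna_content: float = 1.0


@dataclass
class ReferencePanel:
    """Reference expression panel used to build mixtures and signatures.

    base_profiles : genes x cell-types mean expression (non-negative).
    state_programs : per cell type, genes x k multiplicative fold-change
        vectors with geometric mean 1 over genes.
    rna_content : per-type relative RNA mass per cell.
    marker_genes : per-type list of genes exceeding all other types by at
        least the requested fold.
    """

    gene_ids: list
    cell_types: list
    lp_type: str
    base_profiles: pd.DataFrame
    state_programs: dict
    rna_content: pd.Series
    marker_genes: dict
    program_genes: dict
    seed: int

    @property
    def k_states(self) -> dict:
        return {t: self.state_programs[t].shape[1] for t in self.cell_types}


@dataclass
class SyntheticTruth:
    """Planted ground truth for one bulk cohort.

    cell_fractions and expression_fractions are samples x cell-types row
    simplexes; expression fractions are the RNA-mass-weighted fractions that
    deconvolution of TPM mixtures actually estimates.
    """

    cell_fractions: pd.DataFrame
    expression_fractions: pd.DataFrame
    state_labels: pd.DataFrame
    ecotype_labels: pd.Series
    inflation_factor: float
    seed: int
    ecotype_state_map: dict = field(default_factory=dict)


@dataclass
class SpotGrid:
    """Synthetic spatial grid (Visium-like): spots x genes counts, integer
    (row, col) array coordinates, and the planted ecotype per spot."""

    spot_ids: list
    coordinates: pd.DataFrame
    counts: pd.DataFrame
    truth_ecotype_per_spot: pd.Series
    truth_expression_fractions: pd.DataFrame
    truth_state_labels: pd.DataFrame
    seed: int


def default_cell_type_spec(lp_rna_content: float = 16.67) -> list:
    """The study conditions: 14 lineages, 2-4 states each, LP at ~16.67x
    relative RNA content."""
    k = {
        "B": 4, "Dendritic": 2, "Endothelial": 2, "Fibroblast": 2,
        "Mast": 2, "MonoMac": 3, "NK": 2, "Neutrophil": 2, "Plasma": 2,
        "CD4T": 3, "CD8T": 3, "Tfh": 3, "Treg": 2, "LP": 3,
    }
    return [
        CellTypeSpec(t, k[t], lp_rna_content if t == "LP" else 1.0)
        for t in DEFAULT_LINEAGES
    ]


def _as_spec(item) -> CellTypeSpec:
    if isinstance(item, CellTypeSpec):
        return item
    return CellTypeSpec(*item)


def generate_reference_panel(
    n_genes: int,
    cell_type_spec,
    marker_strength: float = 8.0,
    program_fold: float = 3.0,
    n_marker_genes: int = 20,
    seed: int = 0,
) -> ReferencePanel:
    """Build a reference panel with planted marker and state-program genes.

    Each cell type receives ``n_marker_genes`` genes whose base expression
    exceeds every other type by at least ``marker_strength`` fold, plus one
    disjoint block of elevated genes per latent state carrying that state's
    multiplicative program (fold ``program_fold`` on the block, 1 elsewhere,
    then rescaled to geometric mean 1 over genes).
    """
    if n_genes < 200:
        raise ValueError("n_genes must be >= 200")
    specs = [_as_spec(s) for s in cell_type_spec]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell type names")
    lp = [s.name for s in specs if s.name == "LP"]
    if len(lp) != 1:
        raise ValueError("exactly one cell type must be named 'LP'")
    for s in specs:
        if not 2 <= s.k_states <= 4:
            raise ValueError(
                f"k_states for {s.name!r} must be in 2..4, got {s.k_states}"
            )
        if s.rna_content <= 0:
            raise ValueError("rna_content must be positive")

    total_states = sum(s.k_states for s in specs)
    reserved = n_genes - n_marker_genes * len(specs)
    n_prog = min(30, reserved // total_states)
    if n_prog < 8:
        raise ValueError(
            "n_genes too small for the requested types/states "
            f"(would leave {n_prog} genes per state program)"
        )

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    # lognormal background expression (median ~10, TPM-like arbitrary units),
    # then planted marker / program blocks
    base = rng.lognormal(mean=2.3, sigma=0.6, size=(n_genes, len(specs)))

    cursor = 0
    marker_genes: dict = {}
    program_genes: dict = {}
    for j, s in enumerate(specs):
        block = slice(cursor, cursor + n_marker_genes)
        cursor += n_marker_genes
        others = [jj for jj in range(len(specs)) if jj != j]
        base[block, :][:, others] = rng.uniform(
            5.0, 15.0, size=(n_marker_genes, len(others))
        )
        margin = rng.uniform(1.1, 1.6, size=n_marker_genes)
        base[block, j] = marker_strength * base[block, :][:, others].max(axis=1) * margin
        marker_genes[s.name] = [gene_ids[i] for i in range(block.start, block.stop)]
    for j, s in enumerate(specs):
        program_genes[s.name] = []
        for _ in range(s.k_states):
            block = slice(cursor, cursor + n_prog)
            cursor += n_prog
            others = [jj for jj in range(len(specs)) if jj != j]
            # moderately elevated in the owner type so imputation attributes
            # the state signal to it, but well below marker strength and
            # close enough to the background scale that dispersion-based
            # gene selection still ranks these genes by their state signal
            base[block, :][:, others] = rng.uniform(5.0, 15.0, size=(n_prog, len(others)))
            base[block, j] = rng.uniform(1.5, 2.5) * base[block, :][:, others].max(axis=1)
            program_genes[s.name].append([gene_ids[i] for i in range(block.start, block.stop)])

    base_profiles = pd.DataFrame(base, index=gene_ids, columns=names)

    state_programs: dict = {}
    for s in specs:
        cols = {}
        for st in range(s.k_states):
            vec = np.ones(n_genes)
            idx = [gene_ids.index(g) for g in program_genes[s.name][st]]
            vec[idx] = program_fold
            vec /= gmean(vec)
            cols[f"S{st + 1:02d}"] = vec
        state_programs[s.name] = pd.DataFrame(cols, index=gene_ids)

    rna = pd.Series({s.name: float(s.rna_content) for s in specs})
    return ReferencePanel(
        gene_ids=gene_ids,
        cell_types=names,
        lp_type="LP",
        base_profiles=base_profiles,
        state_programs=state_programs,
        rna_content=rna,
        marker_genes=marker_genes,
        program_genes=program_genes,
        seed=seed,
    )


def default_ecotype_state_map(panel: ReferencePanel, n_ecotypes: int = 3, seed: int = 0) -> dict:
    """A deterministic ecotype -> (cell type -> state index) map in which
    every ecotype pins a distinct state wherever the type has enough states
    (types with fewer states than ecotypes wrap around, so two ecotypes may
    share a state there)."""
    del seed  # kept for call-site stability; the map is deterministic
    out: dict = {}
    for e in range(1, n_ecotypes + 1):
        mapping = {}
        for t in panel.cell_types:
            mapping[t] = (e - 1) % panel.k_states[t]
        out[e] = mapping
    return out


def _normalize_tpm(x: np.ndarray) -> np.ndarray:
    return x / x.sum(axis=0, keepdims=True) * 1e6


def generate_bulk_cohort(
    panel: ReferencePanel,
    n_samples: int,
    n_ecotypes: int,
    ecotype_state_map: dict,
    lp_cell_fraction_range=(0.005, 0.02),
    noise_model=None,
    unassigned_fraction: float = 0.15,
    seed: int = 0,
):
    """Mix a bulk cohort from the panel and return (ExpressionMatrix, truth).

    Sample expression is the RNA-mass-weighted mixture of per-type base
    profiles modulated by that sample's planted state program, optionally
    with multiplicative lognormal noise, TPM-normalized to 1e6 per column.
    ``noise_model`` is None/"none" or ("lognormal", sigma).
    """
    if n_ecotypes < 2:
        raise ValueError("n_ecotypes must be >= 2")
    lo, hi = lp_cell_fraction_range
    if not (0.0 < lo <= hi < 0.1):
        raise ValueError("lp_cell_fraction_range must be within (0, 0.1)")
    for e, mapping in ecotype_state_map.items():
        for t, st in mapping.items():
            if t not in panel.cell_types:
                raise ValueError(f"ecotype {e} references unknown cell type {t!r}")
            if not 0 <= st < panel.k_states[t]:
                raise ValueError(f"ecotype {e} references unknown state {st} of {t!r}")
    sigma = 0.0
    if noise_model not in (None, "none"):
        kind, sigma = noise_model
        if kind != "lognormal":
            raise ValueError(f"unknown noise model {kind!r}")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    types = panel.cell_types
    lp_idx = types.index(panel.lp_type)
    other_idx = [i for i in range(len(types)) if i != lp_idx]

    # ecotype labels: balanced assignment, a fixed share left unassigned (-1)
    labels = np.array([(i % n_ecotypes) + 1 for i in range(n_samples)])
    rng.shuffle(labels)
    n_un = int(round(unassigned_fraction * n_samples))
    if n_un:
        un = rng.choice(n_samples, size=n_un, replace=False)
        labels[un] = -1

    cf = np.zeros((n_samples, len(types)))
    cf[:, lp_idx] = rng.uniform(lo, hi, size=n_samples)
    rest = rng.dirichlet(np.full(len(other_idx), 4.0), size=n_samples)
    cf[:, other_idx] = rest * (1.0 - cf[:, [lp_idx]])

    rna = panel.rna_content.reindex(types).to_numpy()
    ef = cf * rna[None, :]
    ef /= ef.sum(axis=1, keepdims=True)

    state_labels = np.zeros((n_samples, len(types)), dtype=int)
    for si in range(n_samples):
        for ti, t in enumerate(types):
            if labels[si] > 0 and t in ecotype_state_map[labels[si]]:
                state_labels[si, ti] = ecotype_state_map[labels[si]][t]
            else:
                state_labels[si, ti] = int(rng.integers(panel.k_states[t]))

    base = panel.base_profiles.to_numpy()
    progs = {t: panel.state_programs[t].to_numpy() for t in types}
    X = np.zeros((len(panel.gene_ids), n_samples))
    for si in range(n_samples):
        for ti, t in enumerate(types):
            X[:, si] += ef[si, ti] * base[:, ti] * progs[t][:, state_labels[si, ti]]
    if sigma > 0:
        X *= np.exp(rng.normal(0.0, sigma, size=X.shape))
    X = _normalize_tpm(X)

    expr = pd.DataFrame(X, index=panel.gene_ids, columns=sample_ids)
    inflation = float(np.mean(ef[:, lp_idx] / cf[:, lp_idx]))
    truth = SyntheticTruth(
        cell_fractions=pd.DataFrame(cf, index=sample_ids, columns=types),
        expression_fractions=pd.DataFrame(ef, index=sample_ids, columns=types),
        state_labels=pd.DataFrame(state_labels, index=sample_ids, columns=types),
        ecotype_labels=pd.Series(labels, index=sample_ids, name="ecotype"),
        inflation_factor=inflation,
        seed=seed,
        ecotype_state_map={e: dict(m) for e, m in ecotype_state_map.items()},
    )
    return expr, truth


def generate_benign_cohort(
    panel: ReferencePanel,
    n_samples: int,
    noise_model=None,
    seed: int = 0,
) -> pd.DataFrame:
    """LP-free mixtures (benign-tissue negative control, like tonsil or
    plasma-depleted whole blood): Dirichlet mixtures over the non-malignant
    types only, TPM-normalized."""
    sigma = 0.0
    if noise_model not in (None, "none"):
        kind, sigma = noise_model
        if kind != "lognormal":
            raise ValueError(f"unknown noise model {kind!r}")
    rng = np.random.default_rng(seed)
    types = [t for t in panel.cell_types if t != panel.lp_type]
    fracs = rng.dirichlet(np.full(len(types), 4.0), size=n_samples)
    base = panel.base_profiles[types].to_numpy()
    X = np.zeros((len(panel.gene_ids), n_samples))
    for si in range(n_samples):
        for ti, t in enumerate(types):
            st = int(rng.integers(panel.k_states[t]))
            X[:, si] += fracs[si, ti] * base[:, ti] * panel.state_programs[t].to_numpy()[:, st]
    if sigma > 0:
        X *= np.exp(rng.normal(0.0, sigma, size=X.shape))
    X = _normalize_tpm(X)
    return pd.DataFrame(X, index=panel.gene_ids, columns=[f"B{i + 1:03d}" for i in range(n_samples)])


def generate_celltype_gep(
    panel: ReferencePanel,
    truth: SyntheticTruth,
    cell_type: str,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """The purified genes x samples expression of one cell type under its
    planted states — the quantity the imputation stage estimates from bulk."""
    rng = np.random.default_rng(seed)
    base = panel.base_profiles[cell_type].to_numpy()
    prog = panel.state_programs[cell_type].to_numpy()
    samples = truth.state_labels.index
    G = np.empty((len(base), len(samples)))
    for si, s in enumerate(samples):
        G[:, si] = base * prog[:, truth.state_labels.loc[s, cell_type]]
    if noise_sigma > 0:
        G *= np.exp(rng.normal(0.0, noise_sigma, size=G.shape))
    return pd.DataFrame(G, index=panel.gene_ids, columns=samples)


def generate_genotype_table(
    truth: SyntheticTruth,
    n_variants_per_sample: int = 8,
    vaf_noise_sd: float = 0.0,
    compartment: str = "plasma",
    depth: int = 5000,
    n_artifacts_per_sample: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Clonal somatic variants with mean VAF = LP cell fraction / 2.

    ``vaf_noise_sd`` is relative (sd of 0.1 means 10% multiplicative noise on
    each VAF). Artifact rows (failing the read-support filter) are included so
    variant filtering is exercised.
    """
    if vaf_noise_sd < 0:
        raise ValueError("vaf_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if "LP" not in truth.cell_fractions.columns:
        raise ValueError("truth has no LP cell type")
    lp = truth.cell_fractions["LP"]
    rows = []
    for s, frac in lp.items():
        base_vaf = frac / 2.0
        for v in range(n_variants_per_sample):
            vaf = base_vaf
            if vaf_noise_sd > 0:
                vaf = base_vaf * (1.0 + rng.normal(0.0, vaf_noise_sd))
            vaf = float(np.clip(vaf, 1e-6, 1.0))
            reads = max(4, int(rng.poisson(depth * vaf)))
            rows.append((s, f"{s}_var{v + 1}", vaf, reads, True, compartment))
        for a in range(n_artifacts_per_sample):
            vaf = float(rng.uniform(0.0002, 0.0008))
            rows.append((s, f"{s}_art{a + 1}", vaf, int(rng.integers(0, 4)), False, compartment))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "variant_id", "vaf", "supporting_reads", "duplex_support", "compartment"],
    )


def generate_spatial_grid(
    panel: ReferencePanel,
    grid_shape,
    ecotype_regions: np.ndarray,
    ecotype_state_map: dict,
    spots_noise_sigma: float = 0.0,
    lp_cell_fraction_range=(0.005, 0.02),
    total_counts: int = 20000,
    poisson_counts: bool = True,
    seed: int = 0,
) -> SpotGrid:
    """A spots grid whose state composition is drawn per-region from the
    ecotype's state map, yielding positive spatial autocorrelation of the
    planted ecotype abundance by construction."""
    rows, cols = grid_shape
    regions = np.asarray(ecotype_regions)
    if regions.shape != (rows, cols):
        raise ValueError("ecotype_regions must match grid_shape")
    if np.any(regions <= 0):
        raise ValueError("every grid cell must be assigned an ecotype region")
    rng = np.random.default_rng(seed)

    spot_ids, coords, eco = [], [], []
    for r in range(rows):
        for c in range(cols):
            spot_ids.append(f"spot_{r}_{c}")
            coords.append((r, c))
            eco.append(int(regions[r, c]))
    n_spots = len(spot_ids)
    coords_df = pd.DataFrame(coords, index=spot_ids, columns=["row", "col"])

    types = panel.cell_types
    lp_idx = types.index(panel.lp_type)
    other_idx = [i for i in range(len(types)) if i != lp_idx]
    lo, hi = lp_cell_fraction_range

    cf = np.zeros((n_spots, len(types)))
    cf[:, lp_idx] = rng.uniform(lo, hi, size=n_spots)
    cf[:, other_idx] = rng.dirichlet(np.full(len(other_idx), 4.0), size=n_spots) * (
        1.0 - cf[:, [lp_idx]]
    )
    rna = panel.rna_content.reindex(types).to_numpy()
    ef = cf * rna[None, :]
    ef /= ef.sum(axis=1, keepdims=True)

    state_labels = np.zeros((n_spots, len(types)), dtype=int)
    base = panel.base_profiles.to_numpy()
    X = np.zeros((len(panel.gene_ids), n_spots))
    for si in range(n_spots):
        mapping = ecotype_state_map[eco[si]]
        for ti, t in enumerate(types):
            st = mapping.get(t)
            if st is None:
                st = int(rng.integers(panel.k_states[t]))
            state_labels[si, ti] = st
            X[:, si] += ef[si, ti] * base[:, ti] * panel.state_programs[t].to_numpy()[:, st]
    if spots_noise_sigma > 0:
        X *= np.exp(rng.normal(0.0, spots_noise_sigma, size=X.shape))
    X = X / X.sum(axis=0, keepdims=True) * total_counts
    if poisson_counts:
        X = rng.poisson(X).astype(float)

    return SpotGrid(
        spot_ids=spot_ids,
        coordinates=coords_df,
        counts=pd.DataFrame(X.T, index=spot_ids, columns=panel.gene_ids),
        truth_ecotype_per_spot=pd.Series(eco, index=spot_ids, name="ecotype"),
        truth_expression_fractions=pd.DataFrame(ef, index=spot_ids, columns=types),
        truth_state_labels=pd.DataFrame(state_labels, index=spot_ids, columns=types),
        seed=seed,
    )


def _power_law_counts(k: int, exponent: float, total_reads: int) -> np.ndarray:
    p = (np.arange(1, k + 1, dtype=float)) ** (-exponent)
    p /= p.sum()
    counts = np.floor(p * total_reads).astype(int)
    # largest-remainder top-up, then drop zeros
    deficit = total_reads - counts.sum()
    if deficit > 0:
        order = np.argsort(-(p * total_reads - counts))
        counts[order[:deficit]] += 1
    return counts[counts >= 1]


def _entropy_nats(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _counts_for_entropy(target: float, repertoire_size: int, total_reads: int) -> np.ndarray:
    """Bisection on the power-law exponent so the realized count entropy hits
    the target (monotone decreasing in the exponent)."""
    if target <= 1e-9:
        return np.array([total_reads])
    hi_entropy = _entropy_nats(_power_law_counts(repertoire_size, 0.0, total_reads))
    if target >= hi_entropy:
        return _power_law_counts(repertoire_size, 0.0, total_reads)
    lo_a, hi_a = 0.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo_a + hi_a)
        h = _entropy_nats(_power_law_counts(repertoire_size, mid, total_reads))
        if h > target:
            lo_a = mid
        else:
            hi_a = mid
    return _power_law_counts(repertoire_size, 0.5 * (lo_a + hi_a), total_reads)


def generate_clonotype_tables(
    n_samples: int,
    group_labels,
    target_entropy_per_group: dict,
    repertoire_size: int = 1000,
    chain: str = "TCR",
    reads_per_clonotype: int = 50,
    entropy_jitter_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """AIRR-style clonotype counts whose Shannon entropy (nats) hits each
    group's target via one-parameter power-law frequency tuning."""
    if len(group_labels) != n_samples:
        raise ValueError("group_labels must have one entry per sample")
    hmax = math.log(repertoire_size)
    for g, h in target_entropy_per_group.items():
        if not 0.0 <= h <= hmax + 1e-9:
            raise ValueError(f"target entropy for group {g!r} outside [0, ln K]")
    rng = np.random.default_rng(seed)
    total_reads = max(10000, reads_per_clonotype * repertoire_size)
    rows = []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        target = target_entropy_per_group[group_labels[i]]
        t = target
        if entropy_jitter_sd > 0 and target > 0:
            t = float(np.clip(target + rng.normal(0.0, entropy_jitter_sd), 0.0, hmax))
        counts = _counts_for_entropy(t, repertoire_size, total_reads)
        for j, c in enumerate(counts):
            rows.append((sid, chain, f"{chain}_clone{j + 1:05d}", int(c)))
    return pd.DataFrame(rows, columns=["sample_id", "chain", "clonotype_id", "count"])


def generate_survival(
    truth: SyntheticTruth,
    baseline_hazard: float = 0.01,
    log_hr_per_unit_ecotype3: float = 0.0,
    censor_rate: float = 0.2,
    risk_ecotype: int = 3,
    abundance_concentration: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential progression times with hazard
    baseline * exp(log_hr * abundance of the risk ecotype), independent
    exponential censoring, plus LP-IPS and management-stratum covariates.

    Ecotype abundances are Dirichlet draws concentrated on each sample's
    planted ecotype (symmetric for unassigned samples).
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = truth.ecotype_labels
    ecolist = sorted({e for e in labels if e > 0})
    if risk_ecotype not in ecolist:
        raise ValueError(f"risk_ecotype {risk_ecotype} not among planted ecotypes {ecolist}")
    n = len(labels)
    abund = np.zeros((n, len(ecolist)))
    for i, (s, e) in enumerate(labels.items()):
        alpha = np.ones(len(ecolist))
        if e > 0:
            alpha[ecolist.index(e)] = abundance_concentration
        abund[i] = rng.dirichlet(alpha)
    a3 = abund[:, ecolist.index(risk_ecotype)]
    hazard = baseline_hazard * np.exp(log_hr_per_unit_ecotype3 * a3)
    times = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    event = (times <= censor).astype(int)
    obs = np.minimum(times, censor)
    obs = np.maximum(obs, 1e-6)

    df = pd.DataFrame(
        {
            "sample_id": labels.index,
            "time_months": obs,
            "event": event,
            "lpips_score": rng.integers(0, 6, size=n),
            "management_stratum": rng.choice(["single_modality", "combined_modality"], size=n),
            "exclude_flag": False,
        }
    ).set_index("sample_id")
    for j, e in enumerate(ecolist):
        df[f"LPE{e}"] = abund[:, j]
    return df
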