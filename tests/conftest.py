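import numpy as np
import pytest

from ecostate import deconvolution as dc
from ecostate import simulate

#: cell types with >= 3 latent states in the default panel; used for state
#: and ecotype discovery (each planted ecotype pins one state per type here)
STATEFUL_TYPES = ["B", "CD4T", "CD8T", "MonoMac", "Tfh", "LP"]


@pytest.fixture(scope="session")
def panel():
    return simulate.generate_reference_panel(
        1200, simulate.default_cell_type_spec(), seed=7
    )


@pytest.fixture(scope="session")
def eco_map(panel):
    return simulate.default_ecotype_state_map(panel, 3)


@pytest.fixture(scope="session")
def noiseless_cohort(panel, eco_map):
    return simulate.generate_bulk_cohort(
        panel, 40, 3, eco_map, noise_model=None, seed=1
    )


@pytest.fixture(scope="session")
def noisy_cohort(panel, eco_map):
    return simulate.generate_bulk_cohort(
        panel, 80, 3, eco_map, noise_model=("lognormal", 0.2), seed=42
    )


@pytest.fixture(scope="session")
def signature(panel):
    return dc.build_signature_matrix(panel.base_profiles)


@pytest.fixture(scope="session")
def fitted_states(panel, eco_map, noisy_cohort):
    """Per-type cell-state models on the noisy discovery cohort."""
    from ecostate import states

    _, truth = noisy_cohort
    out = {}
    for i, ct in enumerate(STATEFUL_TYPES):
        gep = simulate.generate_celltype_gep(panel, truth, ct, noise_sigma=0.2, seed=300 + i)
        out[ct] = states.CellStateNMF(
            gep, ct, ranks=range(2, 7), n_restarts=20, n_top_genes=150, scan_max_iter=200
        ).fit(seed=i)
    return out


@pytest.fixture(scope="session")
def fitted_ecotypes(fitted_states):
    from ecostate import ecotypes

    return ecotypes.EcotypeDiscovery(fitted_states).fit()


def planted_state_of(result, truth, cell_type):
    """Map each discovered state id to its majority planted state index."""
    ab = result.state_abundance
    mapping = {}
    for s in ab.columns:
        dom = [smp for smp in ab.index if ab.loc[smp].idxmax() == s]
        if dom:
            mapping[s] = int(truth.state_labels.loc[dom, cell_type].mode().iloc[0])
    return mapping


def ecotype_correspondence(assignments, truth):
    """Discovered ecotype label -> planted ecotype id by majority vote."""
    import pandas as pd

    df = pd.DataFrame({"pred": assignments, "true": truth.ecotype_labels})
    corr = {}
    for lpe in sorted({p for p in assignments if p != "unassigned"}):
        sub = df[(df["pred"] == lpe) & (df["true"] > 0)]
        if len(sub):
            corr[lpe] = int(sub["true"].mode().iloc[0])
    return corr


def brute_force_moran(values, coords_df, weights):
    z = np.asarray(values, float) - np.mean(values)
    W = weights.toarray()
    n = len(z)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    return n / W.sum() * num / (z**2).sum()
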