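"""Readers and writers for the pipeline's tabular and Visium-dialect files.

Expression tables are genes-as-rows TSV with sample ids in the header;
spot matrices use the MatrixMarket trio (matrix.mtx, features.tsv,
barcodes.tsv) plus a tissue_positions.csv
(barcode,in_tissue,array_row,array_col,pxl_row,pxl_col).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples expression table (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression table: {path}")
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_table_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table_tsv(df: pd.DataFrame, path, index: bool = True, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_visium(grid, outdir) -> None:
    """Write a SpotGrid as matrix.mtx + features.tsv + barcodes.tsv +
    tissue_positions.csv (Visium dialect)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = sparse.csr_matrix(grid.counts.to_numpy().T)  # genes x spots
    spio.mmwrite(outdir / "matrix.mtx", counts)
    pd.DataFrame({"gene_id": grid.counts.columns, "gene_name": grid.counts.columns}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(grid.spot_ids).to_csv(outdir / "barcodes.tsv", header=False, index=False)
    pos = pd.DataFrame(
        {
            "barcode": grid.spot_ids,
            "in_tissue": 1,
            "array_row": grid.coordinates["row"].to_numpy(),
            "array_col": grid.coordinates["col"].to_numpy(),
            "pxl_row": grid.coordinates["row"].to_numpy() * 100,
            "pxl_col": grid.coordinates["col"].to_numpy() * 100,
        }
    )
    pos.to_csv(outdir / "tissue_positions.csv", index=False)


def read_visium(indir):
    """Read a Visium-dialect MTX trio; returns (counts spots x genes,
    positions DataFrame indexed by barcode with row/col columns)."""
    indir = Path(indir)
    mtx = spio.mmread(indir / "matrix.mtx").tocsr()  # genes x spots
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].tolist()
    counts = pd.DataFrame(mtx.T.toarray(), index=barcodes, columns=features[0].tolist())
    pos = pd.read_csv(indir / "tissue_positions.csv").set_index("barcode")
    pos = pos.rename(columns={"array_row": "row", "array_col": "col"})
    return counts, pos.loc[barcodes, ["row", "col"]]


# -- model bundles -----------------------------------------------------------

def save_state_model(res, outdir) -> None:
    """Persist a CellStateResults bundle (W.tsv, H.tsv, abundance.tsv,
    diagnostics.json) for later recovery runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.W.to_csv(outdir / "W.tsv", sep="\t", index_label="feature")
    res.H.to_csv(outdir / "H.tsv", sep="\t", index_label="state")
    res.state_abundance.to_csv(outdir / "abundance.tsv", sep="\t", index_label="sample_id")
    write_json(
        {
            "cell_type": res.cell_type,
            "genes_used": list(res.genes_used),
            "gene_means": [float(x) for x in res.gene_means],
            "gene_stds": [float(x) for x in res.gene_stds],
            "selected_rank": res.selected_rank,
            "cophenetic_by_rank": {
                str(k): (
                    {
                        "cophenetic": v.cophenetic,
                        "clusters_realized": v.clusters_realized,
                        "min_within_consensus": v.min_within_consensus,
                    }
                    if hasattr(v, "cophenetic")
                    else v
                )
                for k, v in res.cophenetic_by_rank.items()
            },
            "afi_by_state": res.afi_by_state,
            "dropped_states": res.dropped_states,
            "low_confidence": res.low_confidence,
            "flags": res.flags,
        },
        outdir / "diagnostics.json",
    )


def load_state_model(indir):
    import numpy as np

    from .states import CellStateResults, RankStability

    indir = Path(indir)
    meta = read_json(indir / "diagnostics.json")
    W = pd.read_csv(indir / "W.tsv", sep="\t", index_col=0)
    H = pd.read_csv(indir / "H.tsv", sep="\t", index_col=0)
    ab = pd.read_csv(indir / "abundance.tsv", sep="\t", index_col=0)
    coph = {
        int(k): (RankStability(**v) if isinstance(v, dict) else v)
        for k, v in meta["cophenetic_by_rank"].items()
    }
    return CellStateResults(
        cell_type=meta["cell_type"],
        genes_used=meta["genes_used"],
        gene_means=np.asarray(meta["gene_means"]),
        gene_stds=np.asarray(meta["gene_stds"]),
        W=W,
        H=H,
        selected_rank=int(meta["selected_rank"]),
        cophenetic_by_rank=coph,
        afi_by_state=meta["afi_by_state"],
        dropped_states=meta["dropped_states"],
        state_abundance=ab,
        low_confidence=meta["low_confidence"],
        flags=meta["flags"],
    )


def save_ecotype_model(res, outdir) -> None:
    """Persist an EcotypeResults bundle: jaccard.tsv, mapping.tsv,
    sample_assignments.tsv, network edge list, model.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.jaccard.to_csv(outdir / "jaccard.tsv", sep="\t", index_label="state")
    res.jaccard_raw.to_csv(outdir / "jaccard_raw.tsv", sep="\t", index_label="state")
    res.pvalues.to_csv(outdir / "pvalues.tsv", sep="\t", index_label="state")
    res.occurrence.to_csv(outdir / "occurrence.tsv", sep="\t", index_label="state")
    pd.DataFrame(
        {"state": list(res.state_to_ecotype), "ecotype": list(res.state_to_ecotype.values())}
    ).to_csv(outdir / "mapping.tsv", sep="\t", index=False)
    assign = res.ecotype_abundance.copy()
    assign.insert(0, "ecotype", res.assignments)
    assign["Q"] = res.qvalues
    assign.to_csv(outdir / "sample_assignments.tsv", sep="\t", index_label="sample_id")
    edges = []
    J = res.jaccard
    for i, a in enumerate(J.index):
        for b in J.columns[i + 1 :]:
            if J.loc[a, b] > 0:
                edges.append((a, b, float(J.loc[a, b])))
    pd.DataFrame(edges, columns=["state_a", "state_b", "jaccard"]).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    write_json({"n_ecotypes": res.n_ecotypes, "q_max": res.q_max}, outdir / "model.json")


def load_ecotype_model(indir):
    from .ecotypes import EcotypeResults

    indir = Path(indir)
    meta = read_json(indir / "model.json")
    mapping_df = pd.read_csv(indir / "mapping.tsv", sep="\t")
    assign = pd.read_csv(indir / "sample_assignments.tsv", sep="\t", index_col=0)
    return EcotypeResults(
        state_to_ecotype=dict(zip(mapping_df["state"], mapping_df["ecotype"].astype(int))),
        n_ecotypes=int(meta["n_ecotypes"]),
        jaccard=pd.read_csv(indir / "jaccard.tsv", sep="\t", index_col=0),
        jaccard_raw=pd.read_csv(indir / "jaccard_raw.tsv", sep="\t", index_col=0),
        pvalues=pd.read_csv(indir / "pvalues.tsv", sep="\t", index_col=0),
        occurrence=pd.read_csv(indir / "occurrence.tsv", sep="\t", index_col=0),
        ecotype_abundance=assign.drop(columns=["ecotype", "Q"]),
        assignments=assign["ecotype"],
        qvalues=assign["Q"],
        q_max=float(meta["q_max"]),
    )
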