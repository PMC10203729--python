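"""Normalise the simulated counts, select variable genes and embed by PCA.

Reads the output of 01_simulate_timecourse.py, runs the standard
counts -> logCP10k -> HVG -> PCA path and writes the PCA embedding plus the
per-component explained variance under results/preprocess/.
"""

import os

import pandas as pd

from germmap.io import read_counts_mtx, read_metadata, write_embedding, write_table
from germmap.preprocess import normalize_logcp10k, pca_embed, select_hvg

SIM = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "preprocess")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cells = read_counts_mtx(
        os.path.join(SIM, "matrix.mtx"),
        os.path.join(SIM, "genes.tsv"),
        os.path.join(SIM, "barcodes.tsv"),
    )
    cells = read_metadata(os.path.join(SIM, "metadata.tsv"), cells)

    norm = normalize_logcp10k(cells)
    n_hvg = min(150, cells.n_genes)
    hvg = select_hvg(norm, n_hvg)
    emb = pca_embed(norm, hvg, n_pcs=50)
    write_embedding(emb, os.path.join(OUT, "pca50.csv"))
    evr = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(50)],
            "explained_variance_ratio": emb.explained_variance_ratio_,
        }
    )
    write_table(evr, os.path.join(OUT, "explained_variance.tsv"))

    top5 = 100 * emb.explained_variance_ratio_[:5].sum()
    print(
        f"normalised {cells.n_cells} cells, selected {n_hvg} variable genes, "
        f"embedded into 50 PCs; the first 5 PCs explain {top5:.1f}% of variance"
    )
    print(f"wrote embedding and variance table to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
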