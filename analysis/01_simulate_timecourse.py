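"""Generate the synthetic differentiation time course used by every
downstream analysis step and write it to disk in exchange formats.

Writes under results/sim/: the MTX count triplet, per-cell metadata TSV,
the ground-truth 10-D embedding CSV, and the planted lineage tree as JSON.
"""

import json
import os

from germmap.io import write_counts_mtx, write_embedding, write_table
from germmap.synth import SynthParams, simulate_timecourse

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sim")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    params = SynthParams(seed=7)
    cells, embedding, tree = simulate_timecourse(params)

    write_counts_mtx(
        cells,
        os.path.join(OUT, "matrix.mtx"),
        os.path.join(OUT, "genes.tsv"),
        os.path.join(OUT, "barcodes.tsv"),
    )
    meta = cells.meta.reset_index()
    write_table(meta, os.path.join(OUT, "metadata.tsv"))
    write_embedding(embedding, os.path.join(OUT, "embedding.csv"))
    truth = {
        "timepoints_h": list(params.timepoints_h),
        "terminal_lineages": list(tree.terminal_lineages),
        "branch_times": tree.branch_times,
        "edges": [[list(src), list(dst)] for src, dst in tree.edges],
        "marker_genes": {
            lin: [f"gene{g:04d}" for g in genes]
            for lin, genes in tree.marker_genes.items()
        },
    }
    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)

    n_nodes = len(tree.nodes)
    print(
        f"simulated {cells.n_cells} cells x {cells.n_genes} genes over "
        f"{len(params.timepoints_h)} timepoints ({n_nodes} cluster:timepoint "
        f"nodes, {len(tree.edges)} planted edges); "
        f"terminal lineages: {', '.join(tree.terminal_lineages)}"
    )
    print(f"wrote MTX triplet, metadata, embedding and truth to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
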