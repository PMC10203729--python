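"""Reference-to-query label transfer by hypergeometric KNN enrichment.

Each query cell's k nearest reference cells (Euclidean, shared embedding)
are tested for enrichment of every reference annotation: with x neighbours
carrying a label of overall size K in a reference of N cells, the upper-tail
probability P(X >= x), X ~ Hypergeometric(N, K, k), measures how unlikely
the observed proximity is under random mixing.  Per cell, the p-values over
candidate labels are Benjamini-Hochberg adjusted; the label with the lowest
adjusted p below alpha is assigned, and cells with no significant label stay
UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import Embedding, UNASSIGNED


@dataclass
class EnrichmentResult:
    """Per-cell enrichment table over candidate labels."""

    cell_id: str
    labels: list[str]
    x: np.ndarray          # observed neighbour count per label
    K_label: np.ndarray    # label size in the reference
    N: int                 # reference size
    k: int                 # neighbours drawn
    p: np.ndarray          # hypergeometric upper-tail probabilities
    p_adj: np.ndarray = field(default_factory=lambda: np.zeros(0))
    assigned_label: str = UNASSIGNED


def knn_query_to_reference(query: Embedding, reference: Embedding, k: int) -> np.ndarray:
    """Indices of each query cell's k nearest reference cells.

    Exact brute-force search with stable sort, so distance ties break to the
    lowest reference index.
    """
    if query.dim != reference.dim:
        raise ValueError(
            f"dimension mismatch: query d={query.dim}, reference d={reference.dim}"
        )
    if query.space_tag != reference.space_tag:
        raise ValueError(
            f"embedding spaces differ: {query.space_tag!r} vs {reference.space_tag!r}"
        )
    if k > reference.n_cells:
        raise ValueError(f"k={k} exceeds reference size {reference.n_cells}")
    d = cdist(query.coords, reference.coords)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def hypergeom_enrichment(
    neighbor_labels: list[str],
    label_counts: dict[str, int],
    N: int,
    cell_id: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of each label among neighbours.

    p = P(X >= x) with X ~ Hypergeometric(N, K_label, k); labels with x = 0
    get p = 1 exactly (P(X >= 0) = 1).
    """
    if sum(label_counts.values()) != N:
        raise ValueError("label counts do not sum to reference size N")
    k = len(neighbor_labels)
    if k > N:
        raise ValueError("more neighbours than reference cells")
    unknown = set(neighbor_labels) - set(label_counts)
    if unknown:
        raise ValueError(f"neighbour labels absent from reference: {sorted(unknown)}")
    labels = sorted(label_counts)
    K = np.array([label_counts[l] for l in labels])
    x = np.array([sum(nl == l for nl in neighbor_labels) for l in labels])
    # sf(x-1) = P(X >= x); exact 1.0 at x = 0
    p = np.where(x == 0, 1.0, hypergeom.sf(x - 1, N, K, k))
    p = np.clip(p, 0.0, 1.0)
    return EnrichmentResult(cell_id=cell_id, labels=labels, x=x, K_label=K, N=N, k=k, p=p)


def assign_labels(results: list[EnrichmentResult], alpha: float = 0.05) -> list[EnrichmentResult]:
    """BH-adjust per cell across its candidate labels and assign the winner.

    The assigned label minimises the adjusted p among labels with
    p_adj < alpha; exact ties break to the smaller raw p, then
    lexicographically.  No significant label leaves the cell UNASSIGNED.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for res in results:
        res.p_adj = multipletests(res.p, method="fdr_bh")[1]
        sig = np.flatnonzero(res.p_adj < alpha)
        if sig.size == 0:
            res.assigned_label = UNASSIGNED
            continue
        # order: p_adj, then raw p, then label
        key = sorted(sig, key=lambda i: (res.p_adj[i], res.p[i], res.labels[i]))
        res.assigned_label = res.labels[key[0]]
    return results


def transfer_labels(
    query: Embedding,
    reference: Embedding,
    reference_labels: list[str],
    k: int = 20,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Full KNN -> enrichment -> assignment pipeline for a query set."""
    if len(reference_labels) != reference.n_cells:
        raise ValueError("reference labels length does not match reference size")
    nn = knn_query_to_reference(query, reference, k)
    labels_arr = np.asarray(reference_labels, dtype=object)
    counts = pd.Series(reference_labels).value_counts().to_dict()
    N = reference.n_cells
    results = [
        hypergeom_enrichment(
            list(labels_arr[nn[j]]), counts, N, cell_id=query.cell_ids[j]
        )
        for j in range(query.n_cells)
    ]
    return assign_labels(results, alpha=alpha)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Wide assignment table: cell_id, assigned_label, best p/p_adj, per-label p_adj."""
    rows = []
    for r in results:
        row = {"cell_id": r.cell_id, "assigned_label": r.assigned_label}
        if r.assigned_label != UNASSIGNED:
            i = r.labels.index(r.assigned_label)
            row["best_p"] = r.p[i]
            row["best_p_adj"] = r.p_adj[i]
        else:
            row["best_p"] = np.nan
            row["best_p_adj"] = np.nan
        for l, padj in zip(r.labels, r.p_adj):
            row[f"p_adj_{l}"] = padj
        rows.append(row)
    return pd.DataFrame(rows)
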