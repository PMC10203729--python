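"""Normalisation, highly-variable-gene selection and PCA embedding.

Counts are normalised to log counts-per-10,000 (natural log of 1 + counts
scaled so each cell totals 10,000), the convention the single-cell ecosystem
calls logCP10k.  Variable genes are ranked by a binned dispersion statistic
(variance of the normalised values z-scored against genes of similar mean)
and the selected columns are centered, unit-variance scaled and embedded by
PCA with a fixed sign convention so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import CellSet, Embedding

DEFAULT_SCALE_TOTAL = 10_000.0
#: PCs used for optimal-transport couplings (deep embedding).
N_PCS_OT = 50
#: PCs used for neighbor graphs and label transfer.
N_PCS_NEIGHBORS = 20


@dataclass
class NormalizedMatrix:
    """logCP10k-normalised expression, cells x genes.

    ``values[c, g] = ln(1 + scale_total * counts[c, g] / total[c])``.
    Cells with zero total counts become all-zero rows and are flagged in
    ``zero_total_cells``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    scale_total: float = DEFAULT_SCALE_TOTAL
    zero_total_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def normalize_logcp10k(cells: CellSet, scale_total: float = DEFAULT_SCALE_TOTAL) -> NormalizedMatrix:
    """Normalise counts to natural-log counts per `scale_total` (logCP10k)."""
    counts = cells.counts_dense().astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    safe_totals = np.where(totals == 0, 1.0, totals)
    values = np.log1p(scale_total * counts / safe_totals[:, None])
    values[zero] = 0.0
    return NormalizedMatrix(
        values=values,
        cell_ids=list(cells.cell_ids),
        gene_ids=list(cells.gene_ids),
        scale_total=scale_total,
        zero_total_cells=zero,
    )


def select_hvg(norm: NormalizedMatrix, n_features: int, n_bins: int = 20) -> np.ndarray:
    """Rank genes by binned dispersion of normalised values; return top indices.

    Genes are binned (up to `n_bins` quantile bins) by mean normalised
    expression; within each bin the gene variances are z-scored, so a gene is
    "variable" relative to genes of comparable abundance.  Deterministic:
    ties broken by gene index.
    """
    values = norm.values
    n_genes = values.shape[1]
    if n_features > n_genes:
        raise ValueError(f"n_features={n_features} exceeds gene count {n_genes}")
    means = values.mean(axis=0)
    variances = values.var(axis=0)

    order = np.argsort(means, kind="stable")
    # keep >= 5 genes per bin so the within-bin z-score is meaningful
    n_bins = max(1, min(n_bins, n_genes // 5))
    bin_of = np.empty(n_genes, dtype=int)
    # quantile bins on the mean, nearly equal occupancy
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bin_of[idx] = b

    z = np.zeros(n_genes)
    for b in range(n_bins):
        members = bin_of == b
        v = variances[members]
        mu, sd = v.mean(), v.std()
        z[members] = (v - mu) / sd if sd > 0 else 0.0

    # highest dispersion first; stable index tie-break
    ranked = np.lexsort((np.arange(n_genes), -z))
    return np.sort(ranked[:n_features])


def _scale_columns(x: np.ndarray, unit_variance: bool = True) -> np.ndarray:
    x = x - x.mean(axis=0)
    if unit_variance:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0  # constant genes stay zero after centering
        x = x / sd
    return x


def pca_embed(
    norm: NormalizedMatrix,
    genes: np.ndarray | list[int] | None = None,
    n_pcs: int = N_PCS_OT,
    scale: bool = True,
    space_tag: str | None = None,
    seed: int = 0,
) -> Embedding:
    """PCA embedding of the (centered, scaled) selected gene columns.

    Components are ordered by decreasing explained variance and the sign of
    each is fixed so the largest-magnitude gene loading is positive.
    """
    values = norm.values if genes is None else norm.values[:, np.asarray(genes)]
    n_cells, n_genes = values.shape
    if n_pcs > min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells, genes) = {min(n_cells, n_genes)}"
        )
    x = _scale_columns(values.astype(float), unit_variance=scale)
    solver = "full" if max(n_cells, n_genes) <= 2000 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| positive per component
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    tag = space_tag or f"pca{n_pcs}"
    emb = Embedding(coords=scores, cell_ids=list(norm.cell_ids), space_tag=tag)
    emb.explained_variance_ratio_ = pca.explained_variance_ratio_  # type: ignore[attr-defined]
    return emb


def preprocess_to_embedding(
    cells: CellSet, n_hvg: int = 5000, n_pcs: int = N_PCS_OT, seed: int = 0
) -> Embedding:
    """counts -> logCP10k -> HVG -> PCA, the standard end-to-end path."""
    norm = normalize_logcp10k(cells)
    n_hvg = min(n_hvg, len(norm.gene_ids))
    hvg = select_hvg(norm, n_hvg)
    n_pcs = min(n_pcs, cells.n_cells - 1, n_hvg)
    return pca_embed(norm, hvg, n_pcs=n_pcs, seed=seed)
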