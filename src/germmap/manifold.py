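"""Diffusion maps and diffusion pseudotime for ordering differentiation.

The kernel is Gaussian with per-cell adaptive bandwidth (distance to the
ceil(n_neighbors/2)-th neighbour), restricted to the symmetrised KNN support
so the geometry is local.  Spectral decomposition of the symmetrically
normalised kernel yields diffusion components (eigenvectors of the
row-stochastic transition matrix, scaled by their eigenvalues); pseudotime
is the diffusion distance to a chosen root cell, accumulated over the
spectral representation with weights lambda/(1 - lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .io import CellSet, Embedding
from .preprocess import normalize_logcp10k


@dataclass
class DiffusionResult:
    """Diffusion components, spectrum and (optionally) pseudotime."""

    dcs: np.ndarray                  # cells x n_comps, DC_l = lambda_l * psi_l
    eigenvalues: np.ndarray          # decreasing, in (0, 1]
    cell_ids: list[str]
    psi: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    stationary: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    pseudotime: np.ndarray | None = None
    root: str | None = None


def _adaptive_kernel(coords: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Locally scaled Gaussian kernel on the symmetrised KNN support."""
    n = coords.shape[0]
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    k_sigma = ceil(n_neighbors / 2)
    sigma = d[np.arange(n), order[:, k_sigma - 1]]
    sigma = np.maximum(sigma, 1e-12)  # duplicate points give zero distances

    # tie-inclusive KNN support (everything at or below the k-th neighbour
    # distance), so duplicated cells receive identical kernel rows
    kth = d[np.arange(n), order[:, n_neighbors - 1]]
    support = d <= kth[:, None]
    support |= support.T

    np.fill_diagonal(d, 0.0)
    K = np.exp(-(d**2) / (2.0 * np.outer(sigma, sigma)))
    K[~support] = 0.0
    np.fill_diagonal(K, 1.0)
    return K


def diffusion_map(embedding: Embedding, n_comps: int = 3, n_neighbors: int = 15) -> DiffusionResult:
    """Diffusion-map embedding of the cells.

    Raises if the KNN graph is disconnected (diffusion distances are then
    undefined across components), naming the component sizes.
    """
    n = embedding.n_cells
    if n_comps >= n:
        raise ValueError(f"n_comps={n_comps} must be < cell count {n}")
    K = _adaptive_kernel(embedding.coords, n_neighbors)

    n_comp_graph, labels = connected_components(sp.csr_matrix(K > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"KNN graph has {n_comp_graph} disconnected components "
            f"(sizes {sizes.tolist()}); increase n_neighbors"
        )

    deg = K.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    M = K * np.outer(inv_sqrt, inv_sqrt)  # symmetric normalisation

    if n <= 1000:
        evals, evecs = np.linalg.eigh(M)
        evals, evecs = evals[::-1], evecs[:, ::-1]
    else:
        evals, evecs = sp.linalg.eigsh(sp.csr_matrix(M), k=n_comps + 1, which="LA")
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]

    # right eigenvectors of the row-stochastic P = D^-1 K; psi_0 is constant
    psi = evecs * inv_sqrt[:, None]
    # normalise against the stationary distribution pi = deg / sum(deg)
    pi = deg / deg.sum()
    psi /= np.sqrt((psi**2 * pi[:, None]).sum(axis=0))
    # fixed sign: largest-|entry| positive
    for l in range(psi.shape[1]):
        if psi[np.argmax(np.abs(psi[:, l])), l] < 0:
            psi[:, l] *= -1.0

    lam = evals[1 : n_comps + 1]
    dcs = psi[:, 1 : n_comps + 1] * lam[None, :]
    return DiffusionResult(
        dcs=dcs,
        eigenvalues=lam,
        cell_ids=list(embedding.cell_ids),
        psi=psi[:, 1 : n_comps + 1],
        stationary=pi,
    )


def diffusion_pseudotime(result: DiffusionResult, root: str) -> DiffusionResult:
    """Fill pseudotime = diffusion distance from the root cell.

    dpt(root, c)^2 = sum_l (lambda_l / (1 - lambda_l))^2 (psi_l(root) - psi_l(c))^2
    accumulated over the computed non-trivial components.
    """
    if root not in result.cell_ids:
        raise KeyError(f"unknown root cell id: {root!r}")
    r = result.cell_ids.index(root)
    lam = result.eigenvalues
    w = np.where(lam < 1.0, lam / (1.0 - lam), 0.0)
    diff = result.psi - result.psi[r]
    result.pseudotime = np.sqrt(np.sum((w[None, :] * diff) ** 2, axis=1))
    result.root = root
    return result


def root_from_time(cells: CellSet) -> str:
    """Default root: the cell with minimal time_h metadata."""
    if "time_h" not in cells.meta.columns:
        raise ValueError("no time_h metadata to pick a root from")
    return cells.meta["time_h"].idxmin()


def order_genes_by_pseudotime(
    cells: CellSet,
    result: DiffusionResult,
    genes: list[str],
    window_frac: float = 0.1,
) -> pd.DataFrame:
    """Cells sorted by pseudotime with rolling-mean-smoothed expression.

    Expression is logCP10k; the rolling window is a centered window of
    max(1, round(window_frac * n)) cells with partial windows at the edges.
    """
    if result.pseudotime is None:
        raise ValueError("pseudotime not computed")
    missing = [g for g in genes if g not in cells.gene_ids]
    if missing:
        raise KeyError(f"genes not found: {missing}")
    norm = normalize_logcp10k(cells)
    gidx = [cells.gene_ids.index(g) for g in genes]
    order = np.argsort(result.pseudotime, kind="stable")
    values = norm.values[np.ix_(order, gidx)]
    n = len(order)
    window = max(1, round(window_frac * n))
    df = pd.DataFrame(values, columns=genes)
    smoothed = df.rolling(window=window, center=True, min_periods=1).mean()
    smoothed.insert(0, "pseudotime", result.pseudotime[order])
    smoothed.insert(0, "cell_id", [result.cell_ids[i] for i in order])
    return smoothed
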