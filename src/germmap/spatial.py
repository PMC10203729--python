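"""Projection of dissociated cells onto a 3D spatially resolved reference.

A query cell j is placed in the reference's physical space by averaging the
3D positions r_i of its K nearest reference cells (in the shared expression
embedding) with shared-nearest-neighbour weights:

    theta_i = Jaccard overlap of the k_graph-NN sets of j and reference cell i
    theta_hat = theta / c,  c = sum_i theta_i
    R = sum_i r_i * theta_hat_i

so R always lies in the convex hull of the neighbours' positions.  Groups of
projected cells (e.g. all PGC-like cells) are summarised as a Gaussian-kernel
density over a 3D grid.

The SNN weight is defined as the Jaccard index of k-nearest-neighbour sets
computed in the pooled (query + reference) embedding — the convention of SNN
graphs in the single-cell ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import Embedding


@dataclass
class SpatialReference:
    """Reference cells with 3D positions, lineage labels and an embedding."""

    positions: np.ndarray
    labels: list[str]
    embedding: Embedding

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (cells, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("labels length does not match positions")
        if self.embedding.n_cells != self.positions.shape[0]:
            raise ValueError("embedding rows do not match positions")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]


@dataclass
class SNNWeights:
    query_cell: str
    neighbor_indices: np.ndarray
    theta: np.ndarray
    theta_hat: np.ndarray
    c: float
    zero_overlap: bool = False


@dataclass
class ProjectedPosition:
    query_cell: str
    R: np.ndarray


def _knn_sets(coords: np.ndarray, k: int) -> list[set[int]]:
    """k-NN index sets (self excluded) for every row; lowest-index tie-break."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return [set(order[i, :k].tolist()) for i in range(coords.shape[0])]


def snn_weights_all(
    query: Embedding,
    reference: SpatialReference,
    K: int = 10,
    k_graph: int = 20,
) -> list[SNNWeights]:
    """SNN weight vectors for every query cell (vectorised over the set)."""
    ref_emb = reference.embedding
    if query.dim != ref_emb.dim:
        raise ValueError("query and reference embeddings differ in dimension")
    n_q, n_r = query.n_cells, ref_emb.n_cells
    if K > n_r:
        raise ValueError(f"K={K} exceeds reference size {n_r}")
    if k_graph >= n_q + n_r:
        raise ValueError("k_graph exceeds available cells")

    pooled = np.vstack([query.coords, ref_emb.coords])  # queries first
    nn_sets = _knn_sets(pooled, k_graph)

    d_qr = cdist(query.coords, ref_emb.coords)
    knn_ref = np.argsort(d_qr, axis=1, kind="stable")[:, :K]

    out = []
    for j in range(n_q):
        set_j = nn_sets[j]
        theta = np.empty(K)
        for a, ri in enumerate(knn_ref[j]):
            set_i = nn_sets[n_q + ri]
            inter = len(set_j & set_i)
            union = len(set_j | set_i)
            theta[a] = inter / union if union else 0.0
        c = float(theta.sum())
        if c > 0:
            theta_hat = theta / c
            zero = False
        else:
            theta_hat = np.full(K, 1.0 / K)
            zero = True
        out.append(
            SNNWeights(
                query_cell=query.cell_ids[j],
                neighbor_indices=knn_ref[j].copy(),
                theta=theta,
                theta_hat=theta_hat,
                c=c,
                zero_overlap=zero,
            )
        )
    return out


def snn_weights(
    query: Embedding,
    reference: SpatialReference,
    j: int,
    K: int = 10,
    k_graph: int = 20,
) -> SNNWeights:
    """SNN weight vector theta for one query cell (index j)."""
    return snn_weights_all(query, reference, K=K, k_graph=k_graph)[j]


def project_position(w: SNNWeights, reference: SpatialReference) -> ProjectedPosition:
    """R = sum_i r_i * theta_hat_i — convex combination of neighbour positions."""
    R = reference.positions[w.neighbor_indices].T @ w.theta_hat
    return ProjectedPosition(query_cell=w.query_cell, R=R)


def project_all(
    query: Embedding, reference: SpatialReference, K: int = 10, k_graph: int = 20
) -> list[ProjectedPosition]:
    return [
        project_position(w, reference)
        for w in snn_weights_all(query, reference, K=K, k_graph=k_graph)
    ]


@dataclass
class GridSpec:
    """Regular 3D evaluation grid: per-axis (lo, hi, n)."""

    x: tuple[float, float, int]
    y: tuple[float, float, int]
    z: tuple[float, float, int]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.linspace(lo, hi, n) for lo, hi, n in (self.x, self.y, self.z))

    def nodes(self) -> np.ndarray:
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def cell_volume(self) -> float:
        steps = []
        for lo, hi, n in (self.x, self.y, self.z):
            steps.append((hi - lo) / (n - 1) if n > 1 else 1.0)
        return float(np.prod(steps))


def silverman_bandwidths(points: np.ndarray) -> np.ndarray:
    """Per-axis Silverman bandwidths h_d = sigma_d * (4 / ((D+2) n))^(1/(D+4))."""
    n, d = points.shape
    sigma = points.std(axis=0, ddof=1)
    sigma = np.where(sigma > 0, sigma, 1e-6)
    factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    return sigma * factor


def group_density(
    projections: list[ProjectedPosition],
    group: set[str] | list[str],
    grid: GridSpec,
    bandwidths: np.ndarray | None = None,
) -> np.ndarray:
    """Diagonal-bandwidth Gaussian KDE of a group's projected positions.

    Returns density values at the grid nodes (shape nx*ny*nz, C order).
    Bandwidths default to Silverman's rule per axis.
    """
    group = set(group)
    pts = np.array([p.R for p in projections if p.query_cell in group])
    if pts.shape[0] == 0:
        raise ValueError("empty group")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 group members for a density")
    h = silverman_bandwidths(pts) if bandwidths is None else np.asarray(bandwidths, float)
    nodes = grid.nodes()
    # sum of separable Gaussian kernels, normalised per kernel
    norm = (2 * np.pi) ** 1.5 * np.prod(h)
    diff = nodes[:, None, :] - pts[None, :, :]  # (G, n, 3)
    expo = -0.5 * np.sum((diff / h) ** 2, axis=2)
    dens = np.exp(expo).sum(axis=1) / (pts.shape[0] * norm)
    return dens


def density_mode(density: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Grid node with maximal density."""
    return grid.nodes()[int(np.argmax(density))]
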