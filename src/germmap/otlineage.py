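"""Optimal-transport lineage reconstruction across a differentiation time course.

Couplings between consecutive timepoints are computed by unbalanced entropic
optimal transport: gamma minimises

    <C, gamma> - eps * H(gamma) + lambda1 * KL(gamma 1 || a) + lambda2 * KL(gamma^T 1 || b)

with squared-Euclidean cost C in the shared embedding (median-normalised so
eps is scale-free), uniform marginals a, b (unit growth), and the defaults
lambda1 = 1, lambda2 = 50, eps = 0.01.  The solver is a stabilised Sinkhorn:
diagonal scalings in the exponential domain with periodic absorption of the
scalings into log-domain potentials, which survives eps = 0.01 without
underflow.  The KL relaxation turns each half-update into a contraction with
factor lambda/(lambda + eps), so the alternating iteration converges
geometrically.

Couplings are aggregated into a (cluster, timepoint) x (cluster, timepoint)
contribution matrix (by default each child cluster's incoming-mass shares;
source-side row fractions are also available), sharpened by an elementwise
power threshold (P = 30, entries <= 0.1 censored to 0),
turned into a directed KNN graph (k = 5) and partitioned into meta-clusters
with the Walktrap random-walk community algorithm; meta-clusters are
annotated by marker-gene expression and the annotations mapped back to
single cells through their cluster identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import CellSet, Embedding
from .preprocess import normalize_logcp10k

# ---------------------------------------------------------------------------
# timepoint conventions


def assign_times(cells: CellSet, mode: str = "offset") -> tuple[np.ndarray, np.ndarray]:
    """Per-cell pipeline times and the sorted unique timepoint sequence.

    mode="offset": pluripotent stem cell samples (sample == "PSC") sit at 0 h,
    pre-mesendoderm ("PreME") at 12 h, and every embryoid-body collection at
    12 h + its collection time, so an EB sample collected at 12 h maps to 24.
    mode="absolute": time_h is used as-is.
    """
    meta = cells.meta
    if mode == "absolute":
        if "time_h" not in meta.columns or meta["time_h"].isna().any():
            raise ValueError("cells with no resolvable time_h")
        times = meta["time_h"].to_numpy(dtype=float)
    elif mode == "offset":
        if "sample" not in meta.columns:
            raise ValueError("offset-mode time assignment needs a sample column")
        sample = meta["sample"].astype(str).str.upper()
        times = np.empty(len(meta), dtype=float)
        is_psc = sample == "PSC"
        is_preme = sample == "PREME"
        is_eb = ~(is_psc | is_preme)
        times[is_psc] = 0.0
        times[is_preme] = 12.0
        if is_eb.any():
            t = pd.to_numeric(meta.loc[is_eb, "time_h"], errors="coerce")
            if t.isna().any():
                raise ValueError("embryoid-body cells with no resolvable time_h")
            times[is_eb.to_numpy()] = 12.0 + t.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    unique = np.unique(times)
    if unique.size < 1:
        raise ValueError("no timepoints")
    return times, unique


# ---------------------------------------------------------------------------
# unbalanced entropic transport


@dataclass
class OTParams:
    """Solver parameters; the defaults are lambda1=1, lambda2=50, eps=0.01."""

    lambda1: float = 1.0
    lambda2: float = 50.0
    epsilon: float = 0.01
    max_iter: int = 5000
    tol: float = 1e-8
    cost_normalisation: str = "median"  # or "none"
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0 or self.epsilon <= 0:
            raise ValueError("lambda1, lambda2 and epsilon must be > 0")
        if self.cost_normalisation not in ("median", "none"):
            raise ValueError("cost_normalisation must be 'median' or 'none'")


@dataclass
class TransportMap:
    """Coupling between cells of two timepoints with solver diagnostics."""

    gamma: np.ndarray
    source_marginal: np.ndarray   # prescribed a
    target_marginal: np.ndarray   # prescribed b
    converged: bool
    marginal_violation: float
    n_iter: int


def _cost_matrix(source: np.ndarray, target: np.ndarray, normalisation: str) -> np.ndarray:
    C = cdist(source, target, metric="sqeuclidean")
    if normalisation == "median":
        med = np.median(C)
        if med > 0:
            C = C / med
    return C


def _sinkhorn_stabilized(
    C: np.ndarray, a: np.ndarray, b: np.ndarray, params: OTParams
) -> tuple[np.ndarray, bool, float, int]:
    """Exp-domain scaling iterations with log-domain absorption.

    Returns (gamma, converged, marginal_violation, iterations).  In balanced
    mode convergence is declared on the L-inf marginal violation; in
    unbalanced mode on the sup-norm change of the potentials.
    """
    eps = params.epsilon
    phi1 = 1.0 if params.balanced else params.lambda1 / (params.lambda1 + eps)
    phi2 = 1.0 if params.balanced else params.lambda2 / (params.lambda2 + eps)
    n, m = C.shape
    f = np.zeros(n)
    g = np.zeros(m)
    u = np.ones(n)
    v = np.ones(m)
    Kt = np.exp(-C / eps)
    tiny = 1e-300
    converged = False
    it = 0
    absorb_every = 50

    def absorb():
        nonlocal f, g, u, v, Kt
        f = f + eps * np.log(np.maximum(u, tiny))
        g = g + eps * np.log(np.maximum(v, tiny))
        Kt = np.exp((f[:, None] + g[None, :] - C) / eps)
        u = np.ones(n)
        v = np.ones(m)

    for it in range(1, params.max_iter + 1):
        u_prev, v_prev = u, v
        Kv = Kt @ v
        Kv = np.maximum(Kv, tiny)
        if params.balanced:
            u = a / Kv
        else:
            # full update of the f-potential in scaling form: the absorbed
            # part of f relaxes by (phi1 - 1)/eps as well
            u = (a / Kv) ** phi1 * np.exp((phi1 - 1.0) * f / eps)
        Ku = Kt.T @ u
        Ku = np.maximum(Ku, tiny)
        if params.balanced:
            v = b / Ku
        else:
            v = (b / Ku) ** phi2 * np.exp((phi2 - 1.0) * g / eps)

        if it % 10 == 0 or it == params.max_iter:
            if params.balanced:
                # column scaling is exact after the v-update; measure rows
                row = u * (Kt @ v)
                viol = np.max(np.abs(row - a))
                if viol < params.tol:
                    converged = True
                    break
            else:
                du = eps * np.max(np.abs(np.log(np.maximum(u, tiny)) - np.log(np.maximum(u_prev, tiny))))
                dv = eps * np.max(np.abs(np.log(np.maximum(v, tiny)) - np.log(np.maximum(v_prev, tiny))))
                if max(du, dv) < params.tol:
                    converged = True
                    break
        if it % absorb_every == 0:
            with np.errstate(divide="ignore"):
                lu = np.max(np.abs(np.log(np.maximum(u, tiny))))
                lv = np.max(np.abs(np.log(np.maximum(v, tiny))))
            if max(lu, lv) > 250.0:  # refresh before exp over/underflow
                absorb()

    gamma = (u[:, None] * Kt) * v[None, :]
    row_viol = np.max(np.abs(gamma.sum(axis=1) - a))
    col_viol = np.max(np.abs(gamma.sum(axis=0) - b))
    return gamma, converged, max(row_viol, col_viol), it


def compute_transport_map(
    source: Embedding | np.ndarray,
    target: Embedding | np.ndarray,
    params: OTParams | None = None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> TransportMap:
    """Unbalanced entropic coupling between two sets of cells.

    Marginals default to uniform (unit growth); per-cell growth weights can
    be supplied through `a`.
    """
    params = params or OTParams()
    src = source.coords if isinstance(source, Embedding) else np.asarray(source, float)
    tgt = target.coords if isinstance(target, Embedding) else np.asarray(target, float)
    if src.shape[0] == 0 or tgt.shape[0] == 0:
        raise ValueError("source and target must be nonempty")
    if src.shape[1] != tgt.shape[1]:
        raise ValueError("source and target embeddings differ in dimension")
    n, m = src.shape[0], tgt.shape[0]
    a = np.full(n, 1.0 / n) if a is None else np.asarray(a, float)
    b = np.full(m, 1.0 / m) if b is None else np.asarray(b, float)
    C = _cost_matrix(src, tgt, params.cost_normalisation)
    gamma, converged, viol, it = _sinkhorn_stabilized(C, a, b, params)
    return TransportMap(
        gamma=gamma,
        source_marginal=a,
        target_marginal=b,
        converged=converged,
        marginal_violation=viol,
        n_iter=it,
    )


def transport_chain(
    embedding: Embedding,
    times: np.ndarray,
    params: OTParams | None = None,
    growth_iters: int = 3,
) -> tuple[list[TransportMap], np.ndarray, list[np.ndarray]]:
    """Couplings between all consecutive timepoints.

    Per pair, the coupling is solved `growth_iters` times, feeding the
    fitted source marginal (gamma 1, renormalised) back in as the growth-
    weighted input marginal: the KL source relaxation (lambda1) estimates
    how much mass each cell should emit, and the self-consistent fixed
    point supplies proliferating progenitors with the mass their
    descendants demand instead of borrowing it from unrelated clusters.
    `growth_iters=1` is plain unit growth.

    Returns (maps, unique timepoints, per-timepoint cell-index arrays).
    """
    params = params or OTParams()
    if growth_iters < 1:
        raise ValueError("growth_iters must be >= 1")
    times = np.asarray(times, float)
    unique = np.unique(times)
    idx = [np.flatnonzero(times == t) for t in unique]
    maps = []
    for i in range(len(unique) - 1):
        src, tgt = embedding.coords[idx[i]], embedding.coords[idx[i + 1]]
        a = None
        for _ in range(growth_iters):
            tm = compute_transport_map(src, tgt, params, a=a)
            fitted = tm.gamma.sum(axis=1)
            total = fitted.sum()
            if total <= 0:
                break
            a = fitted / total
        maps.append(tm)
    return maps, unique, idx


def ancestor_contributions(
    maps: list[TransportMap], target_set: np.ndarray
) -> list[np.ndarray]:
    """Pull a target indicator back through a chain of consecutive couplings.

    `maps` covers t_0 -> t_1 -> ... -> t_J and `target_set` is an indicator
    (or weight) vector over the cells at t_J.  Returns the ancestor mass
    vector at each earlier timepoint t_0..t_{J-1}: the last step is
    gamma_{J-1} s, and earlier steps chain through the row-normalised
    couplings, so a two-step pull-back equals the pull-back through the
    product of the row-normalised maps.
    """
    s = np.asarray(target_set, dtype=float)
    if len(maps) == 0:
        raise ValueError("empty transport chain")
    if maps[-1].gamma.shape[1] != s.shape[0]:
        raise ValueError("target indicator does not match the final coupling")
    for i in range(len(maps) - 1):
        if maps[i].gamma.shape[1] != maps[i + 1].gamma.shape[0]:
            raise ValueError("gap in the transport chain (inner dimensions differ)")
    masses: list[np.ndarray] = [None] * len(maps)  # type: ignore[list-item]
    v = s
    for step in range(len(maps) - 1, -1, -1):
        gamma = maps[step].gamma
        masses[step] = gamma @ v
        if step > 0:
            rows = gamma.sum(axis=1, keepdims=True)
            P = np.divide(gamma, rows, out=np.zeros_like(gamma), where=rows > 0)
            v = P @ v
    return masses


# ---------------------------------------------------------------------------
# lineage graph


@dataclass
class LineageGraph:
    """Directed graph on (cluster, timepoint-index) nodes."""

    nodes: list[tuple[str, int]]
    A: pd.DataFrame
    A_sparse: pd.DataFrame | None = None
    edges: list[tuple[tuple[str, int], tuple[str, int], float]] = field(default_factory=list)
    communities: dict[tuple[str, int], int] = field(default_factory=dict)
    annotations: dict[int, str] = field(default_factory=dict)
    annotation_margin: dict[int, float] = field(default_factory=dict)
    annotation_candidates: dict[int, list[str]] = field(default_factory=dict)


def _node_name(node: tuple[str, int]) -> str:
    return f"{node[0]}@{node[1]}"


def contribution_matrix(
    maps: list[TransportMap],
    clusters: np.ndarray,
    times: np.ndarray,
    normalisation: str = "target",
) -> LineageGraph:
    """Aggregate couplings into the (cluster, timepoint) contribution matrix.

    Rows index source nodes (c, i), columns target nodes (c', i+1).  Two
    normalisations of the transported block mass are supported:

    - "target" (default): entry = share of cluster c''s incoming mass at
      timepoint i+1 contributed by cluster c — each target's column sums
      to 1.  A cluster that feeds several descendants keeps a near-1 entry
      to each, so lineage continuations and branch points both survive the
      downstream power sparsification.
    - "source": entry = fraction of cluster c's transported mass landing in
      c' — each source's outgoing row sums to 1.  At an even n-way split the
      outgoing entries are ~1/n and a hard power threshold removes all of
      them, so this mode is kept for mass accounting, not graph building.
    """
    if normalisation not in ("target", "source"):
        raise ValueError("normalisation must be 'target' or 'source'")
    clusters = np.asarray(clusters, dtype=object)
    times = np.asarray(times, dtype=float)
    unique_t = np.unique(times)
    if len(maps) != len(unique_t) - 1:
        raise ValueError("need one coupling per consecutive timepoint pair")
    idx = [np.flatnonzero(times == t) for t in unique_t]

    nodes: list[tuple[str, int]] = []
    for i, ix in enumerate(idx):
        for c in sorted(set(clusters[ix])):
            nodes.append((str(c), i))
    names = [_node_name(n) for n in nodes]
    A = pd.DataFrame(0.0, index=names, columns=names)

    for i, tm in enumerate(maps):
        src_clusters = clusters[idx[i]]
        tgt_clusters = clusters[idx[i + 1]]
        src_names = sorted(set(src_clusters))
        tgt_names = sorted(set(tgt_clusters))
        block = np.zeros((len(src_names), len(tgt_names)))
        for si, c in enumerate(src_names):
            rows = np.flatnonzero(src_clusters == c)
            for ti, c2 in enumerate(tgt_names):
                cols = np.flatnonzero(tgt_clusters == c2)
                block[si, ti] = tm.gamma[np.ix_(rows, cols)].sum()
        if normalisation == "source":
            denom = block.sum(axis=1, keepdims=True)
            block = np.divide(block, denom, out=np.zeros_like(block), where=denom > 0)
        else:
            denom = block.sum(axis=0, keepdims=True)
            block = np.divide(block, denom, out=np.zeros_like(block), where=denom > 0)
        for si, c in enumerate(src_names):
            for ti, c2 in enumerate(tgt_names):
                A.loc[_node_name((str(c), i)), _node_name((str(c2), i + 1))] = block[si, ti]
    return LineageGraph(nodes=nodes, A=A)


def sparsify(
    A: pd.DataFrame, P: float = 30.0, censor: float = 0.1, mode: str = "powered"
) -> pd.DataFrame:
    """Power-threshold sparsification: A^P elementwise, entries <= censor -> 0.

    mode="powered" keeps the powered values as weights; mode="masked" uses
    A^P only as a mask and keeps the original values.
    """
    powered = A.to_numpy() ** P
    keep = powered > censor
    if mode == "powered":
        out = np.where(keep, powered, 0.0)
    elif mode == "masked":
        out = np.where(keep, A.to_numpy(), 0.0)
    else:
        raise ValueError("mode must be 'powered' or 'masked'")
    return pd.DataFrame(out, index=A.index, columns=A.columns)


def build_lineage_graph(graph: LineageGraph, k_graph: int = 5, A_sparse: pd.DataFrame | None = None) -> LineageGraph:
    """Directed KNN edges: each node keeps its k highest-weight outgoing entries.

    Ties break deterministically by target-node order.
    """
    if A_sparse is not None:
        graph.A_sparse = A_sparse
    if graph.A_sparse is None:
        raise ValueError("sparsify the contribution matrix first")
    M = graph.A_sparse.to_numpy()
    names = list(graph.A_sparse.index)
    node_of = {name: node for name, node in zip(names, graph.nodes)}
    edges = []
    for i, name in enumerate(names):
        row = M[i]
        nz = np.flatnonzero(row > 0)
        if nz.size == 0:
            continue
        top = nz[np.argsort(-row[nz], kind="stable")][:k_graph]
        for j in sorted(top):
            edges.append((node_of[name], node_of[names[j]], float(row[j])))
    graph.edges = edges
    return graph


def detect_communities(graph: LineageGraph, steps: int = 4) -> LineageGraph:
    """Walktrap meta-clusters on the lineage graph.

    The directed weighted graph is symmetrised by summing edge weights (the
    random-walk agglomeration is defined for undirected graphs); isolated
    nodes come out as singleton communities.
    """
    n = len(graph.nodes)
    index_of = {node: i for i, node in enumerate(graph.nodes)}
    weight: dict[tuple[int, int], float] = {}
    for src, dst, w in graph.edges:
        i, j = index_of[src], index_of[dst]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        weight[key] = weight.get(key, 0.0) + w
    g = igraph.Graph(n)
    if weight:
        g.add_edges(list(weight.keys()))
        g.es["weight"] = list(weight.values())
        clustering = g.community_walktrap(weights="weight", steps=steps).as_clustering()
    else:
        clustering = g.community_walktrap(steps=steps).as_clustering()
    graph.communities = {node: clustering.membership[i] for i, node in enumerate(graph.nodes)}
    return graph


def annotate_metaclusters(
    cells: CellSet,
    graph: LineageGraph,
    markers: dict[str, str],
    times: np.ndarray,
) -> tuple[LineageGraph, pd.Series]:
    """Label meta-clusters by marker expression and map labels back to cells.

    `markers` maps gene id -> lineage name.  Each meta-cluster gets the
    lineage whose marker genes have the highest mean logCP10k expression over
    its constituent cells; an exact tie yields UNRESOLVED with the candidates
    recorded.  Returns the graph and a per-cell lineage label series.
    """
    if not markers:
        raise ValueError("marker map is empty")
    if not graph.communities:
        raise ValueError("detect communities first")
    times = np.asarray(times, float)
    unique_t = np.unique(times)
    t_index = {t: i for i, t in enumerate(unique_t)}
    clusters = cells.meta["cluster"].astype(str).to_numpy()
    cell_nodes = [ (clusters[i], t_index[times[i]]) for i in range(cells.n_cells) ]

    lineages = sorted(set(markers.values()))
    gene_pos = {g: i for i, g in enumerate(cells.gene_ids)}
    marker_idx = {
        lin: [gene_pos[g] for g, l in markers.items() if l == lin and g in gene_pos]
        for lin in lineages
    }
    empty = [lin for lin, idx in marker_idx.items() if not idx]
    if empty:
        raise ValueError(f"no marker genes found in the data for: {empty}")
    norm = normalize_logcp10k(cells)

    members: dict[int, list[int]] = {}
    for i, node in enumerate(cell_nodes):
        com = graph.communities.get(node)
        if com is not None:
            members.setdefault(com, []).append(i)
    for com in set(graph.communities.values()):
        if com not in members:
            raise ValueError(f"meta-cluster {com} has no constituent cells")

    for com, rows in members.items():
        scores = {
            lin: float(norm.values[np.ix_(rows, idx)].mean())
            for lin, idx in marker_idx.items()
        }
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, -np.inf)
        margin = best[1] - second[1]
        graph.annotation_margin[com] = margin
        if margin == 0.0 and second[0] is not None:
            graph.annotations[com] = "UNRESOLVED"
            graph.annotation_candidates[com] = [best[0], second[0]]
        else:
            graph.annotations[com] = best[0]
            graph.annotation_candidates[com] = [best[0]]

    labels = pd.Series(
        [graph.annotations[graph.communities[node]] for node in cell_nodes],
        index=cells.meta.index,
        name="wot_lineage",
    )
    return graph, labels


# ---------------------------------------------------------------------------
# plumbing: per-timepoint clustering when none is given


def cluster_cells(embedding: Embedding, resolution: float = 1.0, n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """Leiden-style modularity clustering on a KNN graph (plumbing only)."""
    import leidenalg

    n = embedding.n_cells
    d = cdist(embedding.coords, embedding.coords)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
    edges = set()
    for i in range(n):
        for j in order[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n, list(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def reconstruct_lineages(
    cells: CellSet,
    embedding: Embedding,
    markers: dict[str, str],
    params: OTParams | None = None,
    time_mode: str = "absolute",
    power: float = 30.0,
    censor: float = 0.1,
    k_graph: int = 5,
    sparsify_mode: str = "powered",
    normalisation: str = "target",
    growth_iters: int = 3,
) -> tuple[LineageGraph, pd.Series, list[TransportMap]]:
    """End-to-end lineage reconstruction: couplings -> graph -> annotations."""
    params = params or OTParams()
    times, _ = assign_times(cells, mode=time_mode)
    maps, _, _ = transport_chain(embedding, times, params, growth_iters=growth_iters)
    clusters = cells.meta["cluster"].astype(str).to_numpy()
    graph = contribution_matrix(maps, clusters, times, normalisation=normalisation)
    graph.A_sparse = sparsify(graph.A, P=power, censor=censor, mode=sparsify_mode)
    graph = build_lineage_graph(graph, k_graph=k_graph)
    graph = detect_communities(graph)
    graph, labels = annotate_metaclusters(cells, graph, markers, times)
    return graph, labels, maps
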