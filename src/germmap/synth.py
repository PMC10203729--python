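"""Synthetic branching time courses, spatial references and query sets.

The generator emulates the statistical skeleton of a stem-cell
differentiation time course profiled by droplet scRNA-seq: clusters of cells
follow a planted lineage tree (a pluripotent root that splits into
mesoderm-like, endoderm-like and a shared amnion/PGC progenitor, which
itself bifurcates later), counts are negative-binomial with lineage-marker
genes up-regulated after each branch point, and a low-dimensional embedding
traces the mean trajectory of each branch with Gaussian jitter.  Everything
downstream — label transfer, spatial projection, diffusion geometry,
optimal-transport lineage reconstruction — is validated against this planted
ground truth.

The embedding truth is generated directly in low dimension (d = 10) rather
than via PCA of the counts, so tests of the mapping and transport stages are
decoupled from preprocessing; the counts -> preprocess -> embed path is
exercised separately in integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellSet, Embedding, UNASSIGNED
from .spatial import SpatialReference

import pandas as pd

#: Default collection times (hours): PSC at 0, PreME at 12, then EB stages.
DEFAULT_TIMEPOINTS_H = (0.0, 12.0, 24.0, 30.0, 36.0, 42.0, 44.0, 52.0, 60.0, 108.0)

EMBED_DIM = 10

ROOT = "Epi"
PROGENITOR = "AmPGC"
FOUR_LINEAGES = ("MeLC", "DELC", "PGCLC", "AmLC")


@dataclass
class LineageTree:
    """Planted ground-truth lineage tree over (cluster, timepoint) nodes."""

    nodes: list[tuple[str, int]]
    edges: list[tuple[tuple[str, int], tuple[str, int]]]
    branch_times: dict[str, int]
    parents: dict[str, str | None] = field(default_factory=dict)
    terminal_lineages: tuple[str, ...] = ()
    node_means: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    node_embedding_means: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    marker_genes: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (c1, t1), (c2, t2) in self.edges:
            if t2 != t1 + 1:
                raise ValueError("edges must connect consecutive timepoint indices")
            if (c1, t1) not in node_set or (c2, t2) not in node_set:
                raise ValueError("edge endpoint not a node")

    def descendants_or_self(self, branch: str) -> set[str]:
        """All branches reachable from `branch`, including itself."""
        out = {branch}
        frontier = [branch]
        while frontier:
            b = frontier.pop()
            for child, parent in self.parents.items():
                if parent == b and child not in out:
                    out.add(child)
                    frontier.append(child)
        return out


@dataclass
class SynthParams:
    """Knobs of the generator; defaults are the study conditions.

    `effect_size` is the log-scale mean shift of a lineage's marker genes
    after its branch point; `dispersion` is the negative-binomial
    overdispersion alpha in Var = mu + alpha * mu^2; `noise_sd` is the
    Gaussian jitter of embedding coordinates around the branch mean
    trajectory; `domain_separation` scales the distance between lineage
    centroids in the shared embedding of the spatial reference.
    """

    n_genes: int = 300
    n_cells_per_cluster: int = 200
    n_lineages: int = 4
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    effect_size: float = 1.0
    dispersion: float = 0.5
    noise_sd: float = 0.3
    n_markers_per_lineage: int = 10
    embed_step: float = 1.0
    domain_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_cluster < 0 or self.n_lineages <= 0:
            raise ValueError("sizes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len(self.timepoints_h) < 1:
            raise ValueError("need at least one timepoint")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValueError("timepoints_h must be strictly increasing")


def _lineage_names(n: int) -> list[str]:
    if n == 4:
        return list(FOUR_LINEAGES)
    return [f"L{i + 1}" for i in range(n)]


def _build_topology(params: SynthParams) -> tuple[dict[str, str | None], dict[str, int], list[str]]:
    """Branch -> parent map, branch -> first-timepoint index, terminal names.

    With >= 4 lineages the last two terminals share a later progenitor,
    mirroring the amnion/PGC split arriving after the mesoderm split; with
    fewer, the root splits once into all terminals.
    """
    n_t = len(params.timepoints_h)
    terminals = _lineage_names(params.n_lineages)
    parents: dict[str, str | None] = {ROOT: None}
    branch_idx: dict[str, int] = {ROOT: 0}
    if params.n_lineages == 1:
        return parents, branch_idx, terminals
    b1 = min(3, max(1, n_t - 1))
    b2 = min(5, n_t - 1)
    if params.n_lineages >= 4 and b2 > b1:
        early = terminals[:-2]
        late = terminals[-2:]
        for name in early:
            parents[name] = ROOT
            branch_idx[name] = b1
        parents[PROGENITOR] = ROOT
        branch_idx[PROGENITOR] = b1
        for name in late:
            parents[name] = PROGENITOR
            branch_idx[name] = b2
    else:
        for name in terminals:
            parents[name] = ROOT
            branch_idx[name] = b1
    return parents, branch_idx, terminals


def _alive_interval(branch: str, parents: dict[str, str | None], branch_idx: dict[str, int], n_t: int) -> tuple[int, int]:
    """[first, last] timepoint indices at which `branch` has cells."""
    first = branch_idx[branch]
    children_starts = [branch_idx[c] for c, p in parents.items() if p == branch]
    last = min(children_starts) - 1 if children_starts else n_t - 1
    return first, last


def _gene_model(params: SynthParams, terminals: list[str], rng: np.random.Generator):
    """Baseline per-gene means and disjoint marker-gene sets per terminal lineage."""
    base_log_mean = rng.normal(0.0, 1.0, size=params.n_genes)
    n_mark = params.n_markers_per_lineage
    if n_mark * len(terminals) > params.n_genes:
        raise ValueError("not enough genes for the requested marker sets")
    perm = rng.permutation(params.n_genes)
    markers = {
        lin: sorted(perm[i * n_mark : (i + 1) * n_mark].tolist())
        for i, lin in enumerate(terminals)
    }
    return base_log_mean, markers


def _node_mean(
    branch: str,
    t_idx: int,
    base_log_mean: np.ndarray,
    markers: dict[str, list[int]],
    branch_idx: dict[str, int],
    params: SynthParams,
    ramp_len: int = 2,
) -> np.ndarray:
    """Expected NB mean vector of (branch, t_idx) cells."""
    log_mu = base_log_mean.copy()
    if branch in markers and params.effect_size != 0:
        steps = t_idx - branch_idx[branch] + 1
        ramp = min(1.0, steps / ramp_len)
        log_mu[markers[branch]] += params.effect_size * ramp
    return np.exp(log_mu)


def _sample_nb(mu: np.ndarray, alpha: float, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, np.broadcast_to(p, size))


def simulate_timecourse(params: SynthParams) -> tuple[CellSet, Embedding, LineageTree]:
    """Simulate the branching differentiation time course.

    Returns the counts + metadata (`cluster` is the branch a cell sits on,
    `lineage` its planted branch identity, `time_h` its collection time), the
    ground-truth low-dimensional embedding, and the planted lineage tree with
    per-node generator means attached.
    """
    rng = np.random.default_rng(params.seed)
    n_t = len(params.timepoints_h)
    parents, branch_idx, terminals = _build_topology(params)
    base_log_mean, markers = _gene_model(params, terminals, rng)

    # embedding mean trajectories: each branch walks along its own axis
    # starting from its parent's position at the branch point
    axes = {b: np.eye(EMBED_DIM)[i % EMBED_DIM] for i, b in enumerate(parents)}
    emb_mean: dict[tuple[str, int], np.ndarray] = {}
    nodes: list[tuple[str, int]] = []
    for branch in parents:
        first, last = _alive_interval(branch, parents, branch_idx, n_t)
        parent = parents[branch]
        if parent is None:
            origin = np.zeros(EMBED_DIM)
        else:
            origin = emb_mean[(parent, first - 1)]
        for t in range(first, last + 1):
            emb_mean[(branch, t)] = origin + axes[branch] * params.embed_step * (t - first + 1)
            nodes.append((branch, t))
    nodes.sort(key=lambda n: (n[1], n[0]))

    edges = []
    for branch in parents:
        first, last = _alive_interval(branch, parents, branch_idx, n_t)
        for t in range(first, last):
            edges.append(((branch, t), (branch, t + 1)))
        parent = parents[branch]
        if parent is not None:
            edges.append(((parent, first - 1), (branch, first)))

    node_means: dict[tuple[str, int], np.ndarray] = {}
    counts_blocks, coords_blocks, meta_rows = [], [], []
    n_per = params.n_cells_per_cluster
    for branch, t in nodes:
        mu = _node_mean(branch, t, base_log_mean, markers, branch_idx, params)
        node_means[(branch, t)] = mu
        counts_blocks.append(_sample_nb(mu, params.dispersion, (n_per, params.n_genes), rng))
        coords_blocks.append(
            emb_mean[(branch, t)] + rng.normal(0.0, params.noise_sd, size=(n_per, EMBED_DIM))
        )
        time_h = params.timepoints_h[t]
        meta_rows.extend(
            {
                "time_h": time_h,
                "sample": f"t{time_h:g}h",
                "cluster": branch,
                "lineage": branch,
                "label": UNASSIGNED,
            }
            for _ in range(n_per)
        )

    n_cells = n_per * len(nodes)
    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]
    counts = np.vstack(counts_blocks) if counts_blocks else np.zeros((0, params.n_genes), dtype=int)
    coords = np.vstack(coords_blocks) if coords_blocks else np.zeros((0, EMBED_DIM))
    cells = CellSet(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=[f"gene{i:04d}" for i in range(params.n_genes)],
        meta=pd.DataFrame(meta_rows),
    )
    embedding = Embedding(coords=coords, cell_ids=cell_ids, space_tag="synth10")
    tree = LineageTree(
        nodes=nodes,
        edges=edges,
        branch_times={b: i for b, i in branch_idx.items() if parents[b] is not None},
        parents=parents,
        terminal_lineages=tuple(terminals),
        node_means=node_means,
        node_embedding_means=emb_mean,
        marker_genes=markers,
    )
    return cells, embedding, tree


# ---------------------------------------------------------------------------
# spatial reference + query


def _lineage_embedding_centroids(params: SynthParams, terminals: list[str]) -> np.ndarray:
    """Well-separated lineage centroids in the shared embedding space."""
    cents = np.zeros((len(terminals), EMBED_DIM))
    for i in range(len(terminals)):
        cents[i, i % EMBED_DIM] = params.domain_separation
    return cents


def _spatial_domains(n: int, semi_x: float, margin: float = 0.1):
    """Contiguous, non-overlapping x-intervals along the anterior-posterior axis."""
    edges = np.linspace(-0.9 * semi_x, 0.9 * semi_x, n + 1)
    width = edges[1] - edges[0]
    pad = margin * width
    return [(edges[i] + pad, edges[i + 1] - pad) for i in range(n)]


def simulate_spatial_reference(params: SynthParams) -> SpatialReference:
    """Reference cells on an ellipsoid-like shell with lineage domains along x.

    Each lineage occupies a contiguous interval of the first (anterior-
    posterior) axis; its cells' embedding coordinates are Gaussian around the
    lineage centroid, so embedding proximity tracks lineage identity.
    Domain centroids are attached as ground truth.
    """
    rng = np.random.default_rng(params.seed)
    terminals = _lineage_names(params.n_lineages)
    semi = np.array([3.0, 1.5, 1.0])  # ellipsoid semi-axes, arbitrary units
    domains = _spatial_domains(params.n_lineages, semi[0])
    cents = _lineage_embedding_centroids(params, terminals)

    n_per = params.n_cells_per_cluster
    positions, labels, emb = [], [], []
    for i, lin in enumerate(terminals):
        lo, hi = domains[i]
        x = rng.uniform(lo, hi, size=n_per)
        theta = rng.uniform(0, 2 * np.pi, size=n_per)
        shrink = np.sqrt(np.clip(1.0 - (x / semi[0]) ** 2, 0.0, None))
        radial = 1.0 + rng.normal(0.0, 0.03, size=n_per)  # thin shell
        y = semi[1] * shrink * np.cos(theta) * radial
        z = semi[2] * shrink * np.sin(theta) * radial
        positions.append(np.column_stack([x, y, z]))
        labels.extend([lin] * n_per)
        emb.append(cents[i] + rng.normal(0.0, params.noise_sd, size=(n_per, EMBED_DIM)))

    n_ref = n_per * len(terminals)
    ids = [f"ref{i:06d}" for i in range(n_ref)]
    ref = SpatialReference(
        positions=np.vstack(positions),
        labels=list(labels),
        embedding=Embedding(np.vstack(emb), ids, space_tag="synth10"),
    )
    ref.domain_centroids = {  # type: ignore[attr-defined]
        lin: np.array([(domains[i][0] + domains[i][1]) / 2, 0.0, 0.0])
        for i, lin in enumerate(terminals)
    }
    ref.domain_intervals = {lin: domains[i] for i, lin in enumerate(terminals)}  # type: ignore[attr-defined]
    return ref


def plant_query(
    params: SynthParams, reference: SpatialReference, n_query_per_lineage: int | None = None
) -> tuple[CellSet, Embedding, list[str]]:
    """Query cells drawn from the same lineage distributions as the reference.

    Counts come from the lineage marker model (markers of a cell's lineage
    up-shifted by `effect_size`); embedding coordinates share the reference's
    centroids by construction.  True labels are returned for benchmarking.
    """
    rng = np.random.default_rng(params.seed + 1)
    terminals = _lineage_names(params.n_lineages)
    cents = _lineage_embedding_centroids(params, terminals)
    base_log_mean, markers = _gene_model(params, terminals, np.random.default_rng(params.seed))

    n_per = params.n_cells_per_cluster if n_query_per_lineage is None else n_query_per_lineage
    counts_blocks, emb_blocks, true_labels = [], [], []
    for i, lin in enumerate(terminals):
        log_mu = base_log_mean.copy()
        log_mu[markers[lin]] += params.effect_size
        mu = np.exp(log_mu)
        counts_blocks.append(_sample_nb(mu, params.dispersion, (n_per, params.n_genes), rng))
        emb_blocks.append(cents[i] + rng.normal(0.0, params.noise_sd, size=(n_per, EMBED_DIM)))
        true_labels.extend([lin] * n_per)

    n_q = n_per * len(terminals)
    ids = [f"query{i:06d}" for i in range(n_q)]
    gene_ids = [f"gene{i:04d}" for i in range(params.n_genes)]
    if n_q == 0:
        return (
            CellSet(np.zeros((0, params.n_genes), dtype=int), [], gene_ids),
            Embedding(np.zeros((0, EMBED_DIM)), [], space_tag="synth10"),
            [],
        )
    meta = pd.DataFrame({"lineage": true_labels, "label": UNASSIGNED})
    cells = CellSet(np.vstack(counts_blocks), ids, gene_ids, meta=meta)
    emb = Embedding(np.vstack(emb_blocks), ids, space_tag="synth10")
    return cells, emb, true_labels


def curve_embedding(n: int = 300, dim: int = 10, seed: int = 0, noise_sd: float = 0.0) -> tuple[Embedding, np.ndarray]:
    """Points along a smooth 1-D curve embedded in `dim` dimensions.

    Returns the embedding and the latent curve parameter (ground truth for
    diffusion-component and pseudotime ordering tests).
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, size=n))
    coords = np.zeros((n, dim))
    coords[:, 0] = np.sin(1.5 * np.pi * t)
    coords[:, 1] = np.cos(1.5 * np.pi * t)
    coords[:, 2] = 2.0 * t
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    ids = [f"c{i:05d}" for i in range(n)]
    return Embedding(coords, ids, space_tag="curve"), t
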