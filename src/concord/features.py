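"""Topological feature vectors for constraint pairs.

Each node pair is described by seven symmetric features computed from the
network topology alone: a shared-edge indicator, the common-neighbour
count, the Jaccard overlap of neighbourhoods, the reciprocal shortest-path
length, the cosine similarity of adjacency rows, the SimRank similarity,
and the cosine similarity of random-walk node embeddings.  The feature
matrix is min-max scaled per column over the constraint set before being
fed to outlier detectors, so that margin- and distance-based models see
commensurate scales.

Six of the features are the standard pairwise measures named for this
task; the neighbourhood Jaccard coefficient is this package's choice for
the seventh input dimension and is documented as such in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

FEATURE_NAMES = (
    "shared_edge",
    "common_neighbors",
    "neighborhood_jaccard",
    "shortest_path_score",
    "cosine_similarity",
    "simrank",
    "embedding_similarity",
)

__all__ = [
    "FEATURE_NAMES",
    "PairFeaturizer",
    "compute_simrank",
    "compute_embedding",
    "extract_features",
    "minmax_scale_columns",
]


def _index_graph(g: nx.Graph) -> tuple[np.ndarray, dict[int, int], sp.csr_matrix]:
    """Dense 0-based indexing and the CSR adjacency of a graph."""
    nodes = np.array(sorted(g.nodes()))
    idx = {int(v): i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    n = len(nodes)
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return nodes, idx, adj


def compute_simrank(
    g: nx.Graph, C: float = 0.8, tol: float = 1e-4, max_iter: int = 100
) -> tuple[np.ndarray, dict[int, int]]:
    """All-pairs SimRank by fixed-point iteration of

        s(u, v) = C / (|N(u)| |N(v)|) * sum_{a in N(u), b in N(v)} s(a, b)

    with s(u, u) = 1 and s = 0 whenever either node has no neighbours.
    Implemented in matrix form, ``S <- C * W^T S W`` with W the
    column-normalised adjacency, which keeps the cost at
    O(iterations * nnz * n) using sparse-dense products.

    Returns the similarity matrix over dense indices and the node -> index
    map.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes, idx, adj = _index_graph(g)
    n = len(nodes)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    W = adj.multiply(inv[np.newaxis, :]).tocsr()  # column-normalised
    Wt = W.T.tocsr().astype(np.float32)
    S = np.eye(n, dtype=np.float32)
    isolated = deg == 0
    for _ in range(max_iter):
        # S is symmetric throughout, so W^T S W == Wt @ (Wt @ S)^T
        S_new = C * (Wt @ np.ascontiguousarray((Wt @ S).T))
        np.fill_diagonal(S_new, 1.0)
        S_new[isolated, :] = 0.0
        S_new[:, isolated] = 0.0
        S_new[isolated, isolated] = 1.0
        delta = np.max(np.abs(S_new - S))
        S = S_new
        if delta < tol:
            break
    # exact symmetry (float32 products can drift by ~1e-8)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    S[isolated, :] = 0.0
    S[:, isolated] = 0.0
    S[isolated, isolated] = 1.0
    return S.astype(np.float64), idx


def _random_walks(
    adj: sp.csr_matrix, rng: np.random.Generator, n_walks: int, walk_length: int
) -> np.ndarray:
    """Uniform random walks from every node, vectorised over walkers."""
    n = adj.shape[0]
    deg = np.diff(adj.indptr)
    starts = np.tile(np.arange(n), n_walks)
    walks = np.empty((len(starts), walk_length), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for t in range(1, walk_length):
        r = rng.random(len(cur))
        d = deg[cur]
        # dead ends stay put
        offset = np.floor(r * np.maximum(d, 1)).astype(np.int64)
        nxt = adj.indices[adj.indptr[cur] + np.minimum(offset, np.maximum(d - 1, 0))]
        nxt = np.where(d > 0, nxt, cur)
        walks[:, t] = nxt
        cur = nxt
    return walks


def compute_embedding(
    g: nx.Graph,
    dims: int = 64,
    n_walks: int = 10,
    walk_length: int = 80,
    window: int = 10,
    seed: int | None = 0,
) -> dict[int, np.ndarray]:
    """Random-walk node embedding (node2vec-style corpus, p = q = 1).

    A corpus of uniform random walks is summarised into a window-based
    co-occurrence matrix, converted to shifted positive PMI, and factorised
    by truncated SVD — the closed-form counterpart of skip-gram training
    with negative sampling.  Deterministic given the seed.
    """
    nodes, idx, adj = _index_graph(g)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    walks = _random_walks(adj, rng, n_walks, walk_length)

    # window co-occurrence counts, symmetrised
    rows_all = []
    cols_all = []
    for off in range(1, window + 1):
        rows_all.append(walks[:, :-off].ravel())
        cols_all.append(walks[:, off:].ravel())
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    data = np.ones(len(rows))
    cooc = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    cooc = cooc + cooc.T

    total = cooc.sum()
    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    cooc = cooc.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(cooc.data * total) - np.log(
            row_sums[cooc.row] * row_sums[cooc.col]
        )
    ppmi_data = np.maximum(pmi, 0.0)
    keep = ppmi_data > 0
    ppmi = sp.coo_matrix(
        (ppmi_data[keep], (cooc.row[keep], cooc.col[keep])), shape=(n, n)
    ).tocsr()

    k = min(dims, max(2, n - 1))
    u, s, _ = sp.linalg.svds(ppmi, k=k, random_state=int(rng.integers(2**31 - 1)))
    order = np.argsort(-s)
    vecs = u[:, order] * np.sqrt(s[order])
    if k < dims:
        vecs = np.hstack([vecs, np.zeros((n, dims - k))])
    return {int(v): vecs[i] for v, i in idx.items()}


def minmax_scale_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each column to [0, 1]; constant columns map to 0."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    span_safe = np.where(span > 0, span, 1.0)
    Xs = (X - lo) / span_safe
    Xs[:, span == 0] = 0.0
    return Xs, lo, hi


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class PairFeaturizer:
    """Computes 7-dimensional feature vectors for node pairs of one network.

    The expensive whole-network quantities (SimRank table, embedding) are
    computed once on construction and reused for every constraint batch;
    ``__call__`` returns the raw (unscaled) feature matrix for a pair list.
    """

    graph: nx.Graph
    simrank_C: float = 0.8
    simrank_tol: float = 1e-4
    simrank_max_iter: int = 100
    embedding_dims: int = 64
    n_walks: int = 10
    walk_length: int = 80
    window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self._nodes, self._idx, self._adj = _index_graph(self.graph)
        self._deg = np.diff(self._adj.indptr)
        self._S, _ = compute_simrank(
            self.graph, self.simrank_C, self.simrank_tol, self.simrank_max_iter
        )
        emb = compute_embedding(
            self.graph,
            dims=self.embedding_dims,
            n_walks=self.n_walks,
            walk_length=self.walk_length,
            window=self.window,
            seed=self.seed,
        )
        self._emb = np.vstack([emb[int(v)] for v in self._nodes])
        self._neighbors = [
            set(self._adj.indices[self._adj.indptr[i]: self._adj.indptr[i + 1]])
            for i in range(len(self._nodes))
        ]

    def __call__(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        if not pairs:
            return np.empty((0, len(FEATURE_NAMES)))
        for u, v in pairs:
            if u not in self._idx or v not in self._idx:
                raise ValueError(f"pair ({u}, {v}) references a node absent from the network")
        ui = np.array([self._idx[u] for u, _ in pairs])
        vi = np.array([self._idx[v] for _, v in pairs])

        # shortest paths from the unique sources among the pairs
        sources = np.unique(ui)
        dist = dijkstra(self._adj, indices=sources, unweighted=True, limit=30)
        src_pos = {int(s): i for i, s in enumerate(sources)}

        X = np.empty((len(pairs), len(FEATURE_NAMES)))
        for r, (a, b) in enumerate(zip(ui, vi)):
            na, nb = self._neighbors[a], self._neighbors[b]
            common = len(na & nb)
            union = len(na | nb)
            d = dist[src_pos[int(a)], b]
            X[r, 0] = 1.0 if b in na else 0.0
            X[r, 1] = common
            X[r, 2] = common / union if union else 0.0
            X[r, 3] = 1.0 / d if np.isfinite(d) and d > 0 else 0.0
            X[r, 4] = common / np.sqrt(self._deg[a] * self._deg[b]) if self._deg[a] and self._deg[b] else 0.0
            X[r, 5] = self._S[a, b]
            X[r, 6] = _cosine(self._emb[a], self._emb[b])
        return X


def extract_features(
    pairs: list[tuple[int, int]],
    featurizer: PairFeaturizer,
    scale: bool = True,
) -> np.ndarray:
    """Feature matrix for a list of constraint pairs, min-max scaled per
    column over this batch (the scaling the detectors are fitted on)."""
    X = featurizer(pairs)
    if scale and len(X):
        X, _, _ = minmax_scale_columns(X)
    return X


def write_feature_tsv(X: np.ndarray, path, pairs: list[tuple[int, int]] | None = None) -> None:
    """Serialise a feature matrix to TSV with the canonical column header
    (optionally prefixed by the node pair each row describes)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected a (n, {len(FEATURE_NAMES)}) matrix")
    with open(path, "w") as fh:
        prefix = "u\tv\t" if pairs is not None else ""
        fh.write(prefix + "\t".join(FEATURE_NAMES) + "\n")
        for i, row in enumerate(X):
            lead = f"{pairs[i][0]}\t{pairs[i][1]}\t" if pairs is not None else ""
            fh.write(lead + "\t".join(f"{v:.6g}" for v in row) + "\n")
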