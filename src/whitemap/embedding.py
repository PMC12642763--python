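"""Isomap embedding of a precomputed distance matrix.

The chain is: k-nearest-neighbor graph (union-symmetrized), all-pairs
graph geodesics, double-centered Gram matrix, spectral embedding with
coordinates ``V_d @ diag(sqrt(lambda_d))``.  Geodesics use repeated
Dijkstra, which is output-identical to Floyd-Warshall for nonnegative
weights and far cheaper at large N; the unit tests pin it against a cubic
Floyd-Warshall oracle.  An optional seeded UMAP backend delegates to
umap-learn and is never reimplemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from whitemap.io_core import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "EmbeddingResult",
    "DisconnectedGraphError",
    "knn_graph",
    "geodesic_distances",
    "isomap_embed",
    "embed",
    "min_connected_k",
]

DEFAULT_K = 10


class DisconnectedGraphError(ValueError):
    """The neighbor graph is not connected."""


@dataclass(frozen=True)
class NeighborGraph:
    """Union-symmetrized k-nearest-neighbor graph over N data objects."""

    n_nodes: int
    edges: tuple[tuple[int, int, float], ...]  # i < j, weight = D[i, j]
    k: int

    def adjacency(self) -> sp.csr_matrix:
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        rows = [e[0] for e in self.edges] + [e[1] for e in self.edges]
        cols = [e[1] for e in self.edges] + [e[0] for e in self.edges]
        vals = [e[2] for e in self.edges] * 2
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )


@dataclass(frozen=True)
class EmbeddingResult:
    """N x d coordinates plus the retained (descending) eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    d: int
    backend: Literal["isomap", "umap"] = "isomap"


def knn_graph(D: DistanceMatrix, k: int) -> NeighborGraph:
    """Edges from each node to its k smallest-distance neighbors (self
    excluded, ties broken by lower index), symmetrized by union."""
    n = D.n
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k={k} out of range [1, {n - 1}]")
    values = D.values
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        order = np.argsort(values[i], kind="stable")  # stable => lower index on ties
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            edges.add((min(i, j), max(i, j)))
    edge_list = tuple(
        (i, j, float(values[i, j])) for i, j in sorted(edges)
    )
    return NeighborGraph(n_nodes=n, edges=edge_list, k=k)


def geodesic_distances(G: NeighborGraph, D: DistanceMatrix) -> np.ndarray:
    """All-pairs shortest-path distances through G, with direct edges kept
    at their input distance.  Errors on disconnected graphs, reporting
    component sizes."""
    adj = G.adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise DisconnectedGraphError(
            f"neighbor graph has {n_comp} components (sizes {sizes}); "
            "increase k or pass largest_component=True"
        )
    # zero-weight edges (duplicate objects) vanish in CSR storage, so use a
    # masked dense graph when any are present
    has_zero_edge = any(w == 0.0 for _, _, w in G.edges)
    if has_zero_edge:
        dense = np.zeros((G.n_nodes, G.n_nodes))
        mask = np.ones((G.n_nodes, G.n_nodes), dtype=bool)
        for i, j, w in G.edges:
            dense[i, j] = dense[j, i] = w
            mask[i, j] = mask[j, i] = False
        graph = np.ma.masked_array(dense, mask)
        D_hat = shortest_path(graph, method="D", directed=False)
    else:
        D_hat = shortest_path(adj, method="D", directed=False)
    return np.asarray(D_hat)


def min_connected_k(D: DistanceMatrix, k_start: int = DEFAULT_K) -> int:
    """Smallest k >= k_start whose union-symmetrized kNN graph is
    connected.

    Strongly clustered data (e.g. per-subject clumps of task scans) can
    leave small neighborhoods disconnected; escalating k is preferable to
    silently dropping components.
    """
    for k in range(min(k_start, D.n - 1), D.n):
        adj = knn_graph(D, k).adjacency()
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            if k > k_start:
                logger.info(
                    "k raised from %d to %d for graph connectivity",
                    k_start,
                    k,
                )
            return k
    raise DisconnectedGraphError(
        "graph disconnected even at k=N-1 (infinite/invalid distances?)"
    )


def isomap_embed(D_hat: np.ndarray, d: int) -> EmbeddingResult:
    """Classical-MDS step: double-center the squared distances and embed on
    the top-d nonnegative eigenpairs.

    If fewer than d eigenvalues are positive, fewer columns are returned
    with a warning.
    """
    D_hat = np.asarray(D_hat, dtype=float)
    n = D_hat.shape[0]
    if D_hat.shape != (n, n):
        raise ValidationError("geodesic distance matrix must be square")
    if not 1 <= d <= n - 1:
        raise ValidationError(f"d={d} out of range [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D_hat**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(float(eigvals[0]), 0.0) * 1e-12
    n_pos = int(np.sum(eigvals > tol))
    d_eff = min(d, n_pos)
    if d_eff < d:
        logger.warning(
            "only %d nonnegative eigenvalues available; returning %d of "
            "the requested %d dimensions",
            n_pos,
            d_eff,
            d,
        )
    if d_eff == 0:
        return EmbeddingResult(
            coordinates=np.zeros((n, 1)),
            eigenvalues=np.zeros(1),
            d=1,
            backend="isomap",
        )
    lam = eigvals[:d_eff]
    X = eigvecs[:, :d_eff] * np.sqrt(lam)
    return EmbeddingResult(
        coordinates=X, eigenvalues=lam, d=d_eff, backend="isomap"
    )


def embed(
    D: DistanceMatrix,
    k: int = DEFAULT_K,
    d: int = 2,
    backend: Literal["isomap", "umap"] = "isomap",
    seed: int = 0,
    largest_component: bool = False,
) -> EmbeddingResult:
    """Embed a distance matrix: isomap chains knn_graph -> geodesics ->
    spectral embedding; umap passes D to umap-learn as a precomputed
    metric with a fixed seed."""
    if backend == "umap":
        try:
            import umap  # optional dependency
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "backend='umap' requires the umap-learn package; install "
                "whitemap[umap]"
            ) from exc
        reducer = umap.UMAP(
            n_components=d,
            n_neighbors=min(k + 1, D.n - 1),
            metric="precomputed",
            random_state=seed,
        )
        coords = np.asarray(reducer.fit_transform(D.values), dtype=float)
        return EmbeddingResult(
            coordinates=coords,
            eigenvalues=np.full(coords.shape[1], np.nan),
            d=coords.shape[1],
            backend="umap",
        )
    if backend != "isomap":
        raise ValidationError(f"unknown backend {backend!r}")
    G = knn_graph(D, k)
    try:
        D_hat = geodesic_distances(G, D)
    except DisconnectedGraphError:
        if not largest_component:
            raise
        adj = G.adjacency()
        _, labels = connected_components(adj, directed=False)
        keep = np.flatnonzero(labels == np.bincount(labels).argmax())
        logger.warning(
            "restricting to largest component (%d of %d nodes)",
            keep.size,
            D.n,
        )
        sub = DistanceMatrix(
            values=D.values[np.ix_(keep, keep)],
            object_ids=tuple(D.object_ids[i] for i in keep),
            metric_name=D.metric_name,
        )
        return embed(
            sub, k=min(k, sub.n - 1), d=min(d, sub.n - 1), backend="isomap"
        )
    return isomap_embed(D_hat, d)
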