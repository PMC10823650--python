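"""Per-side similarity graphs for graph convolution.

Each side of the bipartite association matrix (circRNAs, diseases) gets a
symmetric weighted similarity graph built by fusing two signals:

* the Gaussian interaction-profile (GIP) kernel over that side's binary
  association profiles (rows of A for circRNAs, columns for diseases), and
* Jaccard similarity of auxiliary-neighbor sets from the side networks
  (shared miRNA partners, shared gene partners).

The fused matrix is k-nearest-neighbor sparsified, symmetrised, given
self-loops and symmetrically normalised (D^-1/2 (S+I) D^-1/2) for use as the
propagation operator of the graph-convolutional encoders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, SideNetwork

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric similarity weights plus their normalised adjacency.

    ``weights`` is the dense fused similarity (unit diagonal, entries in
    [0, 1]); ``norm_adj`` is the sparsified, self-looped, symmetrically
    normalised operator actually used for convolution.
    """

    weights: np.ndarray
    norm_adj: np.ndarray
    side: str  # "circRNA" | "disease"

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def laplacian(self) -> np.ndarray:
        """Unnormalised graph Laplacian of the dense weights (manifold loss)."""
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return np.diag(w.sum(axis=1)) - w

    def n_edges(self) -> int:
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return int(np.count_nonzero(np.triu(w)))


def gip_kernel(profiles: np.ndarray) -> np.ndarray:
    """Gaussian interaction-profile kernel over binary profile rows.

    K(i, j) = exp(-gamma * ||p_i - p_j||^2) with the bandwidth gamma set to
    1 / mean_i(||p_i||^2), the standard normalisation that makes the kernel
    scale-free in the number of interactions.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("profiles must be a non-empty 2-D matrix")
    sq_norms = (profiles**2).sum(axis=1)
    mean_norm = sq_norms.mean()
    if mean_norm == 0.0:
        raise ValueError("GIP bandwidth undefined: all profiles are zero")
    gamma = 1.0 / mean_norm
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i.p_j
    gram = profiles @ profiles.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def neighbor_jaccard(side_net: SideNetwork) -> np.ndarray:
    """Jaccard similarity of auxiliary-neighbor sets between primary entities.

    S(i, j) = |N_i & N_j| / |N_i | N_j|; the diagonal is 1 by convention (also
    for entities with no auxiliary neighbors), and a pair where both sets are
    empty scores 0 off-diagonal.
    """
    B = np.asarray(side_net.values, dtype=float)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return S


def fuse_similarities(
    gip: np.ndarray, side_sims: list[np.ndarray], gamma: float = 0.5
) -> np.ndarray:
    """Convex fusion S = gamma * GIP + (1 - gamma) * mean(side similarities).

    With no side similarities available the GIP kernel is returned unchanged.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if not side_sims:
        return gip.copy()
    for s in side_sims:
        if s.shape != gip.shape:
            raise ValueError(f"shape mismatch: {s.shape} vs {gip.shape}")
    side_mean = np.mean(side_sims, axis=0)
    S = gamma * gip + (1.0 - gamma) * side_mean
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def sparsify_and_normalize(
    S: np.ndarray, k_neighbors: int, side: str = "circRNA"
) -> SimilarityGraph:
    """kNN-sparsify a similarity matrix and build the normalised adjacency.

    Each node keeps its ``k_neighbors`` strongest off-diagonal weights; the
    result is symmetrised by elementwise max (an edge survives if either
    endpoint keeps it), self-loops are added, and the operator is normalised
    as Deg^-1/2 (S_knn + I) Deg^-1/2, whose spectral radius is <= 1.
    """
    if k_neighbors <= 0:
        raise ValueError("k_neighbors must be positive")
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("S must be square")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("S must be symmetric")
    k = min(k_neighbors, n - 1)
    off = S.copy()
    np.fill_diagonal(off, -np.inf)
    keep = np.zeros_like(S, dtype=bool)
    if n > 1:
        top = np.argpartition(-off, kth=k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        keep[rows, top.ravel()] = True
    sparse = np.where(keep, S, 0.0)
    sparse = np.maximum(sparse, sparse.T)
    np.fill_diagonal(sparse, 0.0)
    a_hat = sparse + np.eye(n)
    deg = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    norm_adj = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    weights = np.clip(0.5 * (S + S.T), 0.0, 1.0)
    np.fill_diagonal(weights, 1.0)
    return SimilarityGraph(weights=weights, norm_adj=norm_adj, side=side)


def build_side_graphs(
    A_train: AssociationMatrix,
    side_nets: dict[str, SideNetwork],
    gamma: float = 0.5,
    k_neighbors: int = 10,
) -> tuple[SimilarityGraph, SimilarityGraph]:
    """Assemble the circRNA and disease similarity graphs from a training split.

    The GIP kernels are computed from the training association matrix only, so
    held-out positives never leak into the similarity structure.  Side
    networks are keyed ``circ-mirna``/``circ-gene`` (circRNA side) and
    ``mirna-disease``/``disease-gene`` (disease side); any subset may be
    absent.
    """
    A = np.asarray(A_train.values, dtype=float)
    circ_sides = [
        neighbor_jaccard(side_nets[k]) for k in ("circ-mirna", "circ-gene") if k in side_nets
    ]
    dis_sides = [
        neighbor_jaccard(side_nets[k])
        for k in ("mirna-disease", "disease-gene")
        if k in side_nets
    ]
    circ_fused = fuse_similarities(gip_kernel(A), circ_sides, gamma)
    dis_fused = fuse_similarities(gip_kernel(A.T), dis_sides, gamma)
    g_circ = sparsify_and_normalize(circ_fused, k_neighbors, side="circRNA")
    g_dis = sparsify_and_normalize(dis_fused, k_neighbors, side="disease")
    return g_circ, g_dis
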