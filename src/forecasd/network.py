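"""Interaction-network shortest-path features.

The interaction graph is confidence-filtered, then converted into a dense
gene x gene matrix of unweighted hop distances ("minimum number of steps").
Unreachable pairs — including every pair involving an isolated node — are
imputed with (max finite off-diagonal distance) + 1, i.e. ordinally "farther
than anything observed", so the feature matrix stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import ValidationError
from .io import InteractionNetwork

DEFAULT_MIN_SCORE = 0.4


def filter_edges(net: InteractionNetwork, min_score: float = DEFAULT_MIN_SCORE) -> InteractionNetwork:
    """Remove low-confidence edges (score < ``min_score``); an edge scoring
    exactly ``min_score`` is kept.  The node list is unchanged, so nodes may
    become isolated."""
    if not (0.0 <= min_score <= 1.0):
        raise ValidationError("min_score must lie in [0, 1]")
    kept = net.edges[net.edges["score"] >= min_score].reset_index(drop=True)
    if len(kept) == 0:
        raise ValidationError(f"no edge has score >= {min_score}")
    return InteractionNetwork(edges=kept, nodes=list(net.nodes))


@dataclass
class ShortestPathMatrix:
    """Symmetric gene x gene hop-distance matrix with zero diagonal.

    ``sentinel`` is the value imputed for unreachable pairs.
    """

    genes: list[str]
    distances: np.ndarray
    sentinel: int

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.genes), len(self.genes)):
            raise ValidationError("distance matrix shape does not match gene list")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.array_equal(d, d.T):
            raise ValidationError("distance matrix must be symmetric")

    def as_dataframe(self) -> pd.DataFrame:
        idx = pd.Index(self.genes, name="gene")
        return pd.DataFrame(self.distances, index=idx, columns=list(self.genes))

    def feature_frame(self) -> pd.DataFrame:
        """Distances as a feature matrix (columns prefixed ``dist_``)."""
        idx = pd.Index(self.genes, name="gene")
        return pd.DataFrame(
            self.distances.astype(float),
            index=idx,
            columns=[f"dist_{g}" for g in self.genes],
        )


def shortest_path_matrix(net: InteractionNetwork, sentinel: int | None = None) -> ShortestPathMatrix:
    """All-pairs unweighted hop distances over the full node set.

    ``sentinel`` overrides the default unreachable-pair imputation of
    (max finite off-diagonal distance) + 1.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValidationError("network has no nodes")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    ia = net.edges["gene_a"].map(index).to_numpy()
    ib = net.edges["gene_b"].map(index).to_numpy()
    adj = coo_matrix((np.ones(len(ia)), (ia, ib)), shape=(n, n)).tocsr()
    dist = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=True)
    finite = np.isfinite(dist)
    off = finite.copy()
    np.fill_diagonal(off, False)
    if sentinel is None:
        sentinel = int(dist[off].max()) + 1 if off.any() else 1
    out = np.where(finite, dist, float(sentinel)).astype(np.int32)
    return ShortestPathMatrix(genes=nodes, distances=out, sentinel=int(sentinel))
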