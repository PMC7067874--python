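"""Size-constrained iterative greedy-modularity clustering.

Top-scoring genes are clustered on their induced interaction subgraph (no
confidence filter; edge confidences act as weights) by greedy agglomerative
modularity optimization.  Clusters larger than ``max_size`` are re-clustered
on their own induced subgraph, depth-first, until they split or prove
unsplittable (a single community at optimum — then retained and logged);
clusters smaller than ``min_size`` are discarded, with the reason recorded
per gene.  Per-cluster statistics: hypergeometric overlap with a reference
gene set against a fixed background, and Fisher enrichment of
haploinsufficiency-intolerant genes (pLI above a threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateInputError, ValidationError
from .evaluation import FisherResult, _fisher_from_table
from .io import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_MAX_SIZE = 200
DEFAULT_MIN_SIZE = 30
DEFAULT_BACKGROUND = 18_000
DEFAULT_PLI_THRESHOLD = 0.5


@dataclass
class ClusterSet:
    """Cluster assignments for retained genes plus bookkeeping.

    ``assignments`` maps gene -> cluster id (``c01``, ``c02``, ... ordered by
    decreasing size, ties by smallest member id); ``discarded`` maps each
    dropped gene to a reason; ``unsplittable`` lists retained clusters that
    exceeded ``max_size`` but would not split further.
    """

    assignments: dict[str, str]
    sizes: pd.Series
    discarded: dict[str, str] = field(default_factory=dict)
    unsplittable: list[str] = field(default_factory=list)

    def members(self, cluster_id: str) -> list[str]:
        return sorted(g for g, c in self.assignments.items() if c == cluster_id)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.sizes.index)


def _greedy_communities(graph: nx.Graph, weighted: bool) -> list[set[str]]:
    weight = "weight" if weighted else None
    comms = nx.community.greedy_modularity_communities(graph, weight=weight)
    return [set(c) for c in comms]


def iterative_modularity_clusters(
    net: InteractionNetwork,
    genes,
    max_size: int = DEFAULT_MAX_SIZE,
    min_size: int = DEFAULT_MIN_SIZE,
    weighted: bool = True,
) -> ClusterSet:
    """Cluster the induced subgraph on ``genes`` with size constraints.

    Vertices are inserted in lexicographic order so results are deterministic
    for identical inputs.  Isolated genes (degree zero in the induced
    subgraph) are discarded up front.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValidationError("empty gene subset")
    gene_set = set(genes)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    sub = net.edges[net.edges["gene_a"].isin(gene_set) & net.edges["gene_b"].isin(gene_set)]
    sub = sub.sort_values(["gene_a", "gene_b"], kind="mergesort")
    for a, b, s in sub[["gene_a", "gene_b", "score"]].itertuples(index=False):
        graph.add_edge(a, b, weight=float(s))
    if graph.number_of_edges() == 0:
        raise ValidationError("induced subgraph has no edges")

    discarded: dict[str, str] = {}
    isolates = [g for g in genes if graph.degree(g) == 0]
    for g in isolates:
        discarded[g] = "isolated"
    graph.remove_nodes_from(isolates)

    final: list[set[str]] = []
    unsplittable_members: list[set[str]] = []

    def recurse(nodes: set[str]) -> None:
        subgraph = graph.subgraph(sorted(nodes))
        if subgraph.number_of_edges() == 0:
            for g in sorted(nodes):
                discarded[g] = "isolated"
            return
        comms = _greedy_communities(subgraph, weighted)
        if len(comms) == 1:
            final.append(nodes)
            if len(nodes) > max_size:
                unsplittable_members.append(nodes)
                logger.warning(
                    "cluster of %d genes exceeds max_size=%d but would not split "
                    "further; retained",
                    len(nodes),
                    max_size,
                )
            return
        for comm in sorted(comms, key=lambda c: (-len(c), min(c))):
            if len(comm) > max_size:
                recurse(set(comm))
            else:
                final.append(set(comm))

    recurse(set(graph.nodes))

    retained = []
    for comm in final:
        if len(comm) < min_size:
            for g in sorted(comm):
                discarded[g] = "small-cluster"
        else:
            retained.append(comm)

    retained.sort(key=lambda c: (-len(c), min(c)))
    width = max(2, len(str(len(retained))))
    assignments: dict[str, str] = {}
    sizes = {}
    unsplit_ids = []
    for i, comm in enumerate(retained, start=1):
        cid = f"c{i:0{width}d}"
        sizes[cid] = len(comm)
        for g in comm:
            assignments[g] = cid
        if any(comm == u for u in unsplittable_members):
            unsplit_ids.append(cid)
    return ClusterSet(
        assignments=assignments,
        sizes=pd.Series(sizes, dtype=int, name="size"),
        discarded=discarded,
        unsplittable=unsplit_ids,
    )


def cluster_overlap_stats(
    clusters: ClusterSet, reference: set[str], background_size: int = DEFAULT_BACKGROUND
) -> pd.Series:
    """Upper-tail hypergeometric p-value of each cluster's overlap with a
    reference gene set, against a fixed background universe size."""
    reference = set(reference)
    if len(reference) > background_size:
        raise ValidationError("reference set larger than the background")
    if background_size < len(clusters.assignments):
        raise ValidationError("background smaller than the clustered gene count")
    out = {}
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        overlap = len(reference.intersection(members))
        # P(X >= overlap), X ~ Hypergeom(background, |reference|, cluster size)
        out[cid] = float(hypergeom.sf(overlap - 1, background_size, len(reference), len(members)))
    return pd.Series(out, name="overlap_p")


def cluster_pli_enrichment(
    clusters: ClusterSet, pli: pd.Series, threshold: float = DEFAULT_PLI_THRESHOLD
) -> dict[str, FisherResult]:
    """Fisher's exact test, per cluster, of pLI > ``threshold`` membership
    against all other clustered genes."""
    pli = pli.dropna()
    vals = pli.to_numpy(float)
    if len(vals) and not np.all((vals >= 0) & (vals <= 1)):
        raise ValidationError("pLI values must lie in [0, 1]")
    clustered = sorted(clusters.assignments)
    with_pli = [g for g in clustered if g in pli.index]
    if not with_pli:
        raise DegenerateInputError("no clustered gene has a pLI value")
    high = {g for g in with_pli if pli.loc[g] > threshold}
    results: dict[str, FisherResult] = {}
    for cid in clusters.cluster_ids:
        members = set(clusters.members(cid)) & set(with_pli)
        others = set(with_pli) - members
        a = len(members & high)
        b = len(members - high)
        c = len(others & high)
        d = len(others - high)
        results[cid] = _fisher_from_table(np.array([[a, b], [c, d]]))
    return results
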