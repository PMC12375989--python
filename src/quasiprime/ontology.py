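"""GO term clustering by Wang semantic similarity.

Terms significant in the cross-species meta-analysis are clustered per
namespace (BP/MF/CC) with average-linkage hierarchical clustering on the
distance 1 − Wang similarity, cut at namespace-specific thresholds
(BP 0.54, MF 0.535, CC 0.52). Each cluster gets a representative term (best
adjusted p, ties broken by presence percentage, combined LOR, then term id)
and a winsorized inverse-variance weighted average LOR.

Wang similarity propagates an S-value from each term up its ancestor graph,
multiplying by an edge-type factor (is_a 0.8, part_of 0.6) and taking the max
over paths; similarity of two terms is the sum of both terms' S-values over
their shared ancestors, normalized by the two total S-value sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["OntologyGraph", "TermStats", "ClusterReport", "load_obo",
           "wang_similarity", "cluster_terms", "select_representative",
           "winsorized_weighted_lor", "NAMESPACE_THRESHOLDS", "WANG_WEIGHTS"]

#: Edge-type semantic contribution factors for Wang similarity.
WANG_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

#: Distance cutoffs (on 1 − similarity) for average-linkage clustering.
NAMESPACE_THRESHOLDS: dict[str, float] = {"BP": 0.54, "MF": 0.535, "CC": 0.52}

_NAMESPACE_CODES = {
    "biological_process": "BP", "molecular_function": "MF",
    "cellular_component": "CC", "BP": "BP", "MF": "MF", "CC": "CC",
}


@dataclass
class OntologyGraph:
    """Directed acyclic term graph; edges point child -> parent with a relation type."""

    graph: nx.DiGraph
    namespaces: dict[str, str]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.graph


def load_obo(path: str) -> OntologyGraph:
    """Read an OBO 1.4 ontology keeping is_a and part_of edges."""
    multigraph = obonet.read_obo(path)
    graph = nx.DiGraph()
    namespaces: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        graph.add_node(term)
        ns = data.get("namespace", "")
        namespaces[term] = _NAMESPACE_CODES.get(ns, ns)
    for child, parent, relation in multigraph.edges(keys=True):
        if relation in WANG_WEIGHTS:
            graph.add_edge(child, parent, relation=relation)
    return OntologyGraph(graph=graph, namespaces=namespaces)


def build_ontology(edges: Sequence[tuple[str, str, str]],
                   namespaces: Mapping[str, str]) -> OntologyGraph:
    """Construct an OntologyGraph from (child, parent, relation) triples."""
    graph = nx.DiGraph()
    for term in namespaces:
        graph.add_node(term)
    for child, parent, relation in edges:
        if relation not in WANG_WEIGHTS:
            raise ValueError(f"unsupported relation {relation!r}")
        graph.add_edge(child, parent, relation=relation)
    return OntologyGraph(graph=graph, namespaces=dict(namespaces))


def _s_values(term: str, ontology: OntologyGraph,
              weights: Mapping[str, float]) -> dict[str, float]:
    """Max-over-paths semantic contribution of each ancestor of ``term``."""
    graph = ontology.graph
    s: dict[str, float] = {term: 1.0}
    # Relax edges outward from the term; the ancestor subgraph is a DAG so a
    # worklist converges (each relaxation only increases values, bounded by 1).
    work = [term]
    while work:
        node = work.pop()
        base = s[node]
        for _, parent, data in graph.out_edges(node, data=True):
            cand = weights[data["relation"]] * base
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                work.append(parent)
    return s


def wang_similarity(
    t1: str,
    t2: str,
    ontology: OntologyGraph,
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Wang semantic similarity of two terms in the same namespace, in (0, 1]."""
    for t in (t1, t2):
        if t not in ontology:
            raise ValueError(f"unknown term {t!r}")
    if ontology.namespaces.get(t1) != ontology.namespaces.get(t2):
        raise ValueError(f"terms {t1!r} and {t2!r} are in different namespaces")
    s1 = _s_values(t1, ontology, weights)
    s2 = _s_values(t2, ontology, weights)
    common = set(s1) & set(s2)
    numerator = sum(s1[t] + s2[t] for t in common)
    return numerator / (sum(s1.values()) + sum(s2.values()))


@dataclass(frozen=True)
class TermStats:
    """Meta-analysis summary carried into clustering for one GO term."""

    term_id: str
    p_adjusted: float
    presence: float      # % of the taxon's species where the term was enriched
    combined_lor: float
    se_combined: float


@dataclass(frozen=True)
class ClusterReport:
    cluster_id: int
    members: tuple[str, ...]
    representative: str
    weighted_lor: float
    member_count: int


def select_representative(members: Sequence[TermStats]) -> str:
    """Best adjusted p; ties by presence desc, combined LOR desc, term id asc."""
    if not members:
        raise ValueError("empty cluster")
    best = min(members, key=lambda t: (t.p_adjusted, -t.presence,
                                       -t.combined_lor, t.term_id))
    return best.term_id


def winsorized_weighted_lor(
    lors: Sequence[float],
    ses: Sequence[float],
    pct: float = 95.0,
) -> float:
    """Inverse-variance weighted mean LOR after upper-tail winsorization.

    Values above the ``pct`` percentile (linear interpolation) of the member
    LORs are clamped to that percentile before weighting by 1/SE².
    """
    lors = np.asarray(lors, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if lors.shape != ses.shape or lors.size == 0:
        raise ValueError("lors and ses must be equal-length and non-empty")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    cap = np.percentile(lors, pct)
    clamped = np.minimum(lors, cap)
    weights = 1.0 / ses**2
    return float((weights * clamped).sum() / weights.sum())


def cluster_terms(
    terms: Sequence[TermStats],
    ontology: OntologyGraph,
    namespace: str,
    threshold: float | None = None,
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> list[ClusterReport]:
    """Average-linkage clustering of terms on 1 − Wang similarity.

    The dendrogram is cut at the namespace threshold (a distance cutoff);
    singleton clusters are retained only when the member's adjusted p < 0.05.
    The distance matrix is computed over sorted term ids, so the result is
    independent of input order.
    """
    if not terms:
        raise ValueError("no terms to cluster")
    for t in terms:
        if ontology.namespaces.get(t.term_id) != namespace:
            raise ValueError(f"term {t.term_id!r} not in namespace {namespace!r}")
    if threshold is None:
        threshold = NAMESPACE_THRESHOLDS[namespace]
    stats_by_id = {t.term_id: t for t in terms}
    ids = sorted(stats_by_id)
    if len(ids) == 1:
        labels = np.array([1])
    else:
        n = len(ids)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = 1.0 - wang_similarity(
                    ids[i], ids[j], ontology, weights)
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(tree, t=threshold, criterion="distance")
    reports = []
    for cluster_id in sorted(set(labels)):
        member_ids = [ids[i] for i in np.flatnonzero(labels == cluster_id)]
        members = [stats_by_id[m] for m in member_ids]
        if len(members) == 1 and not members[0].p_adjusted < 0.05:
            continue
        reports.append(ClusterReport(
            cluster_id=int(cluster_id),
            members=tuple(member_ids),
            representative=select_representative(members),
            weighted_lor=winsorized_weighted_lor(
                [m.combined_lor for m in members],
                [m.se_combined for m in members]),
            member_count=len(members),
        ))
    return reports
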