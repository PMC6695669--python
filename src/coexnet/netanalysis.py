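"""Community structure, centrality, enrichment and cross-disease similarity.

The thresholded consensus network is partitioned by modularity
maximization; each community ("cluster") is then characterized
functionally by hypergeometric over-representation of annotated gene sets,
and two diseases are compared by the Jaccard index between the significant
function sets of their clusters.  A low cross-disease Jaccard matrix means
the diseases' co-expression modules engage different biology even if a few
individual genes are shared.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_community
from scipy.stats import hypergeom

from .datatypes import GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

# graphs up to this size are partitioned by exhaustive search (exact optimum)
_EXACT_NODES = 8


class NetworkAnalysisError(ValueError):
    pass


@dataclass
class Partition:
    """Disjoint communities covering all graph nodes, with their modularity."""

    communities: list[set[str]]
    modularity: float

    def membership(self) -> dict[str, int]:
        return {n: i for i, c in enumerate(self.communities) for n in c}

    @property
    def n_communities(self) -> int:
        return len(self.communities)


@dataclass
class EnrichmentRow:
    cluster: int
    gene_set: str
    overlap: int       # k
    set_size: int      # K
    cluster_size: int  # n
    universe_size: int # N
    p_value: float
    adj_p_value: float


@dataclass
class SimilarityMatrix:
    """Pairwise Jaccard similarity between cluster function sets.

    `undefined` flags pairs where both clusters have no significant
    function; their Jaccard is reported as 0 rather than NaN.
    """

    labels: list[str]
    values: np.ndarray
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]


def modularity(graph: nx.Graph, communities: list[set[str]], resolution: float = 1.0) -> float:
    """Newman-Girvan weighted modularity of a partition."""
    if graph.number_of_nodes() == 0:
        raise NetworkAnalysisError("empty graph")
    if graph.number_of_edges() == 0:
        raise NetworkAnalysisError("modularity undefined for a graph with no edges")
    return float(nx_community.modularity(graph, communities, weight="weight", resolution=resolution))


def _canonicalize(communities: list[set[str]]) -> list[set[str]]:
    # stable labels: descending size, then lexicographic minimum member
    return sorted(communities, key=lambda c: (-len(c), min(c)))


def _partitions(items: list[str]):
    """All set partitions of `items` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


def detect_communities(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Modularity-maximizing partition of a weighted graph.

    Small graphs (<= 8 nodes) are solved exactly by enumerating all set
    partitions; larger graphs use seeded Louvain.  Community labels are
    canonicalized (descending size, then smallest member) so runs are
    comparable.
    """
    if graph.number_of_nodes() == 0:
        raise NetworkAnalysisError("empty graph")
    if graph.number_of_edges() == 0:
        raise NetworkAnalysisError("cannot partition a graph with no edges")
    if graph.number_of_nodes() <= _EXACT_NODES:
        nodes = sorted(graph.nodes)
        best, best_q = None, -np.inf
        for part in _partitions(nodes):
            q = nx_community.modularity(graph, part, weight="weight", resolution=resolution)
            if q > best_q + 1e-15:
                best, best_q = [set(c) for c in part], q
        comms = best
    else:
        comms = [set(c) for c in nx_community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed)]
    comms = _canonicalize(comms)
    q = modularity(graph, comms, resolution=resolution)
    return Partition(communities=comms, modularity=q)


def pagerank_centrality(graph: nx.Graph, damping: float = 0.85) -> dict[str, float]:
    """Damped random-walk stationary importance; values sum to 1."""
    if graph.number_of_nodes() == 0:
        raise NetworkAnalysisError("empty graph")
    if not 0.0 < damping < 1.0:
        raise NetworkAnalysisError(f"damping must be in (0, 1), got {damping}")
    try:
        pr = nx.pagerank(graph, alpha=damping, weight="weight", tol=1e-10, max_iter=10_000)
    except nx.PowerIterationFailedConvergence as err:  # pragma: no cover
        raise NetworkAnalysisError("PageRank power iteration did not converge") from err
    return {n: float(v) for n, v in pr.items()}


def enrich_cluster(
    cluster_genes: set[str],
    gene_sets: GeneSetCollection,
    universe: set[str],
    cluster_index: int = 0,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each gene set in one cluster.

    One-sided tail P(X >= k) with population = `universe` (the genes that
    entered network inference), then BH across gene sets within the
    cluster.  Gene-set members outside the universe are ignored.
    """
    if not universe:
        raise NetworkAnalysisError("empty universe")
    extra = cluster_genes - universe
    if extra:
        raise NetworkAnalysisError(f"cluster genes outside universe: {sorted(extra)[:5]}")
    n_univ = len(universe)
    n_clu = len(cluster_genes)
    rows: list[EnrichmentRow] = []
    for name in gene_sets.names():
        members = set(gene_sets.members(name)) & universe
        k = len(cluster_genes & members)
        p = float(hypergeom.sf(k - 1, n_univ, len(members), n_clu)) if members else 1.0
        rows.append(EnrichmentRow(cluster_index, name, k, len(members), n_clu, n_univ, min(p, 1.0), 1.0))
    if rows:
        adj = bh_adjust([r.p_value for r in rows])
        for r, a in zip(rows, adj):
            r.adj_p_value = float(a)
    return rows


def cluster_functions(
    partition: Partition,
    gene_sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentRow], dict[int, set[str]]]:
    """Enrich every cluster; a cluster's functions are sets with BH adj_p < alpha."""
    all_rows: list[EnrichmentRow] = []
    functions: dict[int, set[str]] = {}
    for idx, genes in enumerate(partition.communities):
        rows = enrich_cluster(set(genes), gene_sets, universe, cluster_index=idx)
        all_rows.extend(rows)
        functions[idx] = {r.gene_set for r in rows if r.adj_p_value < alpha}
    return all_rows, functions


def jaccard(a: set[str], b: set[str]) -> tuple[float, bool]:
    """Jaccard index and an undefined flag (both sets empty -> (0, True))."""
    union = a | b
    if not union:
        return 0.0, True
    return len(a & b) / len(union), False


def jaccard_similarity_matrix(
    functions_a: dict[int, set[str]],
    functions_b: dict[int, set[str]],
    prefix_a: str = "A",
    prefix_b: str = "B",
) -> SimilarityMatrix:
    """Full Jaccard matrix over the clusters of two diseases.

    Clusters are laid out A-first then B (labels carry the disease of
    origin), so the off-diagonal block holds the cross-disease entries.
    """
    labels = [f"{prefix_a}{i}" for i in sorted(functions_a)] + [
        f"{prefix_b}{j}" for j in sorted(functions_b)]
    sets = [functions_a[i] for i in sorted(functions_a)] + [
        functions_b[j] for j in sorted(functions_b)]
    n = len(sets)
    values = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    for i, j in itertools.product(range(n), range(n)):
        values[i, j], undefined[i, j] = jaccard(sets[i], sets[j])
    return SimilarityMatrix(labels=labels, values=values, undefined=undefined)


def module_recovery_ari(module_of: dict[str, int], partition: Partition) -> float:
    """Adjusted Rand index between planted modules and detected communities.

    Scored over the planted module genes (module index >= 0).  A module
    gene absent from the partition (dropped as isolated at thresholding)
    gets its own singleton label, penalizing failures to cluster it;
    background genes are not part of the planted structure and are
    ignored.
    """
    from sklearn.metrics import adjusted_rand_score

    membership = partition.membership()
    genes = sorted(g for g, m in module_of.items() if m >= 0)
    if not genes:
        raise NetworkAnalysisError("no planted module genes to score")
    true_labels = [module_of[g] for g in genes]
    next_free = -1
    pred_labels = []
    for g in genes:
        if g in membership:
            pred_labels.append(membership[g])
        else:
            pred_labels.append(next_free)
            next_free -= 1
    return float(adjusted_rand_score(true_labels, pred_labels))


@dataclass
class DiseaseComparison:
    similarity: SimilarityMatrix
    n_clusters_a: int
    n_clusters_b: int
    cross_max: float
    cross_mean: float


def compare_diseases(
    functions_a: dict[int, set[str]],
    functions_b: dict[int, set[str]],
    prefix_a: str = "A",
    prefix_b: str = "B",
) -> DiseaseComparison:
    """Cross-disease functional-similarity summary (max and mean Jaccard)."""
    if not functions_a or not functions_b:
        raise NetworkAnalysisError("each disease needs at least one cluster")
    sim = jaccard_similarity_matrix(functions_a, functions_b, prefix_a, prefix_b)
    na, nb = len(functions_a), len(functions_b)
    cross = sim.values[:na, na:]
    return DiseaseComparison(
        similarity=sim,
        n_clusters_a=na,
        n_clusters_b=nb,
        cross_max=float(cross.max()),
        cross_mean=float(cross.mean()),
    )
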