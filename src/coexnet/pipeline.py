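"""End-to-end orchestration: DE -> gene selection -> inference -> consensus
-> threshold -> communities -> enrichment.

A pipeline run is a pure function of (inputs, config, seed); every stage
logs its parameters and the bundle carries all intermediate artifacts so
two diseases can be compared afterwards with
:func:`coexnet.netanalysis.compare_diseases`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import diffexpr, inference, netanalysis
from .config import AnalysisConfig
from .datatypes import ExpressionMatrix, GeneSetCollection, SampleGroups
from .overlap import NamedEntityList

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.__cause__ = err


@dataclass
class PipelineResult:
    config: AnalysisConfig
    de_results: list[diffexpr.DEResult]
    selected_genes: list[str]
    method_scores: dict[str, inference.MethodScoreMatrix]
    consensus: inference.ConsensusNetwork
    graph: nx.Graph
    partition: netanalysis.Partition
    pagerank: dict[str, float]
    enrichment: list[netanalysis.EnrichmentRow] = field(default_factory=list)
    cluster_functions: dict[int, set[str]] = field(default_factory=dict)

    def cluster_gene_map(self) -> dict[int, set[str]]:
        return {i: set(c) for i, c in enumerate(self.partition.communities)}


def run_pipeline(
    config: AnalysisConfig,
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    gene_sets: GeneSetCollection | None = None,
    curated_gwas: NamedEntityList | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on one disease dataset and return the result bundle."""

    def stage(name: str, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(name, err) from err

    logger.info(
        "pipeline: %d genes x %d samples, cutoff=%.3f alpha=%.3g bins=%s trees=%d seed=%d res=%.3g",
        matrix.n_genes, matrix.n_samples, config.consensus_cutoff, config.de_alpha,
        config.mi_bins, config.ensemble_trees, config.seed, config.community_resolution,
    )
    de_results = stage("diffexpr", diffexpr.moderated_t_test, matrix, groups)
    selected = stage(
        "gene_selection", diffexpr.select_network_genes,
        de_results, curated_gwas, matrix.gene_ids,
        alpha=config.de_alpha, use_adjusted=config.de_use_adjusted,
    )
    sub = matrix.subset_genes(selected)
    method_scores = stage(
        "inference", inference.infer_all, sub,
        mi_bins=config.mi_bins, n_trees=config.ensemble_trees, seed=config.seed,
    )
    consensus = stage(
        "consensus", inference.consensus_aggregate,
        [method_scores[m] for m in inference.METHODS],
    )
    graph = stage("threshold", inference.threshold_network, consensus, config.consensus_cutoff)
    partition = stage(
        "communities", netanalysis.detect_communities, graph,
        resolution=config.community_resolution, seed=config.seed,
    )
    pagerank = stage("pagerank", netanalysis.pagerank_centrality, graph)

    enrichment: list[netanalysis.EnrichmentRow] = []
    functions: dict[int, set[str]] = {}
    if gene_sets is not None and len(gene_sets) > 0:
        enrichment, functions = stage(
            "enrichment", netanalysis.cluster_functions,
            partition, gene_sets, set(selected), alpha=config.de_alpha,
        )

    result = PipelineResult(
        config=config, de_results=de_results, selected_genes=selected,
        method_scores=method_scores, consensus=consensus, graph=graph,
        partition=partition, pagerank=pagerank,
        enrichment=enrichment, cluster_functions=functions,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    import pandas as pd

    from .io import write_edge_table

    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_json(out_dir / "config.json")
    pd.DataFrame([vars(r) for r in result.de_results]).sort_values("p_value").to_csv(
        out_dir / "de_results.tsv", sep="\t", index=False, float_format="%.12g")
    (out_dir / "selected_genes.txt").write_text("\n".join(result.selected_genes) + "\n")
    write_edge_table(result.consensus, out_dir / "edges.tsv", result.method_scores)
    membership = result.partition.membership()
    pd.DataFrame(
        {"gene_id": list(membership), "community": list(membership.values()),
         "pagerank": [result.pagerank[g] for g in membership]}
    ).to_csv(out_dir / "communities.tsv", sep="\t", index=False, float_format="%.12g")
    if result.enrichment:
        pd.DataFrame([vars(r) for r in result.enrichment]).to_csv(
            out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.12g")
    logger.info("bundle written to %s (Q=%.4f, %d communities)",
                out_dir, result.partition.modularity, result.partition.n_communities)
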