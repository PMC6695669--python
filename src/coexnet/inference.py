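"""Co-expression scoring algorithms and wisdom-of-crowds consensus.

Six complementary dependence measures are computed between every pair of
gene expression profiles:

* absolute Pearson and Spearman correlation;
* distance correlation (double-centered pairwise-distance matrices), which
  detects non-monotone dependence;
* two mutual-information network methods sharing one plug-in MI estimator
  on equal-frequency bins: CLR (per-gene background z-scores of MI) and
  MRNETB (max-relevance min-redundancy with backward elimination);
* a GENIE3-style tree-ensemble score: each gene is regressed on all others
  with a randomized ensemble and predictor importances become directed
  edge scores, symmetrized by max.

No single method wins on all data, so the per-method edge scores are made
commensurable by rank normalization to [0, 1] and averaged (a Borda-style
consensus).  Thresholding the consensus yields the high-confidence
undirected weighted graph passed to community detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesRegressor

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "dcor", "clr", "mrnetb", "genie3")


class InferenceError(ValueError):
    pass


@dataclass
class MethodScoreMatrix:
    """Symmetric nonnegative edge scores from one inference method."""

    method: str
    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if not np.allclose(s, s.T, atol=1e-12, rtol=1e-10, equal_nan=False):
            raise InferenceError(f"{self.method}: score matrix not symmetric")
        s = (s + s.T) / 2.0  # remove float-level asymmetry from BLAS products
        if not np.all(np.isfinite(s)):
            raise InferenceError(f"{self.method}: non-finite scores")
        if np.any(np.diag(s) != 0):
            raise InferenceError(f"{self.method}: nonzero diagonal")
        if np.any(s < 0):
            raise InferenceError(f"{self.method}: negative scores")
        self.scores = s


@dataclass
class ConsensusNetwork:
    """Rank-aggregated consensus over the per-method score matrices."""

    gene_ids: list[str]
    consensus: np.ndarray
    n_contributing: np.ndarray  # per edge: methods with a strictly positive raw score

    def __post_init__(self) -> None:
        c = np.asarray(self.consensus, dtype=float)
        if np.any(c < 0) or np.any(c > 1):
            raise InferenceError("consensus entries must lie in [0, 1]")
        if not np.array_equal(c, c.T):
            raise InferenceError("consensus matrix not symmetric")
        self.consensus = c


def _zero_diag(m: np.ndarray) -> np.ndarray:
    np.fill_diagonal(m, 0.0)
    return m


def _constant_rows(values: np.ndarray) -> np.ndarray:
    return np.ptp(values, axis=1) == 0


def _corr_abs(values: np.ndarray, method: str) -> np.ndarray:
    const = _constant_rows(values)
    if const.any():
        logger.warning("%s: %d constant gene(s) scored 0 against all others", method, const.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(np.corrcoef(values))
    c = np.nan_to_num(c, nan=0.0)
    c[const, :] = 0.0
    c[:, const] = 0.0
    return _zero_diag(np.clip(c, 0.0, 1.0))


def pearson_scores(matrix: ExpressionMatrix) -> MethodScoreMatrix:
    """Absolute Pearson correlation between all gene pairs."""
    if matrix.n_samples < 3:
        raise InferenceError("pearson requires >= 3 samples")
    return MethodScoreMatrix("pearson", list(matrix.gene_ids), _corr_abs(matrix.values, "pearson"))


def spearman_scores(matrix: ExpressionMatrix) -> MethodScoreMatrix:
    """Absolute Spearman (rank) correlation between all gene pairs."""
    if matrix.n_samples < 3:
        raise InferenceError("spearman requires >= 3 samples")
    ranks = np.apply_along_axis(rankdata, 1, matrix.values)
    const = _constant_rows(matrix.values)
    scores = _corr_abs(ranks, "spearman")
    scores[const, :] = 0.0
    scores[:, const] = 0.0
    return MethodScoreMatrix("spearman", list(matrix.gene_ids), scores)


def dcor_scores(matrix: ExpressionMatrix) -> MethodScoreMatrix:
    """Distance correlation between all gene pairs.

    For each gene the n x n matrix of absolute sample differences is
    double-centered; dCor(i,j) is the normalized inner product of the two
    centered matrices.  A constant gene has zero distance variance and is
    scored 0 by convention.
    """
    if matrix.n_samples < 4:
        raise InferenceError("distance correlation requires >= 4 samples")
    x = matrix.values
    p, n = x.shape
    flat = np.empty((p, n * n))
    for i in range(p):
        d = np.abs(x[i][:, None] - x[i][None, :])
        d -= d.mean(axis=0, keepdims=True)
        d -= d.mean(axis=1, keepdims=True)
        flat[i] = d.ravel()
    gram = flat @ flat.T / (n * n)  # dCov^2
    v = np.diag(gram).copy()
    denom = np.sqrt(np.outer(v, v))
    with np.errstate(invalid="ignore", divide="ignore"):
        dcor2 = np.where(denom > 0, gram / denom, 0.0)
    scores = np.sqrt(np.clip(dcor2, 0.0, 1.0))
    return MethodScoreMatrix("dcor", list(matrix.gene_ids), _zero_diag(scores))


# ---------------------------------------------------------------------------
# mutual information kernel and the two MI-based methods

def discretize_equal_frequency(values: np.ndarray, bins: int) -> np.ndarray:
    """Assign each sample of each gene to one of `bins` equal-frequency bins."""
    n = values.shape[1]
    # rank-based binning: ties broken by original order for determinism
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return (ranks * bins) // n


def mutual_information_matrix(matrix: ExpressionMatrix, bins: int | str = "auto") -> np.ndarray:
    """Plug-in mutual information (nats) between all gene pairs.

    Profiles are discretized into equal-frequency bins (auto: ceil(sqrt(n))
    bins) and MI is the maximum-likelihood estimate on the joint histogram.
    """
    if matrix.n_samples < 8:
        raise InferenceError("mutual information requires >= 8 samples")
    if bins == "auto":
        bins = int(np.ceil(np.sqrt(matrix.n_samples)))
    bins = int(bins)
    if bins < 2:
        raise InferenceError(f"bins must be >= 2, got {bins}")
    disc = discretize_equal_frequency(matrix.values, bins)
    p, n = disc.shape
    mi = np.zeros((p, p))
    # marginal entropies
    marg = np.zeros((p, bins))
    for i in range(p):
        marg[i] = np.bincount(disc[i], minlength=bins) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(marg > 0, marg * np.log(marg), 0.0).sum(axis=1)
    for i in range(p):
        joint_codes = disc[i] * bins
        for j in range(i, p):
            counts = np.bincount(joint_codes + disc[j], minlength=bins * bins) / n
            nz = counts[counts > 0]
            h_joint = -(nz * np.log(nz)).sum()
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - h_joint, 0.0)
    return mi


def clr_scores(mi: np.ndarray, gene_ids: list[str]) -> MethodScoreMatrix:
    """Context likelihood of relatedness from an MI matrix.

    Each MI value is z-scored against the background MI distribution of
    both genes (off-diagonal mean and sd per row, z clipped at 0); the edge
    score is sqrt(z_i^2 + z_j^2).  A zero-sd background yields z = 0.
    """
    p = mi.shape[0]
    if p < 3:
        raise InferenceError("CLR requires >= 3 genes (background undefined)")
    off = mi.copy()
    np.fill_diagonal(off, np.nan)
    mu = np.nanmean(off, axis=1)
    sd = np.nanstd(off, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mi - mu[:, None]) / sd[:, None]
    z = np.where(sd[:, None] > 0, z, 0.0)
    z = np.clip(z, 0.0, None)
    scores = np.sqrt(z**2 + z.T**2)
    return MethodScoreMatrix("clr", list(gene_ids), _zero_diag(scores))


def _mrnetb_target(mi: np.ndarray, target: int) -> np.ndarray:
    """MRNETB neighbor scores of one target; returns a length-p vector."""
    p = mi.shape[0]
    candidates = [j for j in range(p) if j != target]
    u = mi[:, target]  # relevance

    def objective(j: int, selected: set[int]) -> float:
        others = [k for k in selected if k != j]
        red = float(np.mean(mi[j, others])) if others else 0.0
        return float(u[j]) - red

    selected = set(candidates)
    removed: list[int] = []
    while len(selected) > 1:
        objs = {j: objective(j, selected) for j in selected}
        j_min = min(objs, key=lambda j: (objs[j], j))
        if objs[j_min] >= 0:
            break
        selected.remove(j_min)
        removed.append(j_min)
    # single forward-swap refinement pass
    for r in removed:
        o_r = objective(r, selected | {r})
        objs = {s: objective(s, selected) for s in selected}
        s_min = min(objs, key=lambda s: (objs[s], s))
        if o_r > objs[s_min]:
            selected.remove(s_min)
            selected.add(r)
    scores = np.zeros(p)
    for j in selected:
        scores[j] = max(objective(j, selected), 0.0)
    return scores


def mrnetb_scores(mi: np.ndarray, gene_ids: list[str]) -> MethodScoreMatrix:
    """Max-relevance min-redundancy (backward variant) from an MI matrix.

    Per target, the neighbor set starts from all candidates; the candidate
    with the worst relevance-minus-mean-redundancy objective is eliminated
    while that objective is negative, followed by a single forward-swap
    refinement pass.  Edge score is the final objective, clipped at 0, and
    the directed scores are symmetrized by max.
    """
    p = mi.shape[0]
    if p < 3:
        raise InferenceError("MRNETB requires >= 3 genes")
    directed = np.zeros((p, p))
    for t in range(p):
        directed[:, t] = _mrnetb_target(mi, t)
    scores = np.maximum(directed, directed.T)
    return MethodScoreMatrix("mrnetb", list(gene_ids), _zero_diag(scores))


def genie3_scores(matrix: ExpressionMatrix, n_trees: int = 100, seed: int = 0) -> MethodScoreMatrix:
    """Tree-ensemble regression importances as edge scores.

    Each gene is regressed on all other genes with an extremely randomized
    tree ensemble (candidate features per split: sqrt of the predictor
    count); impurity-reduction importances, normalized to sum 1 per target,
    score the directed edges, which are symmetrized by max.  A constant
    target contributes a zero row.
    """
    if matrix.n_samples < 10:
        raise InferenceError("tree-ensemble inference requires >= 10 samples")
    x = matrix.values
    p = matrix.n_genes
    directed = np.zeros((p, p))  # [predictor, target]
    const = _constant_rows(x)
    for t in range(p):
        if const[t]:
            continue
        predictors = np.delete(np.arange(p), t)
        model = ExtraTreesRegressor(
            n_estimators=int(n_trees),
            max_features="sqrt",
            random_state=(seed + 7919 * t) % (2**31 - 1),
            n_jobs=1,
        )
        model.fit(x[predictors].T, x[t])
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        directed[predictors, t] = imp
    scores = np.maximum(directed, directed.T)
    return MethodScoreMatrix("genie3", list(matrix.gene_ids), _zero_diag(scores))


# ---------------------------------------------------------------------------
# aggregation

def _triu_indices(p: int):
    return np.triu_indices(p, k=1)


def rank_normalize(score_matrix: MethodScoreMatrix) -> np.ndarray:
    """Map edge scores to [0, 1] by descending rank (ties share average rank).

    The best edge maps to 1, the worst to 0; a single edge maps to 1.
    Invariant under strictly monotone transforms of the raw scores.
    """
    p = len(score_matrix.gene_ids)
    iu = _triu_indices(p)
    edges = score_matrix.scores[iu]
    n_edges = edges.size
    if n_edges < 1:
        raise InferenceError("rank normalization needs at least one edge")
    if n_edges == 1:
        normed = np.ones(1)
    else:
        ranks = rankdata(-edges, method="average")
        normed = 1.0 - (ranks - 1.0) / (n_edges - 1.0)
    out = np.zeros((p, p))
    out[iu] = normed
    return out + out.T


def consensus_aggregate(score_matrices: list[MethodScoreMatrix]) -> ConsensusNetwork:
    """Average the rank-normalized edge scores of several methods."""
    if not score_matrices:
        raise InferenceError("no score matrices to aggregate")
    universe = score_matrices[0].gene_ids
    for m in score_matrices[1:]:
        if m.gene_ids != universe:
            diff = set(m.gene_ids) ^ set(universe)
            raise InferenceError(f"gene universe mismatch across methods: {sorted(diff)[:10]}")
    normed = [rank_normalize(m) for m in score_matrices]
    consensus = np.mean(normed, axis=0)
    n_contrib = np.sum([m.scores > 0 for m in score_matrices], axis=0)
    return ConsensusNetwork(list(universe), consensus, n_contrib)


def infer_all(
    matrix: ExpressionMatrix,
    mi_bins: int | str = "auto",
    n_trees: int = 100,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, MethodScoreMatrix]:
    """Run the requested inference methods; returns method -> score matrix."""
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise InferenceError(f"unknown methods: {sorted(unknown)}")
    out: dict[str, MethodScoreMatrix] = {}
    mi = None
    if {"clr", "mrnetb"} & set(methods):
        mi = mutual_information_matrix(matrix, bins=mi_bins)
    for m in methods:
        logger.info("inference method %s on %d genes x %d samples", m, matrix.n_genes, matrix.n_samples)
        if m == "pearson":
            out[m] = pearson_scores(matrix)
        elif m == "spearman":
            out[m] = spearman_scores(matrix)
        elif m == "dcor":
            out[m] = dcor_scores(matrix)
        elif m == "clr":
            out[m] = clr_scores(mi, list(matrix.gene_ids))
        elif m == "mrnetb":
            out[m] = mrnetb_scores(mi, list(matrix.gene_ids))
        elif m == "genie3":
            out[m] = genie3_scores(matrix, n_trees=n_trees, seed=seed)
    return out


def threshold_network(network: ConsensusNetwork, cutoff: float) -> nx.Graph:
    """Keep edges with consensus >= cutoff as an undirected weighted graph.

    Genes left without any retained edge are dropped from the graph (and
    logged); an entirely empty graph is an error suggesting a lower cutoff.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise InferenceError(f"cutoff must be in [0, 1], got {cutoff}")
    p = len(network.gene_ids)
    iu = _triu_indices(p)
    keep = network.consensus[iu] >= cutoff
    graph = nx.Graph()
    for i, j, w in zip(iu[0][keep], iu[1][keep], network.consensus[iu][keep]):
        graph.add_edge(network.gene_ids[i], network.gene_ids[j], weight=float(w))
    if graph.number_of_edges() == 0:
        raise InferenceError(
            f"no edges with consensus >= {cutoff}; lower the cutoff "
            f"(max consensus = {network.consensus[iu].max():.4f})"
        )
    isolated = set(network.gene_ids) - set(graph.nodes)
    if isolated:
        logger.info("threshold %.3f dropped %d isolated gene(s)", cutoff, len(isolated))
    return graph
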