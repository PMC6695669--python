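"""Six scoring methods, rank aggregation and thresholding.

CLR and MRNETB are checked against naive loop-based re-computations of
their definitions; distance correlation against an explicit
double-centering oracle; consensus against direct averaging.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from coexnet.datatypes import ExpressionMatrix
from coexnet.inference import (
    METHODS,
    InferenceError,
    MethodScoreMatrix,
    clr_scores,
    consensus_aggregate,
    dcor_scores,
    genie3_scores,
    infer_all,
    mrnetb_scores,
    mutual_information_matrix,
    pearson_scores,
    rank_normalize,
    spearman_scores,
    threshold_network,
)


def _matrix(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"S{j}" for j in range(values.shape[1])], values)


# ---------------------------------------------------------------------------
# correlation methods

class TestCorrelationScores:
    def test_perfect_linear_dependence(self, rng):
        x = rng.standard_normal(20)
        m = _matrix([x, 2 * x, rng.standard_normal(20)])
        s = pearson_scores(m).scores
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] < 1.0

    def test_monotone_transform_spearman_one_pearson_below(self, rng):
        x = np.sort(rng.standard_normal(50))
        m = _matrix([x, x**3])
        assert spearman_scores(m).scores[0, 1] == pytest.approx(1.0)
        assert pearson_scores(m).scores[0, 1] < 1.0

    def test_matches_direct_formula(self, rng):
        vals = rng.standard_normal((4, 25))
        s = pearson_scores(_matrix(vals)).scores
        for i, j in itertools.combinations(range(4), 2):
            xi, xj = vals[i] - vals[i].mean(), vals[j] - vals[j].mean()
            r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert s[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_gene_scored_zero(self, rng):
        vals = rng.standard_normal((3, 20))
        vals[1] = 5.0
        for fn in (pearson_scores, spearman_scores):
            s = fn(_matrix(vals)).scores
            assert np.all(s[1] == 0) and np.all(s[:, 1] == 0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(InferenceError):
            pearson_scores(_matrix(rng.standard_normal((3, 2))))


class TestDistanceCorrelation:
    @staticmethod
    def _dcor_oracle(x, y):
        n = len(x)
        def centered(v):
            d = np.abs(v[:, None] - v[None, :])
            return d - d.mean(0) - d.mean(1)[:, None] + d.mean()
        a, b = centered(x), centered(y)
        dcov2 = (a * b).mean()
        dvar_x, dvar_y = (a * a).mean(), (b * b).mean()
        if dvar_x <= 0 or dvar_y <= 0:
            return 0.0
        return np.sqrt(dcov2 / np.sqrt(dvar_x * dvar_y))

    def test_self_dependence_is_one(self, rng):
        x = rng.standard_normal(30)
        m = _matrix([x, x.copy()])
        assert dcor_scores(m).scores[0, 1] == pytest.approx(1.0)

    def test_detects_symmetric_quadratic_dependence(self):
        rng = np.random.default_rng(2024)
        x = rng.uniform(-1, 1, 200)
        m = _matrix([x, x**2])
        assert dcor_scores(m).scores[0, 1] > 0.4
        assert pearson_scores(m).scores[0, 1] < 0.1

    def test_independent_normals_score_low(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.standard_normal((2, 500)))
        assert dcor_scores(m).scores[0, 1] < 0.15

    def test_matches_double_centering_oracle(self, rng):
        vals = rng.standard_normal((5, 40))
        s = dcor_scores(_matrix(vals)).scores
        for i, j in itertools.combinations(range(5), 2):
            assert s[i, j] == pytest.approx(self._dcor_oracle(vals[i], vals[j]), abs=1e-10)

    def test_constant_gene_zero_by_convention(self, rng):
        vals = rng.standard_normal((2, 30))
        vals[0] = 1.0
        assert dcor_scores(_matrix(vals)).scores[0, 1] == 0.0


# ---------------------------------------------------------------------------
# mutual information and the two MI-based methods

class TestMutualInformation:
    def test_self_mi_equals_log_bins_when_divisible(self, rng):
        vals = rng.standard_normal((2, 30))
        mi = mutual_information_matrix(_matrix(vals), bins=5)  # 30 divisible by 5
        assert mi[0, 0] == pytest.approx(np.log(5), abs=1e-12)
        assert mi[1, 1] == pytest.approx(np.log(5), abs=1e-12)

    def test_symmetry_exact(self, rng):
        mi = mutual_information_matrix(_matrix(rng.standard_normal((6, 64))))
        assert np.array_equal(mi, mi.T)

    def test_nonnegative(self, rng):
        mi = mutual_information_matrix(_matrix(rng.standard_normal((6, 50))), bins=4)
        assert np.all(mi >= 0)

    def test_independent_pairs_low_mi(self):
        """Null MI stays near the plug-in bias floor (B-1)^2/(2n), far below
        any real dependence signal."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.uniform(size=(2, 1000))
            mi = mutual_information_matrix(_matrix(vals), bins=4)
            hits += mi[0, 1] < 0.05
        assert hits >= 19  # >=95% of seeds

    def test_null_mi_tracks_plugin_bias_at_many_bins(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(2, 1000))
        mi = mutual_information_matrix(_matrix(vals), bins=31)
        bias = 30 * 30 / (2 * 1000)  # ML plug-in bias for independent pairs
        assert mi[0, 1] == pytest.approx(bias, rel=0.35)

    def test_bad_bins_rejected(self, rng):
        with pytest.raises(InferenceError):
            mutual_information_matrix(_matrix(rng.standard_normal((2, 20))), bins=1)


class TestCLR:
    @staticmethod
    def _clr_oracle(mi):
        p = mi.shape[0]
        z = np.zeros((p, p))
        for i in range(p):
            background = [mi[i, k] for k in range(p) if k != i]
            mu, sd = np.mean(background), np.std(background)
            for j in range(p):
                z[i, j] = max(0.0, (mi[i, j] - mu) / sd) if sd > 0 else 0.0
        out = np.sqrt(z**2 + z.T**2)
        np.fill_diagonal(out, 0.0)
        return out

    def test_flat_background_scores_zero(self):
        mi = np.full((4, 4), 0.3)
        np.fill_diagonal(mi, 1.0)
        s = clr_scores(mi, [f"G{i}" for i in range(4)]).scores
        assert np.all(s == 0)

    def test_matches_bruteforce_oracle(self, rng):
        mi = np.abs(rng.standard_normal((5, 5)))
        mi = (mi + mi.T) / 2
        s = clr_scores(mi, [f"G{i}" for i in range(5)]).scores
        assert s == pytest.approx(self._clr_oracle(mi), abs=1e-9)

    def test_planted_pair_top_ranked(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            vals = rng.standard_normal((6, 200))
            vals[1] = vals[0] + 0.3 * rng.standard_normal(200)
            mi = mutual_information_matrix(_matrix(vals))
            s = clr_scores(mi, [f"G{i}" for i in range(6)]).scores
            iu = np.triu_indices(6, 1)
            top = np.argmax(s[iu])
            hits += (iu[0][top], iu[1][top]) == (0, 1)
        assert hits >= 19

    def test_too_few_genes_rejected(self):
        with pytest.raises(InferenceError):
            clr_scores(np.zeros((2, 2)), ["A", "B"])


class TestMRNETB:
    @staticmethod
    def _oracle(mi):
        """Naive per-target re-execution of the published elimination rule."""
        p = mi.shape[0]
        directed = np.zeros((p, p))
        for t in range(p):
            u = mi[:, t]
            def obj(j, sel):
                others = [k for k in sel if k != j]
                return u[j] - (np.mean([mi[j, k] for k in others]) if others else 0.0)
            sel = set(range(p)) - {t}
            removed = []
            while len(sel) > 1:
                worst = min(sel, key=lambda j: (obj(j, sel), j))
                if obj(worst, sel) >= 0:
                    break
                sel.remove(worst); removed.append(worst)
            for r in removed:
                o_r = obj(r, sel | {r})
                worst = min(sel, key=lambda s: (obj(s, sel), s))
                if o_r > obj(worst, sel):
                    sel.remove(worst); sel.add(r)
            for j in sel:
                directed[j, t] = max(obj(j, sel), 0.0)
        return np.maximum(directed, directed.T)

    def test_two_candidates_reduce_to_relevance_order(self):
        # G0 targets: with only two candidates the redundancy term cancels
        mi = np.array([[1.0, 0.8, 0.2],
                       [0.8, 1.0, 0.1],
                       [0.2, 0.1, 1.0]])
        s = mrnetb_scores(mi, ["G0", "G1", "G2"]).scores
        assert s[0, 1] > s[0, 2]

    def test_dependent_pair_beats_noise(self, rng):
        vals = rng.standard_normal((3, 300))
        vals[1] = vals[0] + 0.2 * rng.standard_normal(300)
        mi = mutual_information_matrix(_matrix(vals))
        s = mrnetb_scores(mi, ["X", "Y", "Z"]).scores
        assert s[0, 1] > s[0, 2] and s[0, 1] > s[1, 2]

    @pytest.mark.parametrize("p", [3, 4, 5, 6])
    def test_matches_exhaustive_oracle(self, p):
        rng = np.random.default_rng(p)
        for _ in range(10):
            mi = np.abs(rng.standard_normal((p, p)))
            mi = (mi + mi.T) / 2
            np.fill_diagonal(mi, 0.0)
            s = mrnetb_scores(mi, [f"G{i}" for i in range(p)]).scores
            assert s == pytest.approx(self._oracle(mi), abs=1e-9)

    def test_symmetric_nonnegative(self, rng):
        mi = np.abs(rng.standard_normal((8, 8)))
        mi = (mi + mi.T) / 2
        s = mrnetb_scores(mi, [f"G{i}" for i in range(8)]).scores
        assert np.array_equal(s, s.T) and np.all(s >= 0)


class TestGenie3:
    def test_planted_regulator_has_top_importance(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            vals = rng.standard_normal((10, 80))
            vals[9] = vals[0] + 0.1 * rng.standard_normal(80)  # target = x0 + noise
            s = genie3_scores(_matrix(vals), n_trees=50, seed=seed).scores
            hits += np.argmax(s[9]) == 0
        assert hits >= 19

    def test_deterministic_for_fixed_seed(self, rng):
        m = _matrix(rng.standard_normal((5, 30)))
        s1 = genie3_scores(m, n_trees=20, seed=3).scores
        s2 = genie3_scores(m, n_trees=20, seed=3).scores
        assert np.array_equal(s1, s2)

    def test_constant_target_contributes_zero_row(self, rng):
        vals = rng.standard_normal((4, 30))
        vals[2] = 1.0
        s = genie3_scores(_matrix(vals), n_trees=20, seed=0)
        directed_into_2 = s.scores[2]  # after max-symmetrization other genes may still score
        assert np.all(np.isfinite(directed_into_2))


# ---------------------------------------------------------------------------
# aggregation

class TestRankNormalize:
    def _from_edges(self, edges):
        # 3-gene matrix with given (01, 02, 12) scores
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = edges[0]
        s[0, 2] = s[2, 0] = edges[1]
        s[1, 2] = s[2, 1] = edges[2]
        return MethodScoreMatrix("pearson", ["A", "B", "C"], s)

    def test_linear_rank_map(self):
        n = rank_normalize(self._from_edges([10, 5, 1]))
        assert (n[0, 1], n[0, 2], n[1, 2]) == pytest.approx((1.0, 0.5, 0.0))

    def test_full_tie_gives_half(self):
        n = rank_normalize(self._from_edges([3, 3, 3]))
        assert np.all(n[np.triu_indices(3, 1)] == pytest.approx(0.5))

    def test_invariant_under_monotone_transform(self, rng):
        vals = np.abs(rng.standard_normal(3)) + 0.1
        n1 = rank_normalize(self._from_edges(vals))
        n2 = rank_normalize(self._from_edges(np.exp(3 * vals)))
        assert n1 == pytest.approx(n2)


class TestConsensus:
    def test_unanimous_rankings_preserved(self, rng):
        vals = rng.standard_normal((4, 30))
        mats = [pearson_scores(_matrix(vals)) for _ in range(6)]
        cons = consensus_aggregate(mats)
        assert cons.consensus == pytest.approx(rank_normalize(mats[0]))

    def test_reversed_rankings_average_to_half(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 3.0
        s[0, 2] = s[2, 0] = 2.0
        s[1, 2] = s[2, 1] = 1.0
        a = MethodScoreMatrix("pearson", ["A", "B", "C"], s)
        b = MethodScoreMatrix("spearman", ["A", "B", "C"], 4.0 - s - 4.0 * np.eye(3))
        cons = consensus_aggregate([a, b])
        assert np.all(cons.consensus[np.triu_indices(3, 1)] == pytest.approx(0.5))

    def test_mean_of_normalized_scores(self, rng):
        mats = []
        for k in range(6):
            v = np.abs(rng.standard_normal((4, 4)))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(MethodScoreMatrix(METHODS[k], ["A", "B", "C", "D"], v))
        cons = consensus_aggregate(mats)
        direct = np.mean([rank_normalize(m) for m in mats], axis=0)
        assert cons.consensus == pytest.approx(direct, abs=1e-12)

    def test_gene_universe_mismatch_rejected(self, rng):
        a = pearson_scores(_matrix(rng.standard_normal((3, 20)), prefix="G"))
        b = pearson_scores(_matrix(rng.standard_normal((3, 20)), prefix="H"))
        with pytest.raises(InferenceError, match="universe"):
            consensus_aggregate([a, b])


class TestThreshold:
    def _consensus(self, rng, p=15):
        vals = rng.standard_normal((p, 40))
        return consensus_aggregate([pearson_scores(_matrix(vals)),
                                    spearman_scores(_matrix(vals))])

    def test_zero_cutoff_keeps_all_edges(self, rng):
        cons = self._consensus(rng)
        g = threshold_network(cons, 0.0)
        assert g.number_of_edges() == 15 * 14 // 2

    def test_cutoff_above_max_is_error(self):
        # two exactly reversed rankings -> every consensus entry is 0.5
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 3.0
        s[0, 2] = s[2, 0] = 2.0
        s[1, 2] = s[2, 1] = 1.0
        a = MethodScoreMatrix("pearson", ["A", "B", "C"], s)
        b = MethodScoreMatrix("spearman", ["A", "B", "C"], 4.0 - s - 4.0 * np.eye(3))
        cons = consensus_aggregate([a, b])
        with pytest.raises(InferenceError, match="lower the cutoff"):
            threshold_network(cons, 0.9)

    def test_quantile_cutoff_keeps_expected_count(self, rng):
        cons = self._consensus(rng)
        iu = np.triu_indices(len(cons.gene_ids), 1)
        edges = cons.consensus[iu]
        cutoff = np.quantile(edges, 0.9)
        kept = threshold_network(cons, cutoff).number_of_edges()
        assert kept == np.sum(edges >= cutoff)


class TestInferAll:
    def test_all_methods_symmetric_zero_diag(self, rng):
        m = _matrix(rng.standard_normal((8, 40)))
        scores = infer_all(m, n_trees=20, seed=0)
        assert set(scores) == set(METHODS)
        for sm in scores.values():
            assert np.allclose(sm.scores, sm.scores.T)
            assert np.all(np.diag(sm.scores) == 0)
            assert np.all(sm.scores >= 0)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(InferenceError):
            infer_all(_matrix(rng.standard_normal((4, 20))), methods=("pearson", "nope"))
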