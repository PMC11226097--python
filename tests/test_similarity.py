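"""Jaccard coefficients, score distances, dendrograms, cophenetic validation."""

import numpy as np
import pytest

from gsmm_lpca.reaction_matrix import BinaryReactionMatrix
from gsmm_lpca.similarity import (
    LinkageTree,
    PairwiseMatrix,
    cophenetic_correlation,
    cophenetic_matrix,
    hierarchical_cluster,
    jaccard_matrix,
    score_distances,
)


def brm(values, row_ids=None, col_ids=None):
    values = np.asarray(values)
    row_ids = row_ids or [f"m{i}" for i in range(values.shape[0])]
    col_ids = col_ids or [f"r{j}" for j in range(values.shape[1])]
    return BinaryReactionMatrix(values, row_ids, col_ids)


class TestJaccard:
    def test_spec_arithmetic(self):
        # supports {r1,r2,r3} and {r2,r3,r4} -> 2/4
        X = brm([[1, 1, 1, 0], [0, 1, 1, 1]])
        J = jaccard_matrix(X)
        assert J.values[0, 1] == 0.5

    def test_identical_and_disjoint_rows(self):
        X = brm([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        J = jaccard_matrix(X)
        assert J.values[0, 1] == 1.0
        assert J.values[0, 2] == 0.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(31)
        X = brm((rng.random((8, 15)) < 0.4).astype(int))
        J = jaccard_matrix(X)
        for i in range(8):
            for j in range(8):
                a, b = X.row_support(i), X.row_support(j)
                expected = 1.0 if not (a | b) else len(a & b) / len(a | b)
                assert J.values[i, j] == pytest.approx(expected, abs=1e-15)

    def test_empty_supports_convention(self):
        X = brm([[0, 0], [0, 0], [1, 0]])
        J = jaccard_matrix(X)
        assert J.values[0, 1] == 1.0
        assert J.values[0, 2] == 0.0


class TestScoreDistances:
    def test_manhattan_and_euclidean_closed_form(self):
        S = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert score_distances(S, "manhattan").values[0, 1] == 3.0
        assert score_distances(S, "euclidean").values[0, 1] == pytest.approx(np.sqrt(5))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(32)
        S = rng.normal(size=(7, 3))
        for metric, f in (("euclidean", lambda d: np.sqrt((d**2).sum())),
                          ("manhattan", lambda d: np.abs(d).sum())):
            D = score_distances(S, metric).values
            for i in range(7):
                for j in range(7):
                    assert D[i, j] == pytest.approx(f(S[i] - S[j]), abs=1e-12)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            score_distances(np.zeros((3, 2)), "cosine")


def distance_matrix(values, ids):
    return PairwiseMatrix(np.asarray(values, dtype=float), ids, "euclidean")


class TestHierarchicalCluster:
    def test_closest_pair_merges_first(self):
        D = distance_matrix([[0, 1, 10], [1, 0, 10], [10, 10, 0]], list("abc"))
        tree = hierarchical_cluster(D)
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 1.0

    def test_ultrametric_input_is_fixed_point(self):
        # valid ultrametric: d(a,b)=2, all distances to c and d are 6, d(c,d)=2
        D = distance_matrix(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], list("abcd")
        )
        for linkage in ("complete", "average", "single"):
            tree = hierarchical_cluster(D, linkage)
            coph = cophenetic_matrix(tree)
            assert np.allclose(coph.to_frame().loc[list("abcd"), list("abcd")], D.values)

    def test_merge_sequence_matches_naive_agglomeration(self):
        rng = np.random.default_rng(33)
        pts = rng.normal(size=(9, 3))
        D = score_distances(pts, "euclidean")
        tree = hierarchical_cluster(D, "complete")

        # naive O(n^3) complete-linkage agglomeration
        clusters = {i: {i} for i in range(9)}
        heights = []
        next_id = 9
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    d = max(D.values[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[next_id] = clusters.pop(a) | clusters.pop(b)
            next_id += 1
        assert np.allclose(sorted(tree.linkage[:, 2]), sorted(heights), atol=1e-12)

    def test_similarity_kind_rejected(self):
        J = PairwiseMatrix(np.eye(3), list("abc"), "jaccard")
        with pytest.raises(ValueError):
            hierarchical_cluster(J)


class TestCopheneticMatrix:
    def test_two_leaf_dendrogram(self):
        D = distance_matrix([[0, 3.5], [3.5, 0]], list("ab"))
        coph = cophenetic_matrix(hierarchical_cluster(D))
        assert coph.values[0, 1] == 3.5

    def test_caterpillar_newick_path_sums(self):
        tree = LinkageTree.from_newick("((a:1,b:1):1,c:2);")
        cm = cophenetic_matrix(tree).to_frame()
        assert cm.loc["a", "b"] == 2.0
        assert cm.loc["a", "c"] == 4.0
        assert cm.loc["b", "c"] == 4.0

    def test_random_newick_matches_independent_path_sums(self):
        # independent patristic computation through scikit-bio
        import io

        import skbio

        newick = "((a:0.5,(b:0.2,c:0.9):0.3):1.1,(d:0.4,e:0.6):0.2);"
        ours = cophenetic_matrix(LinkageTree.from_newick(newick)).to_frame()
        sk = skbio.TreeNode.read(io.StringIO(newick)).tip_tip_distances()
        for a in "abcde":
            for b in "abcde":
                if a != b:
                    assert ours.loc[a, b] == pytest.approx(sk[a, b], abs=1e-12)

    def test_hclust_newick_export_preserves_cophenetic_distances(self):
        rng = np.random.default_rng(34)
        D = score_distances(rng.normal(size=(6, 2)), "euclidean")
        tree = hierarchical_cluster(D, "average")
        reread = LinkageTree.from_newick(tree.to_newick())
        a = cophenetic_matrix(tree).to_frame()
        b = cophenetic_matrix(reread).to_frame().loc[a.index, a.columns]
        assert np.allclose(a, b, atol=1e-9)


class TestCopheneticCorrelation:
    def tree_pair(self, seed=35):
        rng = np.random.default_rng(seed)
        D = score_distances(rng.normal(size=(8, 2)), "euclidean")
        t1 = hierarchical_cluster(D, "complete")
        t2 = hierarchical_cluster(D, "single")
        return t1, t2

    def test_self_correlation_is_one(self):
        t1, _ = self.tree_pair()
        assert cophenetic_correlation(t1, t1) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        t1, _ = self.tree_pair()
        doubled = LinkageTree(
            leaf_ids=list(t1.leaf_ids), source="hclust",
            linkage=np.column_stack([t1.linkage[:, :2], t1.linkage[:, 2] * 2, t1.linkage[:, 3]]),
        )
        assert cophenetic_correlation(t1, doubled) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        t1, t2 = self.tree_pair()
        assert cophenetic_correlation(t1, t2) == pytest.approx(
            cophenetic_correlation(t2, t1), abs=1e-12
        )

    def test_leaf_mismatch_error(self):
        t1, _ = self.tree_pair()
        leaves = t1.leaf_ids
        renamed = ",".join(f"{l}:1" for l in leaves[:-1])
        other = LinkageTree.from_newick(f"(({renamed}):1,zz:2);")
        with pytest.raises(ValueError, match="zz"):
            cophenetic_correlation(t1, other)

    def test_permuted_leaves_decorrelate(self):
        rng = np.random.default_rng(36)
        D = score_distances(rng.normal(size=(10, 2)), "euclidean")
        t1 = hierarchical_cluster(D)
        corrs = []
        for _ in range(40):
            perm = rng.permutation(len(t1.leaf_ids))
            t2 = LinkageTree(
                leaf_ids=[t1.leaf_ids[i] for i in perm], source="hclust", linkage=t1.linkage
            )
            corrs.append(cophenetic_correlation(t1, t2))
        assert abs(np.mean(corrs)) < 0.1


class TestScorePhylogenyPipeline:
    def test_score_dendrogram_recovers_planted_tree(self):
        """Score-space dendrograms correlate with the generating phylogeny."""
        from gsmm_lpca import differentialize, fit_lpca
        from gsmm_lpca.synthgen import SynthSpec, generate_matrix

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = SynthSpec(n_clusters=4, hierarchical=True, seed=100 + seed)
            raw, _, truth = generate_matrix(spec)
            matrix, _ = differentialize(raw)
            model = fit_lpca(matrix, k=2, m=4.0)
            dist = score_distances(model.S, "manhattan", ids=list(matrix.row_ids))
            dend = hierarchical_cluster(dist, "complete")
            if cophenetic_correlation(dend, truth.true_tree) >= 0.8:
                hits += 1
        assert hits >= n_seeds - 1
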