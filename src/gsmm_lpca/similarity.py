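"""Pairwise similarity, clustering, and tree comparison.

Two complementary views of a model collection are compared here: reaction
content directly (Jaccard coefficients on row supports of the differential
matrix) and logistic-PCA score space (Euclidean or Manhattan distances,
agglomerated into a dendrogram).  A dendrogram can then be validated
against an external phylogeny via the cophenetic correlation coefficient —
the Pearson correlation of the two trees' pairwise cophenetic (merge-height
or patristic) distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from .reaction_matrix import BinaryReactionMatrix

logger = logging.getLogger(__name__)

Kind = Literal["jaccard", "euclidean", "manhattan", "cophenetic"]


@dataclass
class PairwiseMatrix:
    """Symmetric similarity/distance matrix with ordered ids."""

    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class LinkageTree:
    """A dendrogram (scipy linkage) or a phylogeny (dendropy tree).

    Both expose pairwise cophenetic distances over the same leaf-id
    interface: merge heights for a dendrogram, patristic (branch-length
    path) distances for a phylogeny.
    """

    leaf_ids: list[str]
    source: Literal["hclust", "newick"]
    linkage: np.ndarray | None = None
    tree: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        if len(set(self.leaf_ids)) != len(self.leaf_ids):
            raise ValueError("duplicate leaf ids")
        if self.source == "hclust" and self.linkage is None:
            raise ValueError("hclust tree requires a linkage matrix")
        if self.source == "newick" and self.tree is None:
            raise ValueError("newick tree requires a dendropy tree")

    @classmethod
    def from_newick(cls, source: str | Path) -> "LinkageTree":
        """Read a Newick tree from a path or a literal newick string."""
        text = str(source)
        if not text.lstrip().startswith("("):  # a path, not a literal newick
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
        leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        return cls(leaf_ids=leaves, source="newick", tree=tree)

    def leaf_order(self) -> list[str]:
        """Leaf ids in display order (dendrogram order for hclust trees)."""
        if self.source == "hclust":
            order = hierarchy.leaves_list(self.linkage)
            return [self.leaf_ids[i] for i in order]
        return list(self.leaf_ids)

    def to_newick(self) -> str:
        if self.source == "newick":
            return self.tree.as_string(schema="newick").strip()
        root = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left, right = node.get_left(), node.get_right()
            parts = [
                f"{render(child)}:{(node.dist - child.dist) / 2.0:g}"
                for child in (left, right)
            ]
            return "(" + ",".join(parts) + ")"

        return render(root) + ";"


def jaccard_matrix(X: BinaryReactionMatrix) -> PairwiseMatrix:
    """Pairwise Jaccard coefficients between the rows' reaction supports.

    ``J(A, B) = |A ∩ B| / |A ∪ B|`` over the sets of present reactions.
    Two rows with empty supports have no defined ratio; they are treated as
    identical (J = 1) and the convention is logged.
    """
    v = X.values.astype(np.int64)
    inter = v @ v.T
    sizes = v.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    out = np.ones_like(inter, dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    if (~nz).any():
        logger.info("empty-support row pair(s): Jaccard defined as 1 by convention")
    return PairwiseMatrix(out, list(X.row_ids), "jaccard")


def score_distances(
    S: np.ndarray | pd.DataFrame,
    metric: Literal["euclidean", "manhattan"] = "manhattan",
    ids: list[str] | None = None,
) -> PairwiseMatrix:
    """Pairwise L2 or L1 distances between score rows."""
    if metric not in ("euclidean", "manhattan"):
        raise ValueError("metric must be 'euclidean' or 'manhattan'")
    if isinstance(S, pd.DataFrame):
        ids = ids or [str(i) for i in S.index]
        S = S.to_numpy()
    if ids is None:
        ids = [str(i) for i in range(S.shape[0])]
    cityblock = {"euclidean": "euclidean", "manhattan": "cityblock"}[metric]
    d = squareform(pdist(np.asarray(S, dtype=float), metric=cityblock))
    return PairwiseMatrix(d, list(ids), metric)


def hierarchical_cluster(
    D: PairwiseMatrix,
    linkage: Literal["complete", "average", "single"] = "complete",
) -> LinkageTree:
    """Agglomerative clustering of a distance matrix into a dendrogram."""
    if D.kind == "jaccard":
        raise ValueError("hierarchical_cluster expects a distance matrix, not similarities")
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    Z = hierarchy.linkage(D.condensed(), method=linkage)
    return LinkageTree(leaf_ids=list(D.ids), source="hclust", linkage=Z)


def cophenetic_matrix(tree: LinkageTree) -> PairwiseMatrix:
    """Pairwise cophenetic distances implied by a tree.

    For a dendrogram this is the merge height at which two leaves first
    share a cluster; for a phylogeny it is the patristic distance (sum of
    branch lengths along the connecting path).
    """
    if tree.source == "hclust":
        d = squareform(hierarchy.cophenet(tree.linkage))
        return PairwiseMatrix(d, list(tree.leaf_ids), "cophenetic")
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(tree.leaf_ids)
    d = np.zeros((n, n))
    for i, a in enumerate(tree.leaf_ids):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[a], taxa[tree.leaf_ids[j]])
            d[i, j] = d[j, i] = dist
    return PairwiseMatrix(d, list(tree.leaf_ids), "cophenetic")


def cophenetic_correlation(
    t1: LinkageTree,
    t2: LinkageTree,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlate the cophenetic distances of two trees over shared leaves.

    Both trees must carry exactly the same leaf ids; the upper triangles of
    the two cophenetic matrices are aligned by id before correlating.
    """
    s1, s2 = set(t1.leaf_ids), set(t2.leaf_ids)
    if s1 != s2:
        missing = sorted(s1 ^ s2)
        raise ValueError(f"leaf sets differ: {missing[:10]}")
    if len(s1) < 3:
        raise ValueError("need at least 3 shared leaves")
    order = sorted(s1)

    def aligned_upper(tree: LinkageTree) -> np.ndarray:
        cm = cophenetic_matrix(tree).to_frame().loc[order, order].to_numpy()
        iu = np.triu_indices(len(order), k=1)
        return cm[iu]

    a, b = aligned_upper(t1), aligned_upper(t2)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cophenetic distances are constant; correlation undefined")
    if method == "pearson":
        return float(pearsonr(a, b).statistic)
    if method == "spearman":
        return float(spearmanr(a, b).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")
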