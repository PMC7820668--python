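"""Whole-microbiome similarity metrics.

Three metrics, one per feature space:

* **OTU profiles** — phylogeny-weighted similarity on a fixed reference tree
  (Meta-Storms style).  Abundance mass is matched bottom-up over the tree:
  mass matched at a leaf counts in full; unmatched residual mass climbs
  toward the root, accumulating branch length, and mass matched at an
  ancestor of combined distance D contributes with weight ``exp(-D)``.
* **Species profiles** — the same kernel on a taxonomy tree built on the fly
  from the lineages of exactly the features present in the two profiles
  (the "dynamic" variant, tolerant of species absent from any fixed tree).
* **KO profiles** — Bray-Curtis similarity, ``1 - BC``.

All metrics are symmetric, bounded in [0, 1], and equal 1 for identical
profiles.  The tree kernel is evaluated by a single post-order pass over a
flattened tree, vectorized over database samples so that one query can be
scored against many candidates at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import ValidationError
from .phylogeny import DEFAULT_EDGE_LENGTH, build_taxonomy_tree
from .profiles import FeatureSpace, Profile, TaxonomyLineage, normalize

__all__ = [
    "SimilarityResult",
    "FlatTree",
    "metastorms_similarity",
    "dynamic_metastorms_similarity",
    "braycurtis_similarity",
    "pairwise_similarity_matrix",
]


@dataclass(frozen=True)
class SimilarityResult:
    """A similarity value plus diagnostics about abundance mass dropped
    because features were absent from the reference tree."""

    value: float
    dropped_mass_a: float = 0.0
    dropped_mass_b: float = 0.0


class FlatTree:
    """A tree flattened to post-order arrays for fast kernel evaluation.

    ``order`` lists node indices in post-order (children before parents,
    root last); ``children[i]`` are the child indices of node i;
    ``length[i]`` is the branch length above node i (0 for the root);
    ``leaf_row`` maps leaf label -> row in the abundance matrix, following
    ``leaf_order``.
    """

    __slots__ = ("n_nodes", "order", "children", "length", "leaf_order", "leaf_row", "leaf_node_index")

    def __init__(self, tree: TreeNode) -> None:
        nodes = list(tree.postorder(include_self=True))
        index = {id(node): i for i, node in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.order = list(range(self.n_nodes))  # postorder by construction
        self.children: list[list[int]] = [
            [index[id(c)] for c in node.children] for node in nodes
        ]
        self.length = np.array(
            [float(node.length or 0.0) for node in nodes], dtype=np.float64
        )
        self.leaf_order: list[str] = [n.name for n in nodes if not n.children]
        self.leaf_row: dict[str, int] = {name: r for r, name in enumerate(self.leaf_order)}
        if len(self.leaf_row) != len(self.leaf_order):
            raise ValidationError("duplicate leaf labels in tree")
        leaf_node_index = np.full(self.n_nodes, -1, dtype=np.int64)
        row = 0
        for i, node in enumerate(nodes):
            if not node.children:
                leaf_node_index[i] = row
                row += 1
        self.leaf_node_index = leaf_node_index

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)


def _kernel(ftree: FlatTree, qa: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Score one aligned query column against each column of ``B``.

    Bottom-up matching recursion: at every node, residual mass packets from
    the two sides are pooled (mass-weighted mean accumulated distance) and
    the overlap ``min`` is matched with weight ``exp(-(D_A + D_B))``.
    Residual mass surviving past the root contributes nothing.
    """
    n_cols = B.shape[1]
    n = ftree.n_nodes
    MA = np.zeros((n, n_cols))
    SA = np.zeros((n, n_cols))  # mass * accumulated distance, side A
    MB = np.zeros((n, n_cols))
    SB = np.zeros((n, n_cols))
    score = np.zeros(n_cols)
    length = ftree.length
    children = ftree.children
    leaf_idx = ftree.leaf_node_index
    for i in range(n):
        kids = children[i]
        if not kids:
            row = leaf_idx[i]
            MA[i, :] = qa[row]
            MB[i, :] = B[row, :]
        else:
            ma, sa, mb, sb = MA[i], SA[i], MB[i], SB[i]
            for c in kids:
                ell = length[c]
                mc = MA[c]
                ma += mc
                sa += SA[c] + mc * ell
                mc = MB[c]
                mb += mc
                sb += SB[c] + mc * ell
        ma, sa, mb, sb = MA[i], SA[i], MB[i], SB[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            DA = np.where(ma > 0.0, sa / np.where(ma > 0.0, ma, 1.0), 0.0)
            DB = np.where(mb > 0.0, sb / np.where(mb > 0.0, mb, 1.0), 0.0)
        matched = np.minimum(ma, mb)
        score += matched * np.exp(-(DA + DB))
        ma -= matched
        mb -= matched
        np.multiply(ma, DA, out=sa)
        np.multiply(mb, DB, out=sb)
    return score


def _align_to_tree(profile: Profile, ftree: FlatTree) -> tuple[np.ndarray, float]:
    """Project a normalized profile onto tree leaves.

    Returns the renormalized abundance vector (ordered by ``leaf_order``)
    and the relative-abundance mass dropped because its features are not
    tree leaves.
    """
    vec = np.zeros(ftree.n_leaves)
    dropped = 0.0
    for fid, value in profile.abundances.items():
        row = ftree.leaf_row.get(fid)
        if row is None:
            dropped += value
        else:
            vec[row] += value
    retained = vec.sum()
    if retained <= 0.0:
        raise ValidationError(
            "profile shares no features with the reference tree (all mass dropped)"
        )
    vec /= retained
    return vec, dropped


def metastorms_similarity(
    a: Profile, b: Profile, tree: TreeNode | FlatTree
) -> SimilarityResult:
    """Phylogeny-weighted similarity of two profiles on a reference tree.

    Features absent from the tree are dropped and the profiles renormalized;
    the dropped mass is reported in the result.  A profile entirely disjoint
    from the tree is an error.
    """
    ftree = tree if isinstance(tree, FlatTree) else FlatTree(tree)
    va, dropped_a = _align_to_tree(normalize(a), ftree)
    vb, dropped_b = _align_to_tree(normalize(b), ftree)
    value = float(_kernel(ftree, va, vb[:, None])[0])
    return SimilarityResult(value=value, dropped_mass_a=dropped_a, dropped_mass_b=dropped_b)


def dynamic_metastorms_similarity(
    a: Profile,
    b: Profile,
    lineages: Mapping[str, TaxonomyLineage],
    edge_length: float = DEFAULT_EDGE_LENGTH,
) -> SimilarityResult:
    """Taxonomy-tree similarity for species profiles.

    The tree is built dynamically from the lineages of exactly the features
    present in ``a`` or ``b``; features without a lineage get an
    all-UNCLASSIFIED lineage and hang directly below the root.  Equivalent to
    :func:`metastorms_similarity` on that tree.
    """
    union = set(a.abundances) | set(b.abundances)
    if not union:
        raise ValidationError("both profiles are empty")
    sub = {fid: lineages.get(fid, TaxonomyLineage()) for fid in union}
    tree = build_taxonomy_tree(sub, edge_length=edge_length)
    return metastorms_similarity(a, b, tree)


def braycurtis_similarity(a: Profile, b: Profile) -> SimilarityResult:
    """Bray-Curtis similarity ``1 - sum|a-b| / sum(a+b)`` on the feature union.

    For normalized profiles this reduces to ``1 - 0.5 * sum|a_i - b_i|``.
    Features absent from one profile count as abundance 0.
    """
    if a.feature_space is not b.feature_space:
        raise ValidationError(
            f"feature-space mismatch: {a.feature_space.value} vs {b.feature_space.value}"
        )
    an = normalize(a).abundances
    bn = normalize(b).abundances
    union = set(an) | set(bn)
    num = 0.0
    den = 0.0
    for fid in sorted(union):
        x = an.get(fid, 0.0)
        y = bn.get(fid, 0.0)
        num += abs(x - y)
        den += x + y
    value = 1.0 - num / den
    return SimilarityResult(value=value)


def pairwise_similarity_matrix(
    profiles: Sequence[Profile],
    *,
    tree: TreeNode | None = None,
    lineages: Mapping[str, TaxonomyLineage] | None = None,
    edge_length: float = DEFAULT_EDGE_LENGTH,
) -> np.ndarray:
    """Symmetric similarity matrix with the metric chosen by feature space.

    OTU -> phylogeny kernel on *tree*; species -> dynamic taxonomy-tree
    kernel on *lineages*; KO -> Bray-Curtis.  The diagonal is 1 by
    definition (self-similarity).
    """
    if not profiles:
        raise ValidationError("no profiles given")
    space = profiles[0].feature_space
    if any(p.feature_space is not space for p in profiles):
        raise ValidationError("mixed feature spaces in pairwise similarity matrix")
    n = len(profiles)
    M = np.ones((n, n))
    if space is FeatureSpace.OTU:
        if tree is None:
            raise ValidationError("OTU similarity requires a reference tree")
        ftree = FlatTree(tree)
        pair = lambda a, b: metastorms_similarity(a, b, ftree).value
    elif space is FeatureSpace.SPECIES:
        if lineages is None:
            raise ValidationError("species similarity requires lineages")
        pair = lambda a, b: dynamic_metastorms_similarity(
            a, b, lineages, edge_length=edge_length
        ).value
    else:
        pair = lambda a, b: braycurtis_similarity(a, b).value
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pair(profiles[i], profiles[j])
    return M
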