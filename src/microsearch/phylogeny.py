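"""Rooted, branch-length-weighted trees backing phylogeny-based similarity.

Two kinds of tree are used: a fixed reference phylogeny parsed from Newick
(OTU searches), and a taxonomy tree built on the fly from lineage strings
(species searches, the "dynamic" variant).  Both are held as scikit-bio
``TreeNode`` objects.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Mapping

from skbio import TreeNode

from .errors import ParseError, ValidationError
from .profiles import RANK_PREFIXES, TaxonomyLineage

__all__ = [
    "DEFAULT_EDGE_LENGTH",
    "parse_newick",
    "serialize_newick",
    "read_newick",
    "write_newick",
    "build_taxonomy_tree",
    "leaf_set",
    "validate_tree",
]

#: Default taxonomy-tree edge length, ln 2: under the exp(-D) discount of the
#: similarity kernel, every taxonomic rank crossed halves a match's weight.
DEFAULT_EDGE_LENGTH = math.log(2.0)


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a rooted tree; absent branch lengths -> 0."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if not math.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"branch length {node.length} on node {node.name!r} is invalid"
            )
    validate_tree(tree)
    return tree


def serialize_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text(encoding="utf-8"))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(serialize_newick(tree), encoding="utf-8")


def validate_tree(tree: TreeNode) -> None:
    """Check leaf-label uniqueness (the core tree invariant for search)."""
    seen: set[str] = set()
    for tip in tree.tips():
        if tip.name in seen:
            raise ValidationError(f"duplicate leaf label {tip.name!r}")
        seen.add(tip.name)


def leaf_set(tree: TreeNode) -> set[str]:
    """The set of leaf (tip) labels of *tree*."""
    return {tip.name for tip in tree.tips()}


def build_taxonomy_tree(
    lineages: Mapping[str, TaxonomyLineage],
    edge_length: float = DEFAULT_EDGE_LENGTH,
) -> TreeNode:
    """Build a rooted taxonomy tree from lineage strings.

    Internal nodes are shared rank prefixes; each feature becomes a leaf that
    occupies its deepest classified rank step, i.e. the leaf hangs below the
    node of the next-shallower rank.  Consequences:

    * two fully classified species of the same genus are sibling leaves under
      the genus node, at distance ``2 * edge_length`` from each other;
    * a feature classified through r ranks sits r edges below the root;
    * a fully unclassified feature hangs one edge below the root.

    Every edge has length *edge_length*.  Construction is order-independent:
    node identity is the rank-prefix path, and children are canonicalized to
    lexicographic order by name.
    """
    if not lineages:
        raise ValidationError("cannot build a taxonomy tree from an empty lineage map")
    if not (edge_length > 0):
        raise ValidationError(f"edge_length must be > 0, got {edge_length}")
    root = TreeNode(name="root")
    root.length = 0.0
    nodes: dict[tuple[str, ...], TreeNode] = {(): root}
    for fid in sorted(lineages):
        prefix = lineages[fid].classified_prefix()
        # Internal chain covers all classified ranks except the deepest; the
        # leaf itself represents the final rank step.
        parent = root
        for depth in range(len(prefix) - 1):
            key = prefix[: depth + 1]
            node = nodes.get(key)
            if node is None:
                node = TreeNode(name=prefix[depth])
                node.length = edge_length
                parent.append(node)
                nodes[key] = node
            parent = node
        leaf = TreeNode(name=fid)
        leaf.length = edge_length
        parent.append(leaf)
    _sort_children(root)
    validate_tree(root)
    return root


def _sort_children(node: TreeNode) -> None:
    for child in node.children:
        _sort_children(child)
    if node.children:
        node.children.sort(key=lambda n: n.name or "")
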