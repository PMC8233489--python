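"""Newick tree I/O and manipulations.

Thin, deterministic layer over dendropy covering the tree handling applied
to an inferred superfamily phylogeny: midpoint rooting (the root placed
halfway along the longest leaf-to-leaf path), collapse of poorly supported
internal edges, clade extraction and taxonomic annotation.  Support values
follow the IQ-TREE convention of numeric internal-node labels.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .core_io import FormatError, SequenceRecord

__all__ = [
    "Tree",
    "parse_newick",
    "read_newick",
    "write_newick",
    "support_value",
    "midpoint_root",
    "collapse_low_support",
    "extract_clade",
    "annotate_taxonomy",
    "patristic_matrix",
    "leaf_depths",
]

Tree = dendropy.Tree


def parse_newick(text: str) -> Tree:
    """Parse a Newick string; supports are internal-node labels.

    Raises :class:`FormatError` (with the parser's position information) for
    malformed input, and for duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dup = sorted({l for l in labels if labels.count(l) > 1})
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if dup or len(labels) != n_leaves:
        raise FormatError(f"duplicate or missing leaf labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError("negative branch length")
    return tree


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def _min_leaf_label(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def _format_length(x: Optional[float]) -> str:
    return "" if x is None else f":{x:.6g}"


def _newick_str(node: dendropy.Node) -> str:
    if node.is_leaf():
        return f"{node.taxon.label}{_format_length(node.edge.length)}"
    children = sorted(node.child_nodes(), key=_min_leaf_label)
    inner = ",".join(_newick_str(c) for c in children)
    label = node.label or ""
    return f"({inner}){label}{_format_length(node.edge.length)}"


def write_newick(tree: Tree) -> str:
    """Canonical Newick: children ordered by smallest descendant leaf label,
    branch lengths formatted with %.6g, supports as internal labels."""
    return _newick_str(tree.seed_node) + ";"


def support_value(node: dendropy.Node) -> Optional[float]:
    """Numeric support parsed from an internal node label, if any."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _clone(tree: Tree) -> Tree:
    return tree.clone(depth=1)


def _path_between(x: dendropy.Node, y: dendropy.Node) -> list[dendropy.Node]:
    up_x = []
    node = x
    while node is not None:
        up_x.append(node)
        node = node.parent_node
    seen = {id(n) for n in up_x}
    up_y = []
    node = y
    while id(node) not in seen:
        up_y.append(node)
        node = node.parent_node
    lca = node
    return up_x[: up_x.index(lca) + 1] + list(reversed(up_y))


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The root is placed on that path at distance D/2 from each of the two
    maximally distant leaves (on a node when the point falls exactly on
    one); patristic distances are unchanged.  Requires branch lengths.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValueError("midpoint rooting requires branch lengths")
    rooted = _clone(tree)

    leaves = list(rooted.leaf_node_iter())
    best = (-1.0, None, None)
    # all-pairs via per-leaf root paths (desk-scale trees)
    for i, x in enumerate(leaves):
        for y in leaves[i + 1:]:
            path = _path_between(x, y)
            d = 0.0
            for a, b in zip(path, path[1:]):
                edge = a if a.parent_node is b else b
                d += edge.edge.length
            if d > best[0]:
                best = (d, x, y)
    dmax, x, y = best
    if dmax <= 0:
        raise ValueError("tree has zero total depth; cannot midpoint-root")

    path = _path_between(x, y)
    half = dmax / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        child = a if a.parent_node is b else b
        step = child.edge.length
        if abs(acc + step - half) < 1e-12 * max(1.0, dmax):
            # midpoint falls exactly on node b
            if b.parent_node is not None:
                rooted.reroot_at_node(b, update_bipartitions=False,
                                      suppress_unifurcations=True)
            acc += step
            break
        if acc + step > half:
            # midpoint inside this edge; length2 is the head-node (child)
            # side of the split, length1 the tail (parent) side
            if child is b:  # walking down: x-side distance from parent end
                head_side = acc + step - half
            else:           # walking up: x-side distance from child end
                head_side = half - acc
            rooted.reroot_at_edge(
                child.edge,
                length1=step - head_side,
                length2=head_side,
                update_bipartitions=False, suppress_unifurcations=True)
            break
        acc += step
    rooted.seed_node.edge.length = None
    return rooted


def collapse_low_support(
    tree: Tree, threshold: float = 90.0
) -> tuple[Tree, list[dict]]:
    """Contract internal edges whose support is <= threshold (strict keep
    of supports above it, matching a 'BS > 90 shown' convention).

    Edges without a parsable support are treated as below threshold.  The
    contracted edge's length is dropped (polytomy semantics), and each
    contraction is recorded in the returned log.  Leaves are never removed.
    """
    out = _clone(tree)
    log: list[dict] = []
    for node in list(out.postorder_internal_node_iter(exclude_seed_node=True)):
        support = support_value(node)
        if support is not None and support > threshold:
            continue
        parent = node.parent_node
        for child in list(node.child_nodes()):
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
        log.append({"support": support, "dropped_length": node.edge.length})
    return out, log


def extract_clade(tree: Tree, leaf_set: Iterable[str]) -> Tree:
    """Minimal subtree spanning ``leaf_set``, rooted at their MRCA."""
    wanted = set(leaf_set)
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = sorted(wanted - present)
    if unknown:
        raise ValueError(f"unknown leaves: {unknown}")
    sub = _clone(tree)
    sub.retain_taxa_with_labels(sorted(wanted))
    # strip any leftover unifurcating root chain so the MRCA is the root
    while (not sub.seed_node.is_leaf()
           and len(sub.seed_node.child_nodes()) == 1):
        child = sub.seed_node.child_nodes()[0]
        sub.seed_node.remove_child(child)
        child.parent_node = None
        sub.seed_node = child
    sub.seed_node.edge.length = None
    return sub


def annotate_taxonomy(
    tree: Tree, records: Sequence[SequenceRecord]
) -> Tree:
    """Attach each leaf's taxonomy and each internal node's majority
    superkingdom (first taxonomy rank; ties alphabetical)."""
    by_id = {r.id: r for r in records}
    out = _clone(tree)
    missing = [lf.taxon.label for lf in out.leaf_node_iter()
               if lf.taxon.label not in by_id]
    if missing:
        raise ValueError(f"records missing for leaves: {missing}")
    for node in out.postorder_node_iter():
        if node.is_leaf():
            node.taxonomy = by_id[node.taxon.label].taxonomy
        else:
            counts = Counter(
                lf.taxonomy[0] for lf in node.leaf_iter()
                if getattr(lf, "taxonomy", None)
            )
            if counts:
                top = max(counts.values())
                node.majority_superkingdom = sorted(
                    k for k, v in counts.items() if v == top
                )[0]
            else:
                node.majority_superkingdom = None
    return out


def patristic_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the symmetric matrix of leaf-to-leaf path lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat


def leaf_depths(tree: Tree) -> dict[str, float]:
    """Root-to-leaf path lengths."""
    depths: dict[str, float] = {}
    for lf in tree.leaf_node_iter():
        d = 0.0
        node = lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[lf.taxon.label] = d
    return depths
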