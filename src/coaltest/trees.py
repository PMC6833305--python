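"""Tree data model, newick I/O, rooting, pruning and Robinson-Foulds distances.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package; this module provides the small, contract-checked surface the rest
of the code relies on.  Internal node labels are treated as support values
when they parse as numbers (the RAxML convention).
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = [
    "Tree",
    "NewickError",
    "TreeError",
    "parse_newick",
    "parse_newick_list",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "leaf_labels",
    "internal_supports",
    "root_by_outgroup",
    "prune_to_taxa",
    "prune_to_common_leaves",
    "rf_distance",
    "nrfd",
    "terminal_branch_lengths",
    "is_binary",
]

Tree = dendropy.Tree


class TreeError(ValueError):
    """Invalid tree or invalid tree operation."""


class NewickError(TreeError):
    """Malformed newick input."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single newick statement into a tree.

    The rooted flag is set from the topology: a tree is rooted iff its root
    has exactly two children.  Internal node labels are kept verbatim on
    ``node.label`` (use :func:`internal_supports` to read them as numbers).

    Raises
    ------
    NewickError
        On empty input, malformed newick, or duplicate leaf labels.
    """
    if text is None or not text.strip():
        raise NewickError("empty newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {', '.join(dups)}")
    if not labels:
        raise NewickError("tree has no leaves")
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def parse_newick_list(text: str) -> list[Tree]:
    """Parse a multi-tree newick string, one statement per line."""
    trees = []
    for line in text.strip().splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    if not trees:
        raise NewickError("no trees found")
    return trees


def read_newick_file(path) -> list[Tree]:
    with open(path) as fh:
        return parse_newick_list(fh.read())


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize a tree to a single newick statement (no rooting token).

    Branch lengths are written with ``precision`` significant digits.
    """
    if tree is None or tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise TreeError("cannot serialize an empty tree")
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
        unquoted_underscores=True,
    )
    return out.strip()


def write_newick_file(trees: Iterable[Tree], path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, precision=precision) + "\n")


# ---------------------------------------------------------------------------
# Accessors
# ---------------------------------------------------------------------------

def leaf_labels(tree: Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def internal_supports(tree: Tree, exclude_root: bool = True) -> list[float]:
    """Numeric support values on internal nodes (root excluded by default)."""
    vals = []
    for nd in tree.preorder_internal_node_iter():
        if exclude_root and nd is tree.seed_node:
            continue
        if nd.label is not None:
            try:
                vals.append(float(nd.label))
            except ValueError:
                pass
    return vals


def terminal_branch_lengths(tree: Tree) -> dict[str, float]:
    """Map leaf label -> length of its terminal branch.

    Raises
    ------
    TreeError
        If any terminal branch lacks a length.
    """
    out = {}
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise TreeError(f"missing branch length on terminal edge of leaf {leaf.taxon.label!r}")
        out[leaf.taxon.label] = float(leaf.edge.length)
    return out


def is_binary(tree: Tree) -> bool:
    """True iff rooted with a bifurcating root and every internal node has 2 children."""
    if len(tree.seed_node.child_nodes()) != 2:
        return False
    for nd in tree.preorder_internal_node_iter():
        if len(nd.child_nodes()) != 2:
            return False
    return True


# ---------------------------------------------------------------------------
# Rooting and pruning
# ---------------------------------------------------------------------------

def root_by_outgroup(tree: Tree, outgroup, drop_outgroup: bool = False) -> Tree:
    """Root a tree so the root separates the outgroup from everything else.

    Parameters
    ----------
    outgroup : str or iterable of str
        One or more leaf labels.  They must form one side of a branch in the
        unrooted tree (i.e. be "monophyletic" in the unrooted sense).
    drop_outgroup : bool
        If true, the outgroup leaves are removed after rooting and the
        ingroup MRCA becomes the root.

    Returns a new tree; the input is not modified.
    """
    if isinstance(outgroup, str):
        og = frozenset([outgroup])
    else:
        og = frozenset(outgroup)
    all_leaves = leaf_labels(tree)
    missing = sorted(og - all_leaves)
    if missing:
        raise TreeError(f"outgroup labels not in tree: {', '.join(missing)}")
    if og == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    work = tree.clone(depth=1)
    target_edge = None
    for nd in work.preorder_node_iter():
        if nd is work.seed_node:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if below == og or (all_leaves - below) == og:
            target_edge = nd.edge
            break
    if target_edge is None:
        # report the smallest clade containing the outgroup, for diagnostics
        best = all_leaves
        for nd in work.preorder_node_iter():
            below = frozenset(l.taxon.label for l in nd.leaf_iter())
            if og <= below and len(below) < len(best):
                best = below
        raise TreeError(
            "outgroup is not monophyletic in the unrooted tree; smallest "
            f"containing bipartition side: {{{', '.join(sorted(best))}}}"
        )
    length = target_edge.length
    if length is not None:
        work.reroot_at_edge(target_edge, length1=length / 2.0, length2=length / 2.0,
                            update_bipartitions=False)
    else:
        work.reroot_at_edge(target_edge, update_bipartitions=False)
    work.is_rooted = True
    if drop_outgroup:
        work = prune_to_taxa(work, all_leaves - og)
        work.is_rooted = True
    return work


def prune_to_taxa(tree: Tree, labels) -> Tree:
    """Restrict a tree to the given leaf labels (returns a new tree).

    Degree-2 nodes created by the pruning are suppressed and their incident
    branch lengths summed, so leaf-to-leaf path lengths are preserved.
    """
    keep = set(labels)
    present = leaf_labels(tree)
    missing = sorted(keep - present)
    if missing:
        raise TreeError(f"labels not in tree: {', '.join(missing)}")
    work = tree.clone(depth=1)
    work.retain_taxa_with_labels(sorted(keep))
    work.purge_taxon_namespace()
    return work


def prune_to_common_leaves(t1: Tree, t2: Tree, min_shared: int = 3) -> tuple[Tree, Tree]:
    """Prune both trees to their shared leaf set.

    Raises
    ------
    TreeError
        If fewer than ``min_shared`` leaves are shared.
    """
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < min_shared:
        raise TreeError(
            f"only {len(shared)} shared leaves (need >= {min_shared})"
        )
    return prune_to_taxa(t1, shared), prune_to_taxa(t2, shared)


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _nontrivial_bipartitions(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted non-trivial bipartitions as canonical {side, complement} pairs."""
    all_leaves = leaf_labels(tree)
    out = set()
    root = tree.seed_node
    root_children = root.child_nodes()
    root_degree = len(root_children)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        above = all_leaves - below
        if len(below) < 2 or len(above) < 2:
            continue
        # with a bifurcating root, the two root edges carry the same split;
        # canonical frozenset-pair form deduplicates them
        out.add(frozenset((below, above)))
    # root degree only matters through deduplication above
    del root_degree
    return out


def _nontrivial_clades(tree: Tree) -> set[frozenset[str]]:
    """Rooted non-trivial clades: proper leaf subsets of size >= 2."""
    all_leaves = leaf_labels(tree)
    out = set()
    for nd in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 2 <= len(below) < len(all_leaves):
            out.add(below)
    return out


def _check_same_leaves(t1: Tree, t2: Tree) -> frozenset[str]:
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise TreeError(f"leaf sets differ; symmetric difference: {', '.join(diff)}")
    return l1


def rf_distance(t1: Tree, t2: Tree, rooted: bool = False) -> int:
    """Robinson-Foulds distance between two trees on the same leaf set.

    By default the trees are compared as unrooted (symmetric difference of
    non-trivial bipartitions).  With ``rooted=True`` they are compared on
    clade sets instead.
    """
    leaves = _check_same_leaves(t1, t2)
    if rooted:
        return len(_nontrivial_clades(t1) ^ _nontrivial_clades(t2))
    if len(leaves) < 4:
        return 0  # no non-trivial unrooted bipartition exists below 4 leaves
    return len(_nontrivial_bipartitions(t1) ^ _nontrivial_bipartitions(t2))


def nrfd(t1: Tree, t2: Tree, rooted: bool = False) -> float:
    """Normalized RF distance: RF divided by the maximum possible distance.

    The denominator is the total number of non-trivial internal edges
    (clades, in rooted mode) across both trees; for two unrooted binary
    trees on n leaves this is 2(n-3).  If both trees are stars the
    distance is defined as 0.
    """
    _check_same_leaves(t1, t2)
    if rooted:
        s1, s2 = _nontrivial_clades(t1), _nontrivial_clades(t2)
    else:
        s1, s2 = _nontrivial_bipartitions(t1), _nontrivial_bipartitions(t2)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom
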