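"""Rooted phylogeny container used throughout the pipeline.

Trees are consumed, never inferred, by this package: the miner classifies
candidate loci on an externally built tree, the reconciliation engine maps a
virus tree onto a host tree, and the transmission counter collapses a labeled
virus tree.  What every stage needs is a light rooted-tree structure with
unique tip labels, optional branch lengths (substitutions/site) and cheap
clade queries.  Newick text is parsed with :mod:`dendropy` (quoted labels,
scientific-notation lengths and internal support labels are handled there)
and converted into this structure at the boundary; serialization round-trips
topology, labels and lengths losslessly.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "Phylogeny", "parse_newick", "write_newick"]

_UNQUOTED_OK = re.compile(r"^[A-Za-z0-9_.+|/-]+$")


class Node:
    """A node of a rooted tree: a label (tips), branch length and children."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        # iterative: candidate trees can be deep caterpillars
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Phylogeny:
    """A rooted tree with uniquely labeled tips.

    Uniqueness of tip labels is enforced at construction from parsed input;
    derived trees (e.g. group-collapsed trees, where leaf labels are host
    groups and may repeat) can opt out via ``require_unique=False``.
    """

    def __init__(self, root: Node, require_unique: bool = True) -> None:
        self.root = root
        if require_unique:
            labels = self.tip_labels()
            dupes = {x for x in labels if labels.count(x) > 1}
            if dupes:
                raise ValueError(f"duplicate tip labels: {sorted(dupes)}")

    # -- basic queries ----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def find_tip(self, label: str) -> Node:
        for n in self.tips():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def clade_tips(self, node: Node) -> frozenset[str]:
        return frozenset(n.label for n in node.leaves())

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        if not want:
            raise ValueError("mrca of empty label set")
        for node in self.postorder():
            if want <= self.clade_tips(node):
                return node
        missing = want - set(self.tip_labels())
        raise KeyError(f"tips not in tree: {sorted(missing)}")

    def copy(self) -> "Phylogeny":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Phylogeny(rec(self.root), require_unique=False)

    def relabel(self, mapping: Callable[[str], str]) -> "Phylogeny":
        t = self.copy()
        for n in t.postorder():
            if n.is_leaf:
                n.label = mapping(n.label)
        return Phylogeny(t.root, require_unique=False)

    # -- rooting ----------------------------------------------------------
    def rooted_on(self, outgroup: set[str]) -> "Phylogeny":
        """Re-root on the branch separating ``outgroup`` tips from the rest.

        The tree is treated as unrooted for this purpose.  Raises if no single
        branch splits exactly the outgroup from the ingroup (i.e. the outgroup
        is not monophyletic in the unrooted sense).
        """
        all_tips = set(self.tip_labels())
        if not outgroup <= all_tips:
            raise KeyError(f"outgroup tips absent: {sorted(outgroup - all_tips)}")
        if not outgroup:
            raise ValueError("empty outgroup")
        if outgroup == all_tips:
            raise ValueError("outgroup cannot contain every tip")
        current = self.clade_tips(self.root.children[0]) if self.root.children else set()
        if len(self.root.children) == 2 and current in (frozenset(outgroup),
                                                       frozenset(all_tips - outgroup)):
            return self.copy()
        # delegate the edge surgery to dendropy
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
        dtree.is_rooted = True
        target = None
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            if below == outgroup or (all_tips - below) == outgroup:
                target = edge
                break
        if target is None:
            raise ValueError("outgroup is not monophyletic; cannot place root")
        if target.length is not None:
            dtree.reroot_at_edge(target, length1=target.length / 2,
                                 length2=target.length / 2)
        else:
            dtree.reroot_at_edge(target)
        dtree.suppress_unifurcations()
        return parse_newick(dtree.as_string(schema="newick",
                                            unquoted_underscores=True))

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        return write_newick(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return _node_eq(self.root, other.root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny({self.n_tips()} tips)"


def _sum_len(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _node_eq(a: Node, b: Node) -> bool:
    if a.label != b.label or a.length != b.length:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(_node_eq(x, y) for x, y in zip(a.children, b.children))


def parse_newick(text: str) -> Phylogeny:
    """Parse one newick tree into a :class:`Phylogeny`.

    Quoted labels and scientific-notation branch lengths are accepted;
    internal-node labels (support values) are kept on the node but ignored by
    every downstream analysis.  Malformed input raises ``ValueError`` with the
    parser's position report.
    """
    if not text.strip():
        raise ValueError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        n = Node(label, dnode.edge.length)
        for ch in dnode.child_nodes():
            n.add_child(convert(ch))
        return n

    return Phylogeny(convert(dtree.seed_node))


def _fmt_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to newick; ``parse_newick(write_newick(t)) == t``."""

    def rec(n: Node) -> str:
        if n.is_leaf:
            s = _fmt_label(n.label if n.label is not None else "")
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.label:
                s += _fmt_label(n.label)
        if n.length is not None:
            s += ":" + _fmt_length(n.length)
        return s

    return rec(tree.root) + ";"
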