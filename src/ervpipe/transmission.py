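"""Interclass transmission counting on a host-group-labeled virus tree.

Ancestral host states deep in a retrovirus phylogeny cannot be reconstructed
unambiguously, so transmission between major host lineages is counted only
where it is unambiguous: after collapsing every maximal clade whose tips all
come from one host group into a single group-labeled leaf, each cherry whose
two leaves carry different groups witnesses one undirected transmission
event between those groups.  The result is an undirected weighted network
over host groups; direction is never inferred, and the counts are biased
toward recent transmissions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .phylo import Node, Phylogeny

logger = logging.getLogger("ervpipe.transmission")

HABITATS = ("aquatic", "terrestrial", "both")


@dataclass(frozen=True)
class HostGroupMap:
    """tip -> host group (class; order for paraphyletic reptiles), and an
    optional tip -> habitat layer for the water-land annotation."""

    groups: Mapping[str, str]
    habitats: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not g for g in self.groups.values()):
            raise ValueError("empty group name")
        bad = set(self.habitats.values()) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitats: {sorted(bad)}")


def collapse_by_group(tree: Phylogeny, groups: HostGroupMap) -> Phylogeny:
    """Collapse maximal single-group clades to one leaf each.

    Every maximal clade whose tips all share one host group becomes a single
    leaf labeled with that group (labels repeat across the tree); the
    remaining topology is unchanged.  Each collapsed leaf remembers the tips
    it absorbed (``_collapsed_tips`` attribute is emulated via the node label
    plus a side table returned on the tree object).
    """
    unmapped = set(tree.tip_labels()) - set(groups.groups)
    if unmapped:
        raise ValueError(f"tips without group mapping: {sorted(unmapped)}")

    group_of: dict[int, Optional[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            group_of[id(node)] = groups.groups[node.label]
        else:
            gs = {group_of[id(c)] for c in node.children}
            group_of[id(node)] = gs.pop() if len(gs) == 1 and None not in gs else None

    members: dict[int, list[str]] = {}

    def rebuild(node: Node) -> Node:
        g = group_of[id(node)]
        if g is not None:
            leaf = Node(g)
            members[id(leaf)] = [n.label for n in node.leaves()] if not node.is_leaf \
                else [node.label]
            return leaf
        new = Node(node.label, node.length)
        for c in node.children:
            new.add_child(rebuild(c))
        return new

    root = rebuild(tree.root)
    collapsed = Phylogeny(root, require_unique=False)
    collapsed.collapsed_members = {  # type: ignore[attr-defined]
        id(n): members.get(id(n), [n.label]) for n in collapsed.tips()}
    logger.info("collapsed %d tips into %d group leaves",
                tree.n_tips(), collapsed.n_tips())
    return collapsed


def _cherries(tree: Phylogeny) -> list[tuple[Node, Node]]:
    out = []
    for node in tree.postorder():
        if len(node.children) == 2 and all(c.is_leaf for c in node.children):
            out.append((node.children[0], node.children[1]))
    return out


def count_terminal_transmissions(collapsed: Phylogeny) -> nx.Graph:
    """Undirected transmission network from mixed cherries.

    Each cherry of the collapsed tree whose two leaf groups differ adds one
    event to the edge between those groups.  Equal-group cherries cannot
    survive collapsing; encountering one indicates the input was not a
    collapsed tree.
    """
    net = nx.Graph()
    for leaf in collapsed.tips():
        net.add_node(leaf.label)
    for a, b in _cherries(collapsed):
        if a.label == b.label:
            raise ValueError(
                f"equal-group cherry ({a.label}) — input is not a collapsed tree")
        if net.has_edge(a.label, b.label):
            net[a.label][b.label]["weight"] += 1
        else:
            net.add_edge(a.label, b.label, weight=1)
    return net


def annotate_habitat_transitions(collapsed: Phylogeny,
                                 groups: HostGroupMap) -> int:
    """Count cherries bridging water and land.

    A collapsed leaf's habitat is the habitat shared by all tips it absorbed,
    or ``both`` if they disagree.  A cherry counts iff one leaf is aquatic
    and the other terrestrial; ``both`` matches either side and never counts.
    """
    if not groups.habitats:
        raise ValueError("no habitat labels supplied")
    members: dict[int, list[str]] = getattr(
        collapsed, "collapsed_members",
        {id(n): [n.label] for n in collapsed.tips()})

    def leaf_habitat(leaf: Node) -> str:
        tips = members.get(id(leaf), [leaf.label])
        habs = set()
        for t in tips:
            if t not in groups.habitats:
                raise ValueError(f"tip {t!r} has no habitat label")
            habs.add(groups.habitats[t])
        return habs.pop() if len(habs) == 1 else "both"

    count = 0
    for a, b in _cherries(collapsed):
        pair = {leaf_habitat(a), leaf_habitat(b)}
        if pair == {"aquatic", "terrestrial"}:
            count += 1
    return count


def network_edges(net: nx.Graph) -> list[tuple[str, str, int]]:
    """Edge list (group_a < group_b lexicographically, weight)."""
    return sorted((min(a, b), max(a, b), d["weight"])
                  for a, b, d in net.edges(data=True))


def write_network(net: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_a\tgroup_b\tweight\n")
        for a, b, w in network_edges(net):
            fh.write(f"{a}\t{b}\t{w}\n")
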