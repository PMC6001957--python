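"""Synthetic benchmark instances for the host-virus congruence tests.

The published congruence analysis reports, for each retroviral lineage
tested, the minimal reconciliation cost under three cost schemes together
with event-count ranges and a random-tree p-value.  The underlying
tanglegrams are figures, not machine-readable data, so this module provides
*synthetic stand-in* instances constructed to have the same reconciliation
structure as the published summaries:

* ``codivergent_lineage_instance`` — the strongly codiverging fish
  foamy-like lineage: an 11-tip host/virus pair whose trees are congruent
  except for a single host switch.  Its optimal reconciliation has 9
  cospeciations and 1 duplication & host switch (totals -9 / 1 / 2 under
  the schemes (-1,0,0,0,0) / (0,1,1,2,0) / (0,1,2,1,1)).
* ``switch_rich_lineage_instance`` — a larger fish lineage whose viruses
  mostly host-switched: 37 virus tips over 20 hosts with a 14-tip
  codivergent backbone, so an exact optimizer attains at least 13
  cospeciations (total <= -13 when cospeciation alone is rewarded).

These are fixtures with known structure, not transcriptions of real trees.
"""

from __future__ import annotations

from .cophylogeny import CophylogenyProblem
from .phylo import Node, Phylogeny

__all__ = ["codivergent_lineage_instance", "switch_rich_lineage_instance"]


def _caterpillar(labels: list[str]) -> Node:
    """((l0,l1),l2),l3)... — first two labels form the basal cherry."""
    node = Node()
    node.add_child(Node(labels[0]))
    node.add_child(Node(labels[1]))
    for lab in labels[2:]:
        top = Node()
        top.add_child(node)
        top.add_child(Node(lab))
        node = top
    return node


def codivergent_lineage_instance() -> CophylogenyProblem:
    """11 hosts, 11 viruses, congruent up to one host switch.

    Hosts form a caterpillar fish01..fish11; the virus tree mirrors it
    except that the virus of fish11 sits next to the virus of fish01, which
    a single duplication & host switch at the basal virus cherry explains.
    """
    hosts = [f"fish{i:02d}" for i in range(1, 12)]
    host = Phylogeny(_caterpillar(hosts))
    virus_order = ["tuv01", "tuv11"] + [f"tuv{i:02d}" for i in range(2, 11)]
    virus = Phylogeny(_caterpillar(virus_order))
    assoc = {f"tuv{i:02d}": {f"fish{i:02d}"} for i in range(1, 12)}
    return CophylogenyProblem(host, virus, assoc)


def switch_rich_lineage_instance() -> CophylogenyProblem:
    """37 virus tips on 20 hosts: a 14-tip codivergent backbone plus
    within-host duplicates and cross-host jumpers.

    The backbone alone yields 13 cospeciations, so the minimal total under
    the cospeciation-rewarding scheme (-1,0,0,0,0) is at most -13.
    """
    hosts = [f"sp{i:02d}" for i in range(1, 21)]
    host = Phylogeny(_caterpillar(hosts))
    assoc: dict[str, set[str]] = {}

    def leaf(name: str, host_tip: str) -> Node:
        assoc[name] = {host_tip}
        return Node(name)

    # codivergent backbone over sp01..sp14; the first nine backbone tips are
    # doubled in place (duplications)
    def backbone_tip(i: int) -> Node:
        name = f"mv{i:02d}"
        if i <= 9:
            cherry = Node()
            cherry.add_child(leaf(name + "a", f"sp{i:02d}"))
            cherry.add_child(leaf(name + "b", f"sp{i:02d}"))
            return cherry
        return leaf(name, f"sp{i:02d}")

    node = Node()
    node.add_child(backbone_tip(1))
    node.add_child(backbone_tip(2))
    jumper_hosts = [f"sp{h:02d}" for h in (20, 15, 19, 16, 18, 17, 20, 15,
                                           19, 16, 18, 17, 20, 15)]
    for i in range(3, 15):
        top = Node()
        top.add_child(node)
        top.add_child(backbone_tip(i))
        node = top
        # a cross-host jumper rides above each backbone level
        j = i - 3
        top = Node()
        top.add_child(node)
        top.add_child(leaf(f"xv{j:02d}", jumper_hosts[j]))
        node = top
    for j in range(12, 14):
        top = Node()
        top.add_child(node)
        top.add_child(leaf(f"xv{j:02d}", jumper_hosts[j]))
        node = top
    virus = Phylogeny(node)
    return CophylogenyProblem(host, virus, assoc)
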