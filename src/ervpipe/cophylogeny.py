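"""Event-based reconciliation of a virus tree onto a host tree.

The model maps every virus-tree node onto the host tree and explains each
internal virus divergence by one of three events — cospeciation (the virus
splits because its host split), duplication (the virus splits within one
host lineage) or duplication & host switching (one daughter stays, the other
jumps to a host branch that is neither an ancestor nor a descendant of the
current one).  Two further events are counted along the way: a loss each
time a virus lineage rides through a host speciation without diverging, and
a failure to diverge for every extra host tip a single virus tip remains
associated with.  Each event type carries a real-valued (possibly negative)
cost and the reconciliation minimizes the summed cost.

The model is untimed: host switches may target any non-ancestral,
non-descendant branch.  This makes the optimum computable exactly by dynamic
programming in O(|virus| * |host|^2), unlike heuristic timed searches.
Event-count ranges over all co-optimal reconciliations are obtained exactly
at any problem size by re-running the DP with a lexicographic secondary
objective (minimize/maximize one event's count among minimum-cost
solutions).  Congruence is assessed against a null of uniformly distributed
random labeled virus-tree topologies with the tip associations held fixed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .phylo import Node, Phylogeny

__all__ = [
    "CostScheme", "CophylogenyProblem", "ReconciliationResult",
    "PermutationTestResult", "reconcile", "brute_force_reconcile",
    "random_parasite_test", "random_topology", "summarize_table",
    "EVENT_NAMES", "DEFAULT_SCHEMES",
]

EVENT_NAMES = ("cospeciation", "duplication", "duplication_host_switch",
               "loss", "failure_to_diverge")

_INF = float("inf")


@dataclass(frozen=True)
class CostScheme:
    """Per-event costs, in the order cospeciation, duplication,
    duplication & host switching, loss, failure to diverge."""

    cospeciation: float
    duplication: float
    duplication_host_switch: float
    loss: float
    failure_to_diverge: float

    def __post_init__(self) -> None:
        for name in EVENT_NAMES:
            v = getattr(self, name)
            if not (v == v and abs(v) != _INF):
                raise ValueError(f"{name} cost must be finite")

    def as_vector(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in EVENT_NAMES)

    @classmethod
    def from_string(cls, text: str) -> "CostScheme":
        parts = [float(x) for x in text.replace("−", "-").split(",")]
        if len(parts) != 5:
            raise ValueError("scheme needs 5 comma-separated costs")
        return cls(*parts)

    def label(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if x == int(x) else str(x)
        return ",".join(fmt(v) for v in self.as_vector())


#: the three published cost schemes (default first: Jane's default setting)
DEFAULT_SCHEMES = (
    CostScheme(0, 1, 2, 1, 1),
    CostScheme(-1, 0, 0, 0, 0),
    CostScheme(0, 1, 1, 2, 0),
)


@dataclass
class CophylogenyProblem:
    host_tree: Phylogeny
    virus_tree: Phylogeny
    associations: Mapping[str, set[str]]

    def __post_init__(self) -> None:
        for name, tree in (("host", self.host_tree), ("virus", self.virus_tree)):
            if not tree.is_binary():
                raise ValueError(f"{name} tree is not binary; resolve "
                                 "multifurcations before reconciling")
        host_tips = set(self.host_tree.tip_labels())
        for vt in self.virus_tree.tip_labels():
            hosts = self.associations.get(vt)
            if not hosts:
                raise ValueError(f"virus tip {vt!r} has no host association")
            missing = set(hosts) - host_tips
            if missing:
                raise ValueError(
                    f"virus tip {vt!r} associated to unknown hosts {sorted(missing)}")


@dataclass
class ReconciliationResult:
    total_cost: float
    event_counts: dict[str, tuple[int, int]]
    witness: dict[str, tuple[str, str]]  # virus node id -> (host node id, event)
    witness_counts: dict[str, int]
    exact_ranges: bool = True

    def count_range(self, event: str) -> tuple[int, int]:
        return self.event_counts[event]


@dataclass(frozen=True)
class PermutationTestResult:
    observed_cost: float
    n_random: int
    n_better_or_equal: int
    p: float
    seed: int


# ---------------------------------------------------------------------------
# host / virus indexing
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-indexed rooted binary tree with O(1) comparability tests."""

    def __init__(self, tree: Phylogeny):
        self.nodes: list[Node] = list(tree.postorder())
        self.n = len(self.nodes)
        id2i = {id(n): i for i, n in enumerate(self.nodes)}
        self.kids: list[Optional[tuple[int, int]]] = []
        for n in self.nodes:
            if n.is_leaf:
                self.kids.append(None)
            elif len(n.children) == 2:
                self.kids.append((id2i[id(n.children[0])],
                                  id2i[id(n.children[1])]))
            else:
                raise ValueError("tree is not binary")
        self.root = self.n - 1
        self.tips = {n.label: i for i, n in enumerate(self.nodes) if n.is_leaf}
        self.parent = [-1] * self.n
        for i, k in enumerate(self.kids):
            if k:
                self.parent[k[0]] = i
                self.parent[k[1]] = i
        # preorder intervals + depth for ancestry tests and loss distances
        self.tin = [0] * self.n
        self.tout = [0] * self.n
        self.depth = [0] * self.n
        timer = 0
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            i, done = stack.pop()
            if done:
                self.tout[i] = timer
                continue
            self.tin[i] = timer
            timer += 1
            stack.append((i, True))
            if self.kids[i]:
                for c in self.kids[i]:
                    self.depth[c] = self.depth[i] + 1
                    stack.append((c, False))

    def is_anc_or_self(self, a: int, b: int) -> bool:
        """Is b inside the subtree rooted at a (including a itself)?"""
        return self.tin[a] <= self.tin[b] < self.tout[a]

    def comparable(self, a: int, b: int) -> bool:
        return self.is_anc_or_self(a, b) or self.is_anc_or_self(b, a)

    def descendants(self, a: int) -> range:
        """Postorder guarantees nothing about contiguity; use tin scan."""
        return [i for i in range(self.n) if self.is_anc_or_self(a, i)]

    def mrca(self, ids: Iterable[int]) -> int:
        ids = list(ids)
        cur = ids[0]
        for other in ids[1:]:
            while not self.is_anc_or_self(cur, other):
                cur = self.parent[cur]
        return cur


def _tip_placements(hi: _TreeIndex, hosts: set[str],
                    ) -> tuple[int, int, int]:
    """Placement of a virus tip: (host node, n_ftd, n_losses).

    A multi-host tip maps to the MRCA of its hosts; the lineage persists
    through every branching node of the hosts' Steiner tree (one failure to
    diverge per extra host) and rides through pass-through speciations on
    that Steiner tree as losses.
    """
    ids = [hi.tips[h] for h in hosts]
    if len(ids) == 1:
        return ids[0], 0, 0
    m = hi.mrca(ids)
    steiner: set[int] = set()
    for t in ids:
        cur = t
        while cur != m:
            steiner.add(cur)
            cur = hi.parent[cur]
    steiner.add(m)
    ftd = losses = 0
    for x in steiner:
        k = hi.kids[x]
        if k is None:
            continue
        inside = (k[0] in steiner) + (k[1] in steiner)
        if inside == 2:
            ftd += 1
        elif inside == 1:
            losses += 1
    return m, ftd, losses


# ---------------------------------------------------------------------------
# dynamic program (scalar, cost only)
# ---------------------------------------------------------------------------

def _dp_cost(hi: _TreeIndex, vi: _TreeIndex,
             assoc: Mapping[str, set[str]], costs: CostScheme) -> float:
    cw, dw, tw, lw, fw = costs.as_vector()
    H = hi.n
    C: list[Optional[list[float]]] = [None] * vi.n
    IN: list[Optional[list[float]]] = [None] * vi.n

    def make_in(c: list[float]) -> list[float]:
        inn = [0.0] * H
        for h in range(H):  # postorder: children before parents
            k = hi.kids[h]
            best = c[h]
            if k:
                for ch in k:
                    cand = inn[ch] + lw
                    if cand < best:
                        best = cand
                inn[h] = best
            else:
                inn[h] = best
        return inn

    for v in range(vi.n):
        if vi.kids[v] is None:
            col = [_INF] * H
            m, ftd, losses = _tip_placements(hi, assoc[vi.nodes[v].label])
            col[m] = ftd * fw + losses * lw
        else:
            v1, v2 = vi.kids[v]
            c1, c2 = C[v1], C[v2]
            in1, in2 = IN[v1], IN[v2]
            # best placement over incomparable hosts, per host node
            out1 = _best_incomparable(hi, c1)
            out2 = _best_incomparable(hi, c2)
            col = [_INF] * H
            for h in range(H):
                best = dw + in1[h] + in2[h]
                k = hi.kids[h]
                if k:
                    a = cw + in1[k[0]] + in2[k[1]]
                    b = cw + in1[k[1]] + in2[k[0]]
                    if a < best:
                        best = a
                    if b < best:
                        best = b
                sw = tw + min(in1[h] + out2[h], in2[h] + out1[h])
                if sw < best:
                    best = sw
                col[h] = best
        C[v] = col
        IN[v] = make_in(col)
    return min(C[vi.root])


def _best_incomparable(hi: _TreeIndex, c: list[float]) -> list[float]:
    out = [_INF] * hi.n
    finite = [y for y in range(hi.n) if c[y] < _INF]
    for h in range(hi.n):
        best = _INF
        for y in finite:
            if not hi.comparable(h, y) and c[y] < best:
                best = c[y]
        out[h] = best
    return out


# ---------------------------------------------------------------------------
# dynamic program (lexicographic secondary objective + witness traceback)
# ---------------------------------------------------------------------------

def _dp_lex(hi: _TreeIndex, vi: _TreeIndex, assoc: Mapping[str, set[str]],
            costs: CostScheme, sec: tuple[float, ...],
            ) -> tuple[float, float]:
    """Minimize (total cost, sum of per-event secondary weights) lexically."""
    cw, dw, tw, lw, fw = costs.as_vector()
    sc, sd, st, sl, sf = sec
    INFV = (_INF, 0.0)
    H = hi.n
    C: list[Optional[list[tuple[float, float]]]] = [None] * vi.n
    IN: list[Optional[list[tuple[float, float]]]] = [None] * vi.n

    for v in range(vi.n):
        if vi.kids[v] is None:
            col = [INFV] * H
            m, ftd, losses = _tip_placements(hi, assoc[vi.nodes[v].label])
            col[m] = (ftd * fw + losses * lw, ftd * sf + losses * sl)
        else:
            v1, v2 = vi.kids[v]
            in1, in2 = IN[v1], IN[v2]
            out1 = _best_incomparable_lex(hi, C[v1])
            out2 = _best_incomparable_lex(hi, C[v2])
            col = []
            for h in range(H):
                a1, b1 = in1[h]
                a2, b2 = in2[h]
                best = (dw + a1 + a2, sd + b1 + b2)
                k = hi.kids[h]
                if k:
                    for x, y in ((k[0], k[1]), (k[1], k[0])):
                        p1, q1 = in1[x]
                        p2, q2 = in2[y]
                        cand = (cw + p1 + p2, sc + q1 + q2)
                        if cand < best:
                            best = cand
                for inn, out in ((in1[h], out2[h]), (in2[h], out1[h])):
                    cand = (tw + inn[0] + out[0], st + inn[1] + out[1])
                    if cand < best:
                        best = cand
                col.append(best)
        C[v] = col
        inn = [INFV] * H
        for h in range(H):
            k = hi.kids[h]
            best = col[h]
            if k:
                for ch in k:
                    cand = (inn[ch][0] + lw, inn[ch][1] + sl)
                    if cand < best:
                        best = cand
            inn[h] = best
        IN[v] = inn
    return min(C[vi.root])


def _best_incomparable_lex(hi: _TreeIndex, c: list[tuple[float, float]],
                           ) -> list[tuple[float, float]]:
    out = []
    finite = [y for y in range(hi.n) if c[y][0] < _INF]
    for h in range(hi.n):
        best = (_INF, 0.0)
        for y in finite:
            if not hi.comparable(h, y) and c[y] < best:
                best = c[y]
        out.append(best)
    return out


def _witness(hi: _TreeIndex, vi: _TreeIndex, assoc: Mapping[str, set[str]],
             costs: CostScheme,
             ) -> tuple[float, dict[str, tuple[str, str]], dict[str, int]]:
    """Traceback of one minimum-cost mapping from the scalar DP tables."""
    cw, dw, tw, lw, fw = costs.as_vector()
    H = hi.n
    C: list[list[float]] = []
    IN: list[list[float]] = []
    for v in range(vi.n):
        if vi.kids[v] is None:
            col = [_INF] * H
            m, ftd, losses = _tip_placements(hi, assoc[vi.nodes[v].label])
            col[m] = ftd * fw + losses * lw
        else:
            v1, v2 = vi.kids[v]
            in1, in2 = IN[v1], IN[v2]
            out1 = _best_incomparable(hi, C[v1])
            out2 = _best_incomparable(hi, C[v2])
            col = []
            for h in range(H):
                best = dw + in1[h] + in2[h]
                k = hi.kids[h]
                if k:
                    best = min(best, cw + in1[k[0]] + in2[k[1]],
                               cw + in1[k[1]] + in2[k[0]])
                best = min(best, tw + in1[h] + out2[h], tw + in2[h] + out1[h])
                col.append(best)
        C.append(col)
        inn = [0.0] * H
        for h in range(H):
            k = hi.kids[h]
            best = col[h]
            if k:
                best = min(best, inn[k[0]] + lw, inn[k[1]] + lw)
            inn[h] = best
        IN.append(inn)

    total = min(C[vi.root])
    counts = dict.fromkeys(EVENT_NAMES, 0)
    mapping: dict[str, tuple[str, str]] = {}

    def vname(v: int) -> str:
        node = vi.nodes[v]
        return node.label if node.is_leaf else f"virus_node_{v}"

    def hname(h: int) -> str:
        node = hi.nodes[h]
        return node.label if node.is_leaf else f"host_node_{h}"

    def descend(v: int, h: int) -> int:
        """Resolve IN[v][h]: walk down charging losses, return mapping node."""
        while abs(C[v][h] - IN[v][h]) > 1e-9:
            k = hi.kids[h]
            nxt = None
            for ch in k:
                if abs(IN[v][ch] + lw - IN[v][h]) <= 1e-9:
                    nxt = ch
                    break
            assert nxt is not None, "inconsistent DP traceback"
            counts["loss"] += 1
            h = nxt
        return h

    def trace(v: int, h: int) -> None:
        """Explain C[v][h] (v mapped exactly at h)."""
        if vi.kids[v] is None:
            _, ftd, losses = _tip_placements(hi, assoc[vi.nodes[v].label])
            counts["failure_to_diverge"] += ftd
            counts["loss"] += losses
            mapping[vname(v)] = (hname(h), "tip")
            return
        v1, v2 = vi.kids[v]
        val = C[v][h]
        k = hi.kids[h]
        if k:
            for x, y in ((k[0], k[1]), (k[1], k[0])):
                if abs(cw + IN[v1][x] + IN[v2][y] - val) <= 1e-9:
                    counts["cospeciation"] += 1
                    mapping[vname(v)] = (hname(h), "cospeciation")
                    trace(v1, descend(v1, x))
                    trace(v2, descend(v2, y))
                    return
        if abs(dw + IN[v1][h] + IN[v2][h] - val) <= 1e-9:
            counts["duplication"] += 1
            mapping[vname(v)] = (hname(h), "duplication")
            trace(v1, descend(v1, h))
            trace(v2, descend(v2, h))
            return
        out1 = _best_incomparable(hi, C[v1])
        out2 = _best_incomparable(hi, C[v2])
        for stay, move, out in ((v1, v2, out2), (v2, v1, out1)):
            if abs(tw + IN[stay][h] + out[h] - val) <= 1e-9:
                counts["duplication_host_switch"] += 1
                mapping[vname(v)] = (hname(h), "duplication_host_switch")
                trace(stay, descend(stay, h))
                target = next(y for y in range(H)
                              if not hi.comparable(h, y)
                              and abs(C[move][y] - out[h]) <= 1e-9)
                trace(move, target)
                return
        raise AssertionError("witness traceback failed")

    h_root = min(range(H), key=lambda h: C[vi.root][h])
    trace(vi.root, h_root)
    return total, mapping, counts


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def reconcile(problem: CophylogenyProblem, costs: CostScheme,
              ranges: bool = True) -> ReconciliationResult:
    """Minimum-cost reconciliation with exact event-count ranges.

    ``ranges=False`` skips the ten secondary DPs and reports the witness
    mapping's counts as a degenerate range (used inside permutation tests,
    where only the total matters).
    """
    hi = _TreeIndex(problem.host_tree)
    vi = _TreeIndex(problem.virus_tree)
    assoc = problem.associations
    total, mapping, wcounts = _witness(hi, vi, assoc, costs)

    event_counts: dict[str, tuple[int, int]] = {}
    if ranges:
        for e, name in enumerate(EVENT_NAMES):
            ind = tuple(1.0 if i == e else 0.0 for i in range(5))
            _, lo = _dp_lex(hi, vi, assoc, costs, ind)
            neg = tuple(-x for x in ind)
            _, hi_neg = _dp_lex(hi, vi, assoc, costs, neg)
            event_counts[name] = (round(lo), round(-hi_neg))
    else:
        event_counts = {name: (wcounts[name], wcounts[name])
                        for name in EVENT_NAMES}
    return ReconciliationResult(
        total_cost=total, event_counts=event_counts, witness=mapping,
        witness_counts=wcounts, exact_ranges=ranges)


def minimal_cost(problem: CophylogenyProblem, costs: CostScheme) -> float:
    """Just the minimum total cost (fast path)."""
    return _dp_cost(_TreeIndex(problem.host_tree),
                    _TreeIndex(problem.virus_tree),
                    problem.associations, costs)


def brute_force_reconcile(problem: CophylogenyProblem, costs: CostScheme,
                          max_tips: int = 8) -> ReconciliationResult:
    """Exhaustive-enumeration oracle for small virus trees.

    Enumerates, for every (virus node, host node) state, the full set of
    event-count vectors attainable at the state's minimum cost (a minimum-
    cost reconciliation is composed of minimum-cost sub-reconciliations of
    its own states, so nothing optimal is missed).  Independent of the
    lexicographic machinery in :func:`reconcile`.
    """
    if problem.virus_tree.n_tips() > max_tips:
        raise ValueError(f"brute force limited to {max_tips} virus tips")
    hi = _TreeIndex(problem.host_tree)
    vi = _TreeIndex(problem.virus_tree)
    w = costs.as_vector()
    H = hi.n
    E_COSP = (1, 0, 0, 0, 0)
    E_DUP = (0, 1, 0, 0, 0)
    E_DHS = (0, 0, 1, 0, 0)

    def cost_of(counts: tuple[int, ...]) -> float:
        return sum(c * x for c, x in zip(w, counts))

    def merge(acc: Optional[tuple[float, set]], cand: tuple[float, set],
              ) -> tuple[float, set]:
        if acc is None or cand[0] < acc[0] - 1e-9:
            return (cand[0], set(cand[1]))
        if abs(cand[0] - acc[0]) <= 1e-9:
            acc[1].update(cand[1])
        return acc

    def cross(a: tuple[float, set], b: tuple[float, set],
              extra: tuple[int, ...]) -> tuple[float, set]:
        counts = {tuple(x + y + e for x, y, e in zip(ca, cb, extra))
                  for ca in a[1] for cb in b[1]}
        return (a[0] + b[0] + cost_of(extra), counts)

    BEST: list[list[Optional[tuple[float, set]]]] = []
    ENTER: list[list[Optional[tuple[float, set]]]] = []
    for v in range(vi.n):
        if vi.kids[v] is None:
            m, ftd, losses = _tip_placements(hi, problem.associations[vi.nodes[v].label])
            counts = (0, 0, 0, losses, ftd)
            col: list[Optional[tuple[float, set]]] = [None] * H
            col[m] = (cost_of(counts), {counts})
        else:
            v1, v2 = vi.kids[v]
            en1, en2 = ENTER[v1], ENTER[v2]
            col = [None] * H
            for h in range(H):
                acc: Optional[tuple[float, set]] = None
                k = hi.kids[h]
                if k and en1[k[0]] and en2[k[1]]:
                    acc = merge(acc, cross(en1[k[0]], en2[k[1]], E_COSP))
                if k and en1[k[1]] and en2[k[0]]:
                    acc = merge(acc, cross(en1[k[1]], en2[k[0]], E_COSP))
                if en1[h] and en2[h]:
                    acc = merge(acc, cross(en1[h], en2[h], E_DUP))
                for stay, move in ((v1, v2), (v2, v1)):
                    if ENTER[stay][h] is None:
                        continue
                    for y in range(H):
                        if hi.comparable(h, y) or BEST[move][y] is None:
                            continue
                        acc = merge(acc, cross(ENTER[stay][h], BEST[move][y],
                                               E_DHS))
                col[h] = acc
        BEST.append(col)
        ent: list[Optional[tuple[float, set]]] = [None] * H
        for h in range(H):
            acc = None
            for y in hi.descendants(h):
                if col[y] is None:
                    continue
                dist = hi.depth[y] - hi.depth[h]
                shifted = (col[y][0] + dist * w[3],
                           {(c0, c1, c2, c3 + dist, c4)
                            for c0, c1, c2, c3, c4 in col[y][1]})
                acc = merge(acc, shifted)
            ent[h] = acc
        ENTER.append(ent)

    final: Optional[tuple[float, set]] = None
    for h in range(H):
        if BEST[vi.root][h] is not None:
            final = merge(final, BEST[vi.root][h])
    assert final is not None
    total, countset = final
    event_counts = {
        name: (min(c[i] for c in countset), max(c[i] for c in countset))
        for i, name in enumerate(EVENT_NAMES)
    }
    any_counts = next(iter(countset))
    return ReconciliationResult(
        total_cost=total, event_counts=event_counts, witness={},
        witness_counts=dict(zip(EVENT_NAMES, any_counts)), exact_ranges=True)


# ---------------------------------------------------------------------------
# random-topology null
# ---------------------------------------------------------------------------

def random_topology(labels: Sequence[str], rng: random.Random) -> Phylogeny:
    """Uniform random rooted binary labeled topology on ``labels``.

    Built by sequential random edge insertion: tip k+1 attaches to one of the
    2k-1 branches (including the root branch) uniformly, giving every one of
    the (2n-3)!! labeled rooted topologies equal probability.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    root = Node(labels[0])
    nodes = [root]
    for lab in labels[1:]:
        target = rng.choice(nodes)
        new_internal = Node()
        new_tip = Node(lab)
        parent = target.parent
        if parent is None:
            root = new_internal
        else:
            parent.children[parent.children.index(target)] = new_internal
            new_internal.parent = parent
        target.parent = None
        new_internal.add_child(target)
        new_internal.add_child(new_tip)
        nodes.extend([new_internal, new_tip])
    return Phylogeny(root)


def random_parasite_test(problem: CophylogenyProblem, costs: CostScheme,
                         n: int = 500, seed: int = 0,
                         ) -> PermutationTestResult:
    """Congruence test against n uniform random virus-tree topologies.

    p is the proportion of random topologies whose minimum reconciliation
    cost is <= the observed minimum (associations held fixed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    hi = _TreeIndex(problem.host_tree)
    observed = _dp_cost(hi, _TreeIndex(problem.virus_tree),
                        problem.associations, costs)
    rng = random.Random(seed)
    labels = problem.virus_tree.tip_labels()
    hits = 0
    for _ in range(n):
        topo = random_topology(labels, rng)
        cost = _dp_cost(hi, _TreeIndex(topo), problem.associations, costs)
        if cost <= observed + 1e-9:
            hits += 1
    return PermutationTestResult(observed_cost=observed, n_random=n,
                                 n_better_or_equal=hits, p=hits / n, seed=seed)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarize_table(problems: Mapping[str, CophylogenyProblem],
                    schemes: Sequence[CostScheme],
                    n_random: int = 500, seed: int = 0) -> pd.DataFrame:
    """One row per (problem, scheme): total cost, event-count ranges, p.

    Column order follows the congruence-test table: cospeciation,
    duplication, duplication & host switching, loss, failure to diverge.
    """
    if not schemes:
        raise ValueError("empty scheme list")
    rows = []
    for name, problem in problems.items():
        for scheme in schemes:
            res = reconcile(problem, scheme)
            test = random_parasite_test(problem, scheme, n=n_random, seed=seed)
            row: dict[str, object] = {
                "test": name,
                "event_costs": scheme.label(),
                "total_cost": res.total_cost,
            }
            for ev in EVENT_NAMES:
                lo, hi = res.event_counts[ev]
                row[ev] = f"{lo}-{hi}" if lo != hi else str(lo)
            row["p_value"] = round(test.p, 3)
            row["n_random"] = test.n_random
            rows.append(row)
    return pd.DataFrame(rows)
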