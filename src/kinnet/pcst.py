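"""Prize-collecting Steiner tree (PCST) solver.

Given an undirected graph with positive edge weights w and non-negative
node prizes p, the unrooted PCST problem asks for a subtree T minimizing

    sum_{e in T} w(e)  +  sum_{v not in T} p(v),

i.e. pay for the edges you use and forfeit the prizes you fail to collect.

The solver implements the classic moat-growing (dual-growth) scheme of
Goemans and Williamson in its unrooted prize-collecting variant: every
node starts as an active cluster with a prize budget; clusters grow
uniform duals, merge when an edge becomes tight, and deactivate when
their budget is exhausted. The growth forest is then strong-pruned
(bottom-up removal of subtrees whose collected prize does not pay for
their connecting edge), which preserves the scheme's approximation
guarantee of 2 and is usually optimal in practice.

All tie-breaks are deterministic (events ordered by time, kind, index;
nodes processed in sorted order), so results are reproducible.

:func:`exact_pcst_bruteforce` is an independent exhaustive oracle for
small instances, used to verify the approximation guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

_EPS = 1e-12


@dataclass(frozen=True)
class PCSTInstance:
    """An undirected PCST instance: nodes, positive-weight edges, and
    non-negative node prizes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    prizes: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for u, v, w in self.edges:
            if w <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive weight {w}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge ({u}, {v}) has an endpoint outside the node set")
        for v in self.nodes:
            if self.prizes.get(v, 0.0) < 0:
                raise ValueError(f"negative prize at node {v}")

    @property
    def total_prize(self) -> float:
        return sum(self.prizes.get(v, 0.0) for v in self.nodes)

    def objective(self, tree_nodes: set[str], tree_edges: set[frozenset[str]]) -> float:
        edge_cost = sum(w for u, v, w in self.edges if frozenset((u, v)) in tree_edges)
        forfeited = sum(self.prizes.get(v, 0.0) for v in self.nodes if v not in tree_nodes)
        return edge_cost + forfeited


@dataclass(frozen=True)
class PCSTSolution:
    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    objective: float
    net_worth: float  # collected prize minus edge cost


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        self.parent[max(ra, rb)] = min(ra, rb)
        return min(ra, rb)


def _grow(nodes: list[str], edges: list[tuple[str, str, float]], prizes: dict[str, float]):
    """Moat-growing phase. Returns the list of merge edges (the growth
    forest, as index pairs into *nodes*)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    eidx = [(idx[u], idx[v], w) for u, v, w in edges]
    uf = _UnionFind(n)
    slack = [float(prizes.get(v, 0.0)) for v in nodes]  # remaining prize budget
    active = [s > _EPS for s in slack]
    load = [0.0] * len(eidx)  # dual already accumulated on each edge
    forest: list[tuple[int, int]] = []

    while True:
        # candidate events: edge tightness and cluster deactivation
        best = None  # (time, kind, index); kind 0 = edge, 1 = deactivation
        for ei, (u, v, w) in enumerate(eidx):
            cu, cv = uf.find(u), uf.find(v)
            if cu == cv:
                continue
            rate = int(active[cu]) + int(active[cv])
            if rate == 0:
                continue
            t = (w - load[ei]) / rate
            cand = (t, 0, ei)
            if best is None or cand < best:
                best = cand
        seen_roots = set()
        for i in range(n):
            r = uf.find(i)
            if r in seen_roots or not active[r]:
                continue
            seen_roots.add(r)
            cand = (slack[r], 1, r)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        dt, kind, target = best
        dt = max(dt, 0.0)
        # advance time: shrink active budgets, fatten moats on boundary edges
        for r in {uf.find(i) for i in range(n)}:
            if active[r]:
                slack[r] -= dt
        for ei, (u, v, w) in enumerate(eidx):
            cu, cv = uf.find(u), uf.find(v)
            if cu == cv:
                continue
            load[ei] += dt * (int(active[cu]) + int(active[cv]))
        if kind == 0:
            u, v, _ = eidx[target]
            cu, cv = uf.find(u), uf.find(v)
            merged_slack = slack[cu] + slack[cv]
            root = uf.union(cu, cv)
            slack[root] = merged_slack
            active[root] = merged_slack > _EPS
            forest.append((u, v))
        else:
            slack[target] = 0.0
            active[target] = False
    return forest


def _strong_prune(
    tree_nodes: list[str],
    tree_edges: list[tuple[str, str, float]],
    prizes: dict[str, float],
) -> tuple[set[str], set[frozenset[str]], float]:
    """Best strong-pruned subtree of a tree: try every node as root,
    bottom-up keep a child branch only if its net value exceeds the cost
    of the connecting edge. Returns (nodes, edges, net worth)."""
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in tree_nodes}
    for u, v, w in tree_edges:
        adj[u].append((v, w))
        adj[v].append((u, w))

    best: tuple[float, list[str]] | None = None  # (net, sorted nodes) for ties
    best_result: tuple[set[str], set[frozenset[str]]] | None = None
    for root in sorted(tree_nodes):
        # iterative post-order DP
        order: list[str] = []
        parent: dict[str, str | None] = {root: None}
        stack = [root]
        while stack:
            x = stack.pop()
            order.append(x)
            for y, _ in adj[x]:
                if y != parent.get(x):
                    parent[y] = x
                    stack.append(y)
        value = {v: float(prizes.get(v, 0.0)) for v in tree_nodes}
        keep_child: dict[str, list[tuple[str, float]]] = {v: [] for v in tree_nodes}
        for x in reversed(order):
            for y, w in adj[x]:
                if parent.get(y) == x:
                    # net-neutral branches are kept (ties resolve toward
                    # the larger tree; see _better)
                    if value[y] - w >= -_EPS:
                        value[x] += value[y] - w
                        keep_child[x].append((y, w))
        net = value[root]
        kept_nodes = {root}
        kept_edges: set[frozenset[str]] = set()
        stack = [root]
        while stack:
            x = stack.pop()
            for y, w in keep_child[x]:
                kept_nodes.add(y)
                kept_edges.add(frozenset((x, y)))
                stack.append(y)
        key = (-round(net / _EPS) * _EPS, -len(kept_nodes), sorted(kept_nodes))
        if best is None or key < best:
            best = key
            best_result = (kept_nodes, kept_edges)
    assert best is not None and best_result is not None
    return best_result[0], best_result[1], -best[0]


def solve_pcst(instance: PCSTInstance) -> PCSTSolution:
    """Solve unrooted PCST with the moat-growing 2-approximation.

    Works on arbitrary (possibly disconnected) instances; the growth phase
    naturally partitions the graph into clusters, each cluster tree is
    strong-pruned, and the tree with the highest net worth (collected
    prize − edge cost) is returned. Returns a single-node tree when no
    edge pays for itself.
    """
    nodes = sorted(instance.nodes)
    if not nodes:
        return PCSTSolution(frozenset(), frozenset(), 0.0, 0.0)
    edges = sorted(instance.edges)
    forest = _grow(nodes, list(edges), instance.prizes)

    # split the growth forest into its trees
    uf = _UnionFind(len(nodes))
    idx = {v: i for i, v in enumerate(nodes)}
    for iu, iv in forest:
        uf.union(iu, iv)
    comp_nodes: dict[int, list[str]] = {}
    for v in nodes:
        comp_nodes.setdefault(uf.find(idx[v]), []).append(v)
    weight = {frozenset((u, v)): w for u, v, w in edges}
    comp_edges: dict[int, list[tuple[str, str, float]]] = {r: [] for r in comp_nodes}
    for iu, iv in forest:
        u, v = nodes[iu], nodes[iv]
        comp_edges[uf.find(iu)].append((u, v, weight[frozenset((u, v))]))

    best: PCSTSolution | None = None
    for r in sorted(comp_nodes):
        kn, ke, net = _strong_prune(comp_nodes[r], comp_edges[r], instance.prizes)
        obj = instance.objective(kn, ke)
        cand = PCSTSolution(frozenset(kn), frozenset(ke), obj, net)
        if best is None or _better(cand, best):
            best = cand
    assert best is not None
    return best


def _better(a: PCSTSolution, b: PCSTSolution) -> bool:
    """Tie rule: higher net worth, then more nodes (kinase prizes exist to
    make collecting hub nodes worthwhile, so a net-neutral extension is
    taken), then lexicographically smallest node set."""
    if a.net_worth > b.net_worth + _EPS:
        return True
    if a.net_worth < b.net_worth - _EPS:
        return False
    if len(a.nodes) != len(b.nodes):
        return len(a.nodes) > len(b.nodes)
    return sorted(a.nodes) < sorted(b.nodes)


def exact_pcst_bruteforce(instance: PCSTInstance, max_nodes: int = 12) -> PCSTSolution:
    """Exhaustive PCST oracle: enumerate all connected node subsets, cost
    each with a minimum spanning tree, return the global optimum.

    Intended for verification only; refuses instances above *max_nodes*.
    Ties are broken as in :func:`_better` (larger node set first, then
    lexicographically smallest), so it is directly comparable with the
    approximate solver.
    """
    nodes = sorted(instance.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {len(nodes)}")
    if not nodes:
        return PCSTSolution(frozenset(), frozenset(), 0.0, 0.0)
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v, _ in instance.edges:
        adj[u].add(v)
        adj[v].add(u)

    def connected(sub: tuple[str, ...]) -> bool:
        subset = set(sub)
        seen = {sub[0]}
        stack = [sub[0]]
        while stack:
            x = stack.pop()
            for y in adj[x] & subset:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen == subset

    def mst(sub: tuple[str, ...]) -> tuple[float, set[frozenset[str]]] | None:
        subset = set(sub)
        cand = sorted(
            (w, u, v) for u, v, w in instance.edges if u in subset and v in subset
        )
        uf = _UnionFind(len(sub))
        idx = {v: i for i, v in enumerate(sub)}
        cost, chosen, used = 0.0, set(), 0
        for w, u, v in cand:
            if uf.find(idx[u]) != uf.find(idx[v]):
                uf.union(idx[u], idx[v])
                cost += w
                chosen.add(frozenset((u, v)))
                used += 1
        if used != len(sub) - 1:
            return None
        return cost, chosen

    best: PCSTSolution | None = None
    for size in range(1, len(nodes) + 1):
        for sub in combinations(nodes, size):
            if not connected(sub):
                continue
            m = mst(sub)
            if m is None:
                continue
            cost, chosen = m
            forfeited = sum(
                instance.prizes.get(v, 0.0) for v in nodes if v not in set(sub)
            )
            obj = cost + forfeited
            collected = sum(instance.prizes.get(v, 0.0) for v in sub)
            cand = PCSTSolution(frozenset(sub), frozenset(chosen), obj, collected - cost)
            if best is None or _better(cand, best):
                best = cand
    assert best is not None
    return best
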