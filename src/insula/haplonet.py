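"""Haplotype collapsing and median-joining networks.

Aligned control-region sequences are collapsed into haplotypes over
their variable substitution sites (indels set aside as annotated
events), and connected by a median-joining network: the epsilon-relaxed
minimum spanning network over observed haplotypes, iteratively augmented
with quasi-median ("median vector") sequences wherever they reduce
connection cost, with latent vertices of degree <= 2 pruned at the end.
Edge weights are mutational steps (Hamming distance over variable
sites). All tie-breaking is lexicographic on the haplotype state string,
so the result is invariant to input order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "IndelEvent",
    "collapse_haplotypes",
    "median_joining",
    "network_cost",
    "write_network",
    "read_network",
]


@dataclass
class IndelEvent:
    """A contiguous gap/insert interval, with presence per haplotype."""

    interval: tuple  # half-open alignment columns
    presence: dict = field(default_factory=dict)  # haplotype_id -> bool


@dataclass
class Haplotype:
    state: str  # bases at the variable substitution sites
    count: int
    members: list
    populations: dict = field(default_factory=dict)  # label -> count


@dataclass
class HaplotypeTable:
    haplotypes: dict  # haplotype_id -> Haplotype
    variable_sites: list  # 0-based alignment columns
    indel_events: list

    @property
    def n_sequences(self) -> int:
        return sum(h.count for h in self.haplotypes.values())


def collapse_haplotypes(
    sequences: dict,
    labels: dict | None = None,
    indel_policy: str = "annotate",
) -> HaplotypeTable:
    """Merge identical sequences over variable substitution sites.

    Columns containing a gap in any sequence are indel columns: maximal
    runs of adjacent indel columns form one indel event each (an 11-bp
    insertion is one event, not eleven). Substitution sites are the
    remaining polymorphic columns. ``indel_policy`` is ``"annotate"``
    (record events per haplotype) or ``"ignore"`` (drop them).
    """
    if not sequences:
        raise ValueError("no input sequences")
    if indel_policy not in ("annotate", "ignore"):
        raise ValueError(f"unknown indel_policy {indel_policy!r}")
    labels = labels or {}
    seqs = {k: v.upper() for k, v in sequences.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("sequences have unequal lengths")
    L = lengths.pop()
    names = list(seqs)

    gap_col = [any(seqs[n][j] == "-" for n in names) for j in range(L)]
    # maximal runs of gap columns -> indel event intervals
    intervals = []
    j = 0
    while j < L:
        if gap_col[j]:
            k = j
            while k < L and gap_col[k]:
                k += 1
            intervals.append((j, k))
            j = k
        else:
            j += 1

    variable_sites = [
        j
        for j in range(L)
        if not gap_col[j] and len({seqs[n][j] for n in names}) > 1
    ]

    groups: dict[str, list] = {}
    for n in names:
        key = "".join(seqs[n][j] for j in variable_sites)
        groups.setdefault(key, []).append(n)

    haplotypes: dict[str, Haplotype] = {}
    state_to_id: dict[str, str] = {}
    for i, state in enumerate(sorted(groups), start=1):
        members = groups[state]
        pops: dict[str, int] = {}
        for m in members:
            lab = labels.get(m, "")
            pops[lab] = pops.get(lab, 0) + 1
        hid = f"H{i}"
        haplotypes[hid] = Haplotype(
            state=state, count=len(members), members=sorted(members),
            populations=pops,
        )
        state_to_id[state] = hid

    events = []
    if indel_policy == "annotate":
        for start, end in intervals:
            presence = {}
            for state, hid in state_to_id.items():
                # present = majority of member columns carry a base (not a gap)
                votes = [
                    c != "-"
                    for m in haplotypes[hid].members
                    for c in seqs[m][start:end]
                ]
                presence[hid] = sum(votes) * 2 > len(votes)
            events.append(IndelEvent(interval=(start, end), presence=presence))

    return HaplotypeTable(
        haplotypes=haplotypes,
        variable_sites=variable_sites,
        indel_events=events,
    )


# --------------------------------------------------------- median joining

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(states: list, epsilon: int) -> list:
    """Epsilon-relaxed minimum spanning network over state strings.

    An edge (u, v) is included when d(u, v) <= (bottleneck connection
    distance of u and v) + epsilon, where the bottleneck distance is the
    minimax edge weight over paths — computed from a minimum spanning
    tree. With epsilon=0 this is the union of all minimum spanning
    trees.
    """
    states = sorted(states)
    n = len(states)
    if n < 2:
        return []
    d = {
        (i, j): _hamming(states[i], states[j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    # Kruskal MST with lexicographic tie-break (states are sorted)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for (i, j), w in sorted(d.items(), key=lambda kv: (kv[1], kv[0])):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((i, j, w))

    # bottleneck (minimax) distances via the MST
    adj = {i: [] for i in range(n)}
    for i, j, w in mst:
        adj[i].append((j, w))
        adj[j].append((i, w))
    bottleneck = [[0] * n for _ in range(n)]
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    bottleneck[src][nb] = max(mx, w)
                    stack.append((nb, max(mx, w)))

    return [
        (states[i], states[j], w)
        for (i, j), w in d.items()
        if w <= bottleneck[i][j] + epsilon
    ]


def _spanning_cost(states) -> int:
    """Minimum spanning tree cost of a state set under Hamming distance."""
    states = sorted(states)
    n = len(states)
    if n < 2:
        return 0
    in_tree = [False] * n
    dist = [len(states[0]) + 1] * n
    dist[0] = 0
    total = 0
    for _ in range(n):
        i = min(
            (j for j in range(n) if not in_tree[j]), key=lambda j: dist[j]
        )
        in_tree[i] = True
        total += dist[i]
        for j in range(n):
            if not in_tree[j]:
                d = _hamming(states[i], states[j])
                if d < dist[j]:
                    dist[j] = d
    return total


def _quasi_medians(u: str, v: str, w: str) -> set:
    """Quasi-median sequences of three states (majority per site; a
    three-way disagreement contributes each of the three values)."""
    per_site = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            per_site.append((a,))
        elif b == c:
            per_site.append((b,))
        else:
            per_site.append((a, b, c))
    return {"".join(p) for p in itertools.product(*per_site)}


def median_joining(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of the haplotype table.

    Iterates: build the epsilon-relaxed minimum spanning network over the
    current sequence set; for every pair of edges sharing a node, form the
    quasi-medians of the three endpoint states; among new medians, add
    those whose connection cost to their generating triple is within
    epsilon of the minimum. Terminates when no median is added, then
    prunes median vectors of degree <= 2 (a degree-2 Steiner point never
    shortens a path in Hamming space) and returns the final network as a
    ``networkx.Graph`` with ``steps`` edge weights.
    """
    observed = {h.state: hid for hid, h in table.haplotypes.items()}
    if len(observed) < 2:
        raise ValueError("median joining requires >= 2 distinct haplotypes")
    nodes = set(observed)

    for _ in range(10_000):
        edges = _msn_edges(sorted(nodes), epsilon)
        adj: dict[str, set] = {s: set() for s in nodes}
        for a, b, _w in edges:
            adj[a].add(b)
            adj[b].add(a)
        candidates: dict[str, int] = {}
        for u in sorted(nodes):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for m in _quasi_medians(u, v, w):
                    if m in nodes:
                        continue
                    lam = _hamming(m, u) + _hamming(m, v) + _hamming(m, w)
                    if m not in candidates or lam < candidates[m]:
                        candidates[m] = lam
        if not candidates:
            break
        lam_min = min(candidates.values())
        added = {m for m, lam in candidates.items() if lam <= lam_min + epsilon}
        nodes |= added
    else:  # pragma: no cover - bounded by site count in practice
        raise RuntimeError("median joining did not converge")

    # Prune unused median vectors: latent vertices of degree <= 2 in the
    # network (a degree-2 Steiner point never shortens a path in Hamming
    # space), and medians that do not reduce the connection cost of the
    # node set. The retained medians are a minimum-cost, then
    # minimum-cardinality, subset (exact search while the candidate set
    # is small, greedy single-removal beyond that).
    while True:
        edges = _msn_edges(sorted(nodes), epsilon)
        degree: dict[str, int] = {s: 0 for s in nodes}
        for a, b, _w in edges:
            degree[a] += 1
            degree[b] += 1
        prune = {s for s in nodes if s not in observed and degree[s] <= 2}
        if prune:
            nodes -= prune
            continue
        medians = sorted(s for s in nodes if s not in observed)
        if len(medians) <= 12:
            best = (_spanning_cost(nodes), len(medians), tuple(medians))
            for size in range(len(medians) + 1):
                for subset in itertools.combinations(medians, size):
                    cost = _spanning_cost(set(observed) | set(subset))
                    if (cost, size, subset) < best:
                        best = (cost, size, subset)
            keep = set(best[2])
        else:  # pragma: no cover - large networks only
            keep = set(medians)
            base = _spanning_cost(set(observed) | keep)
            improved = True
            while improved:
                improved = False
                for m in sorted(keep):
                    cost = _spanning_cost(set(observed) | (keep - {m}))
                    if cost <= base:
                        keep.discard(m)
                        base = cost
                        improved = True
                        break
        if keep == set(medians):
            break
        nodes = set(observed) | keep

    graph = nx.Graph(epsilon=epsilon)
    median_ids = {}
    n_median = 0
    for state in sorted(nodes):
        if state in observed:
            hid = observed[state]
            hap = table.haplotypes[hid]
            graph.add_node(
                hid,
                state=state,
                median=0,
                frequency=hap.count,
                populations=";".join(
                    f"{k or 'NA'}:{v}" for k, v in sorted(hap.populations.items())
                ),
            )
        else:
            n_median += 1
            mid = f"MV{n_median}"
            median_ids[state] = mid
            graph.add_node(mid, state=state, median=1, frequency=0,
                           populations="")
    name = lambda s: observed.get(s) or median_ids[s]
    for a, b, w in edges:
        graph.add_edge(name(a), name(b), steps=int(w))
    return graph


def network_cost(graph: nx.Graph) -> int:
    """Total mutational steps of a minimum spanning tree of the network."""
    mst = nx.minimum_spanning_tree(graph, weight="steps")
    return int(sum(d["steps"] for _u, _v, d in mst.edges(data=True)))


def write_network(graph: nx.Graph, path, fmt: str = "gml") -> None:
    from . import io

    if fmt == "gml":
        io.write_gml(graph, path)
    elif fmt == "dot":
        io.write_dot(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path) -> nx.Graph:
    from . import io

    g = io.read_gml(path)
    for _u, _v, d in g.edges(data=True):
        d["steps"] = int(d["steps"])
    for _n, d in g.nodes(data=True):
        d["median"] = int(d["median"])
        d["frequency"] = int(d["frequency"])
    return g
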