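"""Complete-network measures: degree, closeness, betweenness, brokerage.

Degree is counted on the directed tie list (in-degree: how many residents
name the person; out-degree: how many the person names).  Closeness and
betweenness are computed by default on the undirected projection of the
discussion network — a village discussion network is far from strongly
connected, and "all-closeness" on the projection is the convention that
keeps the measures informative there — with directed variants available.

The network is typically disconnected, so plain closeness (reciprocal of the
summed shortest-path lengths, scaled by N-1) is ill-defined.  The default
uses the Wasserman–Faust component correction: with R the set of nodes
reachable from i and d the geodesic distance,

    C(i) = |R|^2 / (sum_{j in R} d(i, j) * (N - 1)),

which equals the classical normalized closeness on a connected graph and
degrades gracefully on small components; isolates score 0.  Alternatives
(within-component normalization, harmonic closeness) are selectable.

Betweenness is Brandes' algorithm with fractional credit over equally short
paths, normalized by the number of pairs excluding the node:
(N-1)(N-2)/2 undirected, (N-1)(N-2) directed.

Brokerage follows Gould and Fernandez: each ordered two-path j -> i -> k
(j, k, i distinct) classifies broker i by the district memberships g(j),
g(i), g(k) into coordinator (all same), gatekeeper (outsider names i, i
names an insider), representative (insider names i, i names an outsider),
itinerant (j and k share a district foreign to i) and liaison (all three
distinct).  By default a two-path only counts when its endpoints are
disconnected otherwise (no direct tie between j and k in either direction);
the classic count that ignores direct ties is available as ``mode="classic"``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .network_assembly import CompleteNetwork

__all__ = [
    "BrokerageCounts",
    "adjacency",
    "degree",
    "closeness_norm",
    "betweenness_norm",
    "brokerage",
    "centrality_frame",
    "brokerage_frame",
]

NodeId = Hashable
ROLES = ("coordinator", "gatekeeper", "representative", "itinerant", "liaison")


@dataclass(frozen=True)
class BrokerageCounts:
    coordinator: int = 0
    gatekeeper: int = 0
    representative: int = 0
    itinerant: int = 0
    liaison: int = 0

    @property
    def total(self) -> int:
        return (
            self.coordinator
            + self.gatekeeper
            + self.representative
            + self.itinerant
            + self.liaison
        )


def _edges_nodes(
    network: CompleteNetwork | tuple,
) -> tuple[list[NodeId], list[tuple[NodeId, NodeId]]]:
    """Accept a CompleteNetwork or a raw (nodes, edges) pair."""
    if isinstance(network, CompleteNetwork):
        return sorted(network.nodes), sorted(network.ties)
    nodes, edges = network
    return sorted(nodes), sorted(edges)


def adjacency(
    network: CompleteNetwork | tuple, directed: bool = False
) -> dict[NodeId, list[NodeId]]:
    """Adjacency lists; the undirected projection merges both tie directions."""
    nodes, edges = _edges_nodes(network)
    adj: dict[NodeId, set[NodeId]] = {u: set() for u in nodes}
    for u, v in edges:
        if u == v:
            continue
        adj[u].add(v)
        if not directed:
            adj[v].add(u)
    return {u: sorted(adj[u]) for u in nodes}


def degree(network: CompleteNetwork | tuple) -> pd.DataFrame:
    """Per-node in/out-degree over the directed tie list."""
    nodes, edges = _edges_nodes(network)
    indeg = {u: 0 for u in nodes}
    outdeg = {u: 0 for u in nodes}
    for u, v in edges:
        outdeg[u] += 1
        indeg[v] += 1
    return pd.DataFrame(
        {"in_degree": [indeg[u] for u in nodes], "out_degree": [outdeg[u] for u in nodes]},
        index=pd.Index(nodes, name="node"),
    )


def _bfs_distances(adj: Mapping[NodeId, list[NodeId]], source: NodeId) -> dict[NodeId, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def closeness_norm(
    network: CompleteNetwork | tuple,
    directed: bool = False,
    variant: str = "wf",
) -> dict[NodeId, float]:
    """Normalized closeness per node (see module notes for the conventions).

    variant: "wf" (Wasserman–Faust component correction, default),
    "within_component" (|R| / sum of distances, no global scaling), or
    "harmonic" (mean reciprocal distance over all other nodes).
    In directed mode distances follow outgoing ties.
    """
    adj = adjacency(network, directed=directed)
    n = len(adj)
    out: dict[NodeId, float] = {}
    for u in adj:
        dist = _bfs_distances(adj, u)
        reach = len(dist) - 1  # |R|, excluding u itself
        tot = sum(dist.values())
        if variant == "harmonic":
            out[u] = (
                sum(1.0 / d for d in dist.values() if d > 0) / (n - 1) if n > 1 else 0.0
            )
            continue
        if reach == 0 or tot == 0:
            out[u] = 0.0
        elif variant == "wf":
            out[u] = (reach * reach) / (tot * (n - 1)) if n > 1 else 0.0
        elif variant == "within_component":
            out[u] = reach / tot
        else:
            raise ValueError(f"unknown closeness variant {variant!r}")
    return out


def betweenness_norm(
    network: CompleteNetwork | tuple, directed: bool = False
) -> dict[NodeId, float]:
    """Brandes shortest-path betweenness, normalized to [0, 1].

    Each pair (s, t) distributes one unit of credit over the interior nodes
    of its shortest paths, fractionally across equally short paths; the raw
    count is divided by the number of node pairs excluding the focal node.
    """
    adj = adjacency(network, directed=directed)
    nodes = list(adj)
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    for s in nodes:
        # single-source shortest paths with path counts (Brandes)
        stack: list[NodeId] = []
        pred: dict[NodeId, list[NodeId]] = {u: [] for u in nodes}
        sigma = {u: 0.0 for u in nodes}
        dist = {u: -1 for u in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {u: 0.0 for u in nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if not directed:
        for u in bc:
            bc[u] /= 2.0
        denom = (n - 1) * (n - 2) / 2.0
    else:
        denom = float((n - 1) * (n - 2))
    if denom > 0:
        for u in bc:
            bc[u] /= denom
    return bc


def brokerage(
    network: CompleteNetwork | tuple,
    groups: Mapping[NodeId, str],
    mode: str = "excluded",
) -> dict[NodeId, BrokerageCounts]:
    """Gould–Fernandez brokerage counts per node with district groups.

    mode="excluded" (default) counts a two-path j->i->k only when j and k
    have no direct tie in either direction — the broker connects two people
    who are disconnected otherwise.  mode="classic" counts every two-path.
    """
    if mode not in {"excluded", "classic"}:
        raise ValueError(f"unknown brokerage mode {mode!r}")
    nodes, edges = _edges_nodes(network)
    for u in nodes:
        if u not in groups:
            raise KeyError(f"node {u!r} has no district group")
    out_adj: dict[NodeId, set[NodeId]] = {u: set() for u in nodes}
    in_adj: dict[NodeId, set[NodeId]] = {u: set() for u in nodes}
    for u, v in edges:
        if u == v:
            continue
        out_adj[u].add(v)
        in_adj[v].add(u)
    counts = {u: dict.fromkeys(ROLES, 0) for u in nodes}
    for i in nodes:
        gi = groups[i]
        for j in in_adj[i]:
            for k in out_adj[i]:
                if k == j or k == i or j == i:
                    continue
                if mode == "excluded" and (k in out_adj[j] or j in out_adj[k]):
                    continue
                gj, gk = groups[j], groups[k]
                if gj == gi == gk:
                    role = "coordinator"
                elif gj != gi and gi == gk:
                    role = "gatekeeper"
                elif gj == gi and gi != gk:
                    role = "representative"
                elif gj == gk and gj != gi:
                    role = "itinerant"
                else:
                    role = "liaison"
                counts[i][role] += 1
    return {u: BrokerageCounts(**counts[u]) for u in nodes}


def centrality_frame(
    network: CompleteNetwork | tuple,
    directed: bool = False,
    closeness_variant: str = "wf",
) -> pd.DataFrame:
    """Degrees plus normalized closeness and betweenness, one row per node."""
    df = degree(network)
    clos = closeness_norm(network, directed=directed, variant=closeness_variant)
    btw = betweenness_norm(network, directed=directed)
    df["closeness_norm"] = [clos[u] for u in df.index]
    df["betweenness_norm"] = [btw[u] for u in df.index]
    return df


def brokerage_frame(
    network: CompleteNetwork | tuple,
    groups: Mapping[NodeId, str],
    mode: str = "excluded",
) -> pd.DataFrame:
    counts = brokerage(network, groups, mode=mode)
    nodes = sorted(counts)
    return pd.DataFrame(
        {role: [getattr(counts[u], role) for u in nodes] for role in ROLES}
        | {"total": [counts[u].total for u in nodes]},
        index=pd.Index(nodes, name="node"),
    )
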