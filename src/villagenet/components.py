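"""Weak/strong components, the five-class component typology and summaries.

A weak component is a maximal set of nodes mutually reachable when tie
direction is ignored; a strong component respects direction.  Village
discussion networks fragment into one dominant component, a handful of
mid-sized ones and many dyads and isolates, so components are summarised
through a five-class typology: the largest component, the second largest,
components of 3-7 nodes, dyads, and isolates.  Components of 8 or more
nodes outside the top two do not fit the typology; they are folded into the
3-7 class with a warning rather than given an invented sixth class.

Per-class summaries report node-level composition (counts, district shares)
and respondent-level survey measures (age, chronic conditions, network
size, marriage, self-rated health), with one-way ANOVA across classes for
each numeric column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import anova_oneway
from .network_assembly import CompleteNetwork
from .survey_io import PersonRecord

__all__ = [
    "ComponentPartition",
    "COMPONENT_CLASSES",
    "find_components",
    "classify_components",
    "summarize_classes",
]

NodeId = Hashable
COMPONENT_CLASSES = ("largest", "second_largest", "size_3_7", "dyadic", "isolate")


@dataclass
class ComponentPartition:
    assignment: dict[NodeId, int]
    sizes: dict[int, int]
    mode: str  # "weak" | "strong"

    def members(self, cid: int) -> list[NodeId]:
        return sorted(u for u, c in self.assignment.items() if c == cid)


def _edges_nodes(network: CompleteNetwork | tuple):
    if isinstance(network, CompleteNetwork):
        return sorted(network.nodes), sorted(network.ties)
    nodes, edges = network
    return sorted(nodes), sorted(edges)


def _weak_components(nodes, edges) -> list[list[NodeId]]:
    parent = {u: u for u in nodes}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            if rv < ru:
                ru, rv = rv, ru
            parent[rv] = ru
    comps: dict[NodeId, list[NodeId]] = {}
    for u in nodes:
        comps.setdefault(find(u), []).append(u)
    return list(comps.values())


def _strong_components(nodes, edges) -> list[list[NodeId]]:
    """Iterative Tarjan strongly connected components."""
    adj: dict[NodeId, list[NodeId]] = {u: [] for u in nodes}
    for u, v in edges:
        if u != v:
            adj[u].append(v)
    index: dict[NodeId, int] = {}
    low: dict[NodeId, int] = {}
    on_stack: set[NodeId] = set()
    stack: list[NodeId] = []
    sccs: list[list[NodeId]] = []
    counter = 0
    for root in nodes:
        if root in index:
            continue
        work = [(root, 0)]
        while work:
            u, pi = work[-1]
            if pi == 0:
                index[u] = low[u] = counter
                counter += 1
                stack.append(u)
                on_stack.add(u)
            advanced = False
            for vi in range(pi, len(adj[u])):
                v = adj[u][vi]
                if v not in index:
                    work[-1] = (u, vi + 1)
                    work.append((v, 0))
                    advanced = True
                    break
                if v in on_stack:
                    low[u] = min(low[u], index[v])
            if advanced:
                continue
            work.pop()
            if low[u] == index[u]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == u:
                        break
                sccs.append(comp)
            if work:
                pu = work[-1][0]
                low[pu] = min(low[pu], low[u])
    return sccs


def find_components(
    network: CompleteNetwork | tuple, mode: str = "weak"
) -> ComponentPartition:
    """Partition the nodes into weak or strong components.

    Component ids are assigned deterministically: components sorted by
    (descending size, smallest member id) get ids 0, 1, 2, ...
    """
    nodes, edges = _edges_nodes(network)
    if mode == "weak":
        comps = _weak_components(nodes, edges)
    elif mode == "strong":
        comps = _strong_components(nodes, edges)
    else:
        raise ValueError(f"unknown component mode {mode!r}")
    comps = sorted(comps, key=lambda c: (-len(c), min(c)))
    assignment = {u: cid for cid, comp in enumerate(comps) for u in comp}
    sizes = {cid: len(comp) for cid, comp in enumerate(comps)}
    return ComponentPartition(assignment=assignment, sizes=sizes, mode=mode)


def classify_components(partition: ComponentPartition) -> dict[NodeId, str]:
    """Map each node to its component class (see module notes).

    Rank 1 and 2 by size (ties broken by smallest member id) are "largest"
    and "second_largest" regardless of their absolute size; the rest bin by
    size: 1 isolate, 2 dyadic, 3-7 (and, with a warning, >= 8) size_3_7.
    """
    order = sorted(partition.sizes, key=lambda c: c)  # already ranked by id
    classes: dict[int, str] = {}
    for rank, cid in enumerate(order):
        size = partition.sizes[cid]
        if rank == 0:
            if size == 1:
                warnings.warn("degenerate ranking: the largest component is a singleton")
            classes[cid] = "largest"
        elif rank == 1:
            classes[cid] = "second_largest"
        elif size == 1:
            classes[cid] = "isolate"
        elif size == 2:
            classes[cid] = "dyadic"
        else:
            if size > 7:
                warnings.warn(
                    f"component {cid} of size {size} outside the typology; "
                    "folded into size_3_7"
                )
            classes[cid] = "size_3_7"
    return {u: classes[c] for u, c in partition.assignment.items()}


def summarize_classes(
    partition: ComponentPartition,
    classes: Mapping[NodeId, str],
    roster: Sequence[PersonRecord],
    ego_metrics: pd.DataFrame,
    network: CompleteNetwork | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-class characteristics plus one-way ANOVA p-values per column.

    Node-level columns (n_nodes, district shares) run over every node of the
    class; respondent-level columns (age, % female, chronic conditions,
    years in the village, network size, % married, self-rated health) run
    over the roster respondents in the class.  The ANOVA for each numeric
    column compares its respondent-level values across classes.
    """
    by_id = {p.person_id: p for p in roster}
    node_district = {}
    if network is not None:
        node_district = {nid: node.district for nid, node in network.nodes.items()}
    districts = sorted(
        {p.district for p in roster} | set(node_district.values())
    )

    rows = []
    col_values: dict[str, dict[str, list[float]]] = {}
    for cls in COMPONENT_CLASSES:
        members = sorted(u for u, c in classes.items() if c == cls)
        if not members:
            continue
        respondents = [by_id[u] for u in members if u in by_id and by_id[u].is_respondent]
        sizes = [
            float(ego_metrics.loc[p.person_id, "size"])
            for p in respondents
            if p.person_id in ego_metrics.index
        ]
        values = {
            "mean_age": [float(p.age) for p in respondents],
            "prop_female": [1.0 if p.gender == "female" else 0.0 for p in respondents],
            "mean_chronic": [float(p.n_chronic) for p in respondents],
            "mean_years_in_village": [float(p.years_in_village) for p in respondents],
            "mean_network_size": sizes,
            "prop_married": [
                1.0 if p.marital_status == "living_with_spouse" else 0.0
                for p in respondents
            ],
            "mean_srh": [float(p.srh) for p in respondents],
        }
        row: dict[str, object] = {
            "class": cls,
            "n_nodes": len(members),
            "n_respondents": len(respondents),
        }
        for col, vals in values.items():
            row[col] = float(np.mean(vals)) if vals else float("nan")
            col_values.setdefault(col, {})[cls] = vals
        member_districts = [
            node_district.get(u, by_id[u].district if u in by_id else None)
            for u in members
        ]
        member_districts = [d for d in member_districts if d is not None]
        for d in districts:
            share = (
                member_districts.count(d) / len(member_districts)
                if member_districts
                else float("nan")
            )
            row[f"share_{d}"] = share
        rows.append(row)

    summary = pd.DataFrame(rows).set_index("class")
    anova_p: dict[str, float] = {}
    for col, groups in col_values.items():
        samples = [np.asarray(v) for v in groups.values() if len(v) > 0]
        if len(samples) < 2:
            anova_p[col] = float("nan")
        else:
            _, p = anova_oneway(samples)
            anova_p[col] = p
    return summary, anova_p
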