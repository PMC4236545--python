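"""Entity resolution of alter mentions and complete-network construction.

The same village resident is typically named by several respondents, with
small discrepancies in the reported name and age.  Two mentions (or a
mention and a roster person) are taken to denote the same person when all
four criteria hold: at least two of the three name tokens match
position-wise, the gender is the same, the age difference is strictly less
than five years, and the district ("Ri") is the same.

Resolution proceeds in two stages: every report is first matched against
the full roster (so spouse reports collapse onto roster spouses and married
respondent pairs become two mutually tied nodes); reports matching no roster
person are then clustered among themselves by the transitive closure
(union-find) of pairwise matches.  Pairwise matching is not transitive, so
the closure is taken deliberately: it is deterministic and independent of
report order, and cluster diameters are logged.

The complete network retains a node unless it *both* is not the spouse of a
respondent *and* resides outside the township — the conjunction matters: an
out-of-township spouse of a respondent stays in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .survey_io import AlterReport, EgoNetwork, PersonRecord

__all__ = [
    "MatchRule",
    "Node",
    "Resolution",
    "CompleteNetwork",
    "reports_match",
    "resolve_duplicates",
    "build_complete_network",
    "pairwise_resolution_scores",
]

ReportKey = tuple[str, str]  # (ego_id, slot)


@dataclass(frozen=True)
class MatchRule:
    """The four duplicate-identification criteria, each individually tunable.

    Defaults: >= 2 of 3 position-wise name tokens equal, same gender, age
    gap strictly below 5 years, same district.
    """

    min_name_token_matches: int = 2
    max_age_gap: int = 5  # strict: |a - b| < max_age_gap
    require_same_gender: bool = True
    require_same_district: bool = True

    def __post_init__(self) -> None:
        if self.min_name_token_matches not in {1, 2, 3}:
            raise ValueError("min_name_token_matches must be in {1, 2, 3}")
        if self.max_age_gap <= 0:
            raise ValueError("max_age_gap must be > 0")


@dataclass
class Node:
    """A canonical person of the complete network."""

    node_id: str
    name: tuple[str, str, str]
    gender: str
    age: int
    district: str
    is_respondent: bool
    is_respondent_spouse: bool = False


@dataclass
class Resolution:
    """Outcome of duplicate resolution: canonical nodes plus a total assignment."""

    nodes: dict[str, Node]
    assignment: dict[ReportKey, str]  # every report -> exactly one node id
    provenance: dict[str, list[ReportKey]]
    log: list[str] = field(default_factory=list)


@dataclass
class CompleteNetwork:
    """Resolved node set and deduplicated directed ego->alter tie list."""

    nodes: dict[str, Node]
    ties: set[tuple[str, str]]
    provenance: dict[str, list[ReportKey]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_ties(self) -> int:
        return len(self.ties)


def _identity(x: AlterReport | PersonRecord | Node):
    name = x.name
    gender = x.gender
    age = x.age
    district = x.district
    return name, gender, age, district


def reports_match(
    a: AlterReport | PersonRecord | Node,
    b: AlterReport | PersonRecord | Node,
    rule: MatchRule | None = None,
) -> bool:
    """True iff the four duplicate criteria all hold between ``a`` and ``b``.

    Name comparison is position-wise (token 1 vs token 1, ...), reflecting
    the fixed surname position.  A missing field yields a non-match with a
    warning rather than an error.
    """
    rule = rule or MatchRule()
    name_a, gender_a, age_a, district_a = _identity(a)
    name_b, gender_b, age_b, district_b = _identity(b)
    fields = (name_a, gender_a, age_a, district_a, name_b, gender_b, age_b, district_b)
    if any(v is None for v in fields):
        warnings.warn("report with missing identity field treated as non-match")
        return False
    token_matches = sum(1 for ta, tb in zip(name_a, name_b) if ta == tb)
    if token_matches < rule.min_name_token_matches:
        return False
    if rule.require_same_gender and gender_a != gender_b:
        return False
    if abs(age_a - age_b) >= rule.max_age_gap:
        return False
    if rule.require_same_district and district_a != district_b:
        return False
    return True


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root: smaller key wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra

    def clusters(self) -> dict:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return out


def resolve_duplicates(
    surveys: Sequence[EgoNetwork],
    roster: Sequence[PersonRecord],
    rule: MatchRule | None = None,
) -> Resolution:
    """Resolve every alter report to a canonical node.

    Stage 1 matches each report against the roster (ambiguous multi-matches
    are resolved to the candidate with the smallest age gap, then smallest
    person id, and logged).  Stage 2 clusters the remaining reports by
    union-find over pairwise matches; each cluster becomes one new node whose
    attributes come from its first report (by ego id, then slot), with
    attribute conflicts logged.  Respondents are always nodes, named or not.
    """
    rule = rule or MatchRule()
    log: list[str] = []

    # roster index by (district, gender) blocks; blocking is exact because
    # the rule requires equality on both fields (relaxed rules fall back to
    # a full scan)
    strict_block = rule.require_same_gender and rule.require_same_district
    block: dict[tuple[str, str], list[PersonRecord]] = {}
    for p in roster:
        block.setdefault((p.district, p.gender), []).append(p)

    assignment: dict[ReportKey, str] = {}
    unmatched: list[AlterReport] = []
    for net in surveys:
        for rep in net.members:
            key = (rep.ego_id, rep.slot)
            candidates = (
                block.get((rep.district, rep.gender), []) if strict_block else list(roster)
            )
            hits = [p for p in candidates if reports_match(rep, p, rule)
                    and p.person_id != rep.ego_id]
            if not hits:
                unmatched.append(rep)
                continue
            if len(hits) > 1:
                hits.sort(key=lambda p: (abs(p.age - rep.age), p.person_id))
                log.append(
                    f"report {key}: {len(hits)} roster candidates, "
                    f"kept {hits[0].person_id}"
                )
            assignment[key] = hits[0].person_id

    # stage 2: cluster unresolved reports among themselves
    keys = sorted(((r.ego_id, r.slot) for r in unmatched))
    by_key = {(r.ego_id, r.slot): r for r in unmatched}
    uf = _UnionFind(keys)
    rep_block: dict[tuple[str, str], list[ReportKey]] = {}
    for k in keys:
        r = by_key[k]
        rep_block.setdefault((r.district, r.gender), []).append(k)
    groups = rep_block.values() if strict_block else [keys]
    for grp in groups:
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if reports_match(by_key[grp[i]], by_key[grp[j]], rule):
                    uf.union(grp[i], grp[j])

    nodes: dict[str, Node] = {}
    provenance: dict[str, list[ReportKey]] = {}
    for p in roster:
        if p.is_respondent:
            nodes[p.person_id] = Node(
                node_id=p.person_id,
                name=p.name,
                gender=p.gender,
                age=p.age,
                district=p.district,
                is_respondent=True,
            )
            provenance[p.person_id] = []
    roster_by_id = {p.person_id: p for p in roster}
    for key, pid in assignment.items():
        if pid not in nodes:
            p = roster_by_id[pid]
            nodes[pid] = Node(
                node_id=pid,
                name=p.name,
                gender=p.gender,
                age=p.age,
                district=p.district,
                is_respondent=p.is_respondent,
            )
            provenance[pid] = []
        provenance[pid].append(key)

    counter = 0
    for root, members in sorted(uf.clusters().items()):
        members = sorted(members)
        node_id = f"U{counter:04d}"
        counter += 1
        first = by_key[members[0]]
        for k in members[1:]:
            other = by_key[k]
            if other.name != first.name or other.age != first.age:
                log.append(
                    f"cluster {node_id}: attribute conflict between {members[0]} and {k}"
                )
        if len(members) > 1:
            ages = [by_key[k].age for k in members]
            log.append(
                f"cluster {node_id}: {len(members)} reports, age diameter "
                f"{max(ages) - min(ages)}"
            )
        nodes[node_id] = Node(
            node_id=node_id,
            name=first.name,
            gender=first.gender,
            age=first.age,
            district=first.district,
            is_respondent=False,
        )
        provenance[node_id] = members
        for k in members:
            assignment[k] = node_id

    # mark spouses of respondents (targets of any spouse-slot report)
    for (ego_id, slot), nid in assignment.items():
        if slot == "spouse":
            nodes[nid].is_respondent_spouse = True

    return Resolution(nodes=nodes, assignment=assignment, provenance=provenance, log=log)


def build_complete_network(
    resolution: Resolution,
    surveys: Sequence[EgoNetwork],
    township_districts: Iterable[str],
) -> CompleteNetwork:
    """Directed complete network after the retention filter.

    A node is dropped only when it is *both* not the spouse of any respondent
    *and* living outside the township districts; incident ties go with it.
    Ties are deduplicated and self-ties (an ego whose report resolves to
    itself) are discarded.
    """
    districts = set(township_districts)
    keep = {
        nid
        for nid, node in resolution.nodes.items()
        if node.is_respondent_spouse or node.district in districts
    }
    ties: set[tuple[str, str]] = set()
    for net in surveys:
        ego_id = net.ego.person_id
        if ego_id not in keep:
            continue
        for rep in net.members:
            target = resolution.assignment[(rep.ego_id, rep.slot)]
            if target in keep and target != ego_id:
                ties.add((ego_id, target))
    nodes = {nid: resolution.nodes[nid] for nid in keep}
    provenance = {nid: resolution.provenance.get(nid, []) for nid in keep}
    return CompleteNetwork(nodes=nodes, ties=ties, provenance=provenance)


def pairwise_resolution_scores(
    assignment: Mapping[ReportKey, str],
    identity_map: Mapping[ReportKey, str],
) -> tuple[float, float]:
    """Pairwise precision and recall of a resolution against ground truth.

    Two reports form a predicted (true) pair when the assignment (identity
    map) sends them to the same canonical person.  Precision = true pairs
    among predicted; recall = predicted among true.  With no predicted
    (true) pairs, precision (recall) is 1.0 by convention.
    """
    keys = sorted(identity_map)
    pred_clusters: dict[str, list[ReportKey]] = {}
    true_clusters: dict[str, list[ReportKey]] = {}
    for k in keys:
        pred_clusters.setdefault(assignment[k], []).append(k)
        true_clusters.setdefault(identity_map[k], []).append(k)

    def n_pairs(clusters: dict[str, list[ReportKey]]) -> int:
        return sum(len(v) * (len(v) - 1) // 2 for v in clusters.values())

    true_label = {k: identity_map[k] for k in keys}
    tp = 0
    for members in pred_clusters.values():
        counts: dict[str, int] = {}
        for k in members:
            counts[true_label[k]] = counts.get(true_label[k], 0) + 1
        tp += sum(c * (c - 1) // 2 for c in counts.values())
    n_pred = n_pairs(pred_clusters)
    n_true = n_pairs(true_clusters)
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall
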