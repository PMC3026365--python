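"""The bipartite association network over collective BLASTN results.

The core screening idea: if several supplied queries each return the same
database sequence as a hit — at whatever rank — that subject is
*associated* with all of them, and a subject associated with many queries
is phylogenetically interesting even if it never ranked first. The
network has query nodes on one side, hit (subject) nodes on the other,
and one evidence-carrying edge per (query, subject) pair that passed the
per-edge gate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .blast_io import HitEvidence, QueryResult
from .errors import ValidationError



@dataclass(frozen=True)
class EdgeGate:
    """Conjunctive per-edge evidence thresholds; absent bound = no constraint."""

    max_evalue: float | None = None
    min_bit_score: float | None = None
    min_percent_identity: float | None = None
    max_rank: int | None = None

    def __post_init__(self):
        if self.min_percent_identity is not None and not (
            0.0 <= self.min_percent_identity <= 100.0
        ):
            raise ValidationError("min_percent_identity must lie in [0, 100]")
        if self.max_rank is not None and self.max_rank < 1:
            raise ValidationError("max_rank must be >= 1")

    def passes(self, ev: HitEvidence) -> bool:
        if self.max_evalue is not None and ev.evalue > self.max_evalue:
            return False
        if self.min_bit_score is not None and ev.bit_score < self.min_bit_score:
            return False
        if (
            self.min_percent_identity is not None
            and ev.percent_identity < self.min_percent_identity
        ):
            return False
        if self.max_rank is not None and ev.rank > self.max_rank:
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "max_evalue": self.max_evalue,
            "min_bit_score": self.min_bit_score,
            "min_percent_identity": self.min_percent_identity,
            "max_rank": self.max_rank,
        }

    @classmethod
    def from_dict(cls, d: dict | None) -> "EdgeGate":
        d = d or {}
        return cls(
            max_evalue=d.get("max_evalue"),
            min_bit_score=d.get("min_bit_score"),
            min_percent_identity=d.get("min_percent_identity"),
            max_rank=d.get("max_rank"),
        )


@dataclass
class AssociationNetwork:
    """Bipartite query/hit graph with one evidence edge per pair.

    Edges whose subject id equals any query id are self edges: stored,
    flagged, and excluded from association counts unless
    ``count_self_edges`` was set at build time.
    """

    graph: nx.Graph
    query_nodes: frozenset[str]
    hit_nodes: frozenset[str]
    self_edges: frozenset[tuple[str, str]]
    gate_applied: EdgeGate = field(default_factory=EdgeGate)
    count_self_edges: bool = False

    def evidence(self, query_id: str, subject_id: str) -> HitEvidence:
        return self.graph.edges[query_id, subject_id]["evidence"]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    results: list[QueryResult],
    gate: EdgeGate | None = None,
    count_self_edges: bool = False,
) -> AssociationNetwork:
    """Assemble the association network from per-query BLAST results.

    An edge (q, h) exists iff h is among q's deduplicated hits and the
    evidence passes every present gate bound. The result is independent
    of the order of ``results``.
    """
    gate = gate or EdgeGate()
    qids = [r.query_id for r in results]
    seen: set[str] = set()
    for qid in qids:
        if qid in seen:
            raise ValidationError(f"duplicate query id across results: {qid!r}")
        seen.add(qid)

    g = nx.Graph()
    query_nodes = frozenset(qids)
    self_edges: set[tuple[str, str]] = set()
    hit_nodes: set[str] = set()

    for qid in sorted(query_nodes):  # sorted: order-invariant construction
        g.add_node(qid, partition="query")
    for result in sorted(results, key=lambda r: r.query_id):
        for ev in result.hits:
            if not gate.passes(ev):
                continue
            is_self = ev.subject_id in query_nodes
            if is_self:
                self_edges.add((result.query_id, ev.subject_id))
            else:
                hit_nodes.add(ev.subject_id)
                if ev.subject_id not in g:
                    g.add_node(
                        ev.subject_id,
                        partition="hit",
                        description=ev.subject_description,
                    )
                elif ev.subject_description and not g.nodes[ev.subject_id].get(
                    "description"
                ):
                    g.nodes[ev.subject_id]["description"] = ev.subject_description
            g.add_edge(result.query_id, ev.subject_id, evidence=ev, is_self=is_self)

    return AssociationNetwork(
        graph=g,
        query_nodes=query_nodes,
        hit_nodes=frozenset(hit_nodes),
        self_edges=frozenset(self_edges),
        gate_applied=gate,
        count_self_edges=count_self_edges,
    )


def association_counts(net: AssociationNetwork) -> dict[str, int]:
    """Distinct non-self query neighbors per hit node.

    With ``count_self_edges`` the map additionally contains, for each
    subject that is itself a query id, the number of queries hitting it.
    """
    counts: dict[str, int] = {}
    for h in net.hit_nodes:
        counts[h] = sum(
            1 for q in net.graph.neighbors(h) if not net.graph.edges[q, h]["is_self"]
        )
    if net.count_self_edges:
        for q, s in net.self_edges:
            counts[s] = counts.get(s, 0) + 1
    return counts


def neighbors(net: AssociationNetwork, node_id: str) -> dict[str, HitEvidence]:
    """Adjacent nodes of a query or hit, with the connecting evidence."""
    if node_id not in net.graph:
        raise ValidationError(f"unknown node {node_id!r}")
    return {
        other: net.graph.edges[node_id, other]["evidence"]
        for other in net.graph.neighbors(node_id)
    }


def _sorted_hits(net: AssociationNetwork) -> list[tuple[str, int]]:
    counts = association_counts(net)
    return sorted(
        ((h, counts[h]) for h in net.hit_nodes), key=lambda t: (-t[1], t[0])
    )


def _sorted_edges(net: AssociationNetwork) -> list[HitEvidence]:
    evs = [net.graph.edges[e]["evidence"] for e in net.graph.edges]
    return sorted(evs, key=lambda ev: (ev.query_id, ev.rank, ev.subject_id))


def export_graphml(net: AssociationNetwork, stream) -> None:
    """GraphML export with a byte-stable node/edge ordering.

    Nodes carry ``partition`` (query|hit); hit nodes additionally carry
    ``description`` and ``association_count``. Edges carry the evidence
    scalars.
    """
    out = nx.Graph()
    for q in sorted(net.query_nodes):
        out.add_node(q, partition="query")
    for h, count in _sorted_hits(net):
        out.add_node(
            h,
            partition="hit",
            description=net.graph.nodes[h].get("description", ""),
            association_count=count,
        )
    for ev in _sorted_edges(net):
        out.add_edge(
            ev.query_id,
            ev.subject_id,
            rank=ev.rank,
            evalue=ev.evalue,
            bit_score=ev.bit_score,
            percent_identity=ev.percent_identity,
        )
    text = "\n".join(nx.generate_graphml(out, named_key_ids=True)) + "\n"
    stream.write(text)


def export_edge_list(net: AssociationNetwork, stream) -> None:
    """TSV edge list: query, subject, rank, evalue, bit score, identity."""
    stream.write("query\tsubject\trank\tevalue\tbit_score\tpercent_identity\n")
    for ev in _sorted_edges(net):
        stream.write(
            f"{ev.query_id}\t{ev.subject_id}\t{ev.rank}\t{ev.evalue!r}\t"
            f"{ev.bit_score!r}\t{ev.percent_identity!r}\n"
        )


def export_report_doc(net: AssociationNetwork, stream) -> None:
    """Structured JSON document mirroring the GraphML content."""
    doc = {
        "gate": net.gate_applied.to_dict(),
        "queries": sorted(net.query_nodes),
        "hits": [
            {
                "subject_id": h,
                "description": net.graph.nodes[h].get("description", ""),
                "association_count": count,
                "queries": sorted(
                    q
                    for q in net.graph.neighbors(h)
                    if not net.graph.edges[q, h]["is_self"]
                ),
            }
            for h, count in _sorted_hits(net)
        ],
        "edges": [
            {
                "query": ev.query_id,
                "subject": ev.subject_id,
                "rank": ev.rank,
                "evalue": ev.evalue,
                "bit_score": ev.bit_score,
                "percent_identity": ev.percent_identity,
            }
            for ev in _sorted_edges(net)
        ],
        "self_edges": sorted(list(e) for e in net.self_edges),
    }
    json.dump(doc, stream, indent=2, sort_keys=True)
    stream.write("\n")
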