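"""Screening report: the minimum-association filter plus per-sequence toggles.

A hit survives screening when it is associated with at least
``min_associations`` distinct queries (default 2 — a hit shared by a
single query is just ordinary BLAST output), unless it is explicitly
toggled in or out. The retained hits, together with the supplied
queries, form the sequence set passed to alignment.
"""

from __future__ import annotations

import datetime
import io
import json
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .blast_io import HitEvidence
from .errors import ValidationError
from .network import AssociationNetwork, EdgeGate, association_counts
from .seqio import Collection, SequenceRecord


@dataclass(frozen=True)
class ScreeningCriteria:
    min_associations: int = 2
    gate: EdgeGate = field(default_factory=EdgeGate)
    include_ids: frozenset[str] = frozenset()
    exclude_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.min_associations < 1:
            raise ValidationError("min_associations must be >= 1")
        overlap = set(self.include_ids) & set(self.exclude_ids)
        if overlap:
            raise ValidationError(
                f"ids toggled both in and out: {sorted(overlap)!r}"
            )

    def to_dict(self) -> dict:
        return {
            "min_associations": self.min_associations,
            "gate": self.gate.to_dict(),
            "include_ids": sorted(self.include_ids),
            "exclude_ids": sorted(self.exclude_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningCriteria":
        return cls(
            min_associations=d.get("min_associations", 2),
            gate=EdgeGate.from_dict(d.get("gate")),
            include_ids=frozenset(d.get("include_ids", ())),
            exclude_ids=frozenset(d.get("exclude_ids", ())),
        )


@dataclass(frozen=True)
class HitSummary:
    subject_id: str
    description: str
    association_count: int
    queries: tuple[str, ...]
    drop_reason: str | None = None  # None = retained


@dataclass(frozen=True)
class ScreeningReport:
    criteria: ScreeningCriteria
    retained_hits: tuple[HitSummary, ...]
    dropped_hits: tuple[HitSummary, ...]
    created_at: datetime.datetime = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
    )

    def retained_ids(self) -> list[str]:
        return [h.subject_id for h in self.retained_hits]

    def to_json(self) -> str:
        """Deterministic document; timestamps deliberately excluded so a
        re-screen with the same criteria is byte-identical."""
        doc = {
            "criteria": self.criteria.to_dict(),
            "retained": [
                {
                    "subject_id": h.subject_id,
                    "description": h.description,
                    "association_count": h.association_count,
                    "queries": list(h.queries),
                }
                for h in self.retained_hits
            ],
            "dropped": [
                {
                    "subject_id": h.subject_id,
                    "description": h.description,
                    "association_count": h.association_count,
                    "queries": list(h.queries),
                    "reason": h.drop_reason,
                }
                for h in self.dropped_hits
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("subject\tstatus\treason\tassociations\tqueries\tdescription\n")
        for h in self.retained_hits:
            buf.write(
                f"{h.subject_id}\tretained\t-\t{h.association_count}\t"
                f"{','.join(h.queries)}\t{h.description}\n"
            )
        for h in self.dropped_hits:
            buf.write(
                f"{h.subject_id}\tdropped\t{h.drop_reason}\t{h.association_count}\t"
                f"{','.join(h.queries)}\t{h.description}\n"
            )
        return buf.getvalue()


@dataclass(frozen=True)
class SequenceSet:
    """Alignment input: collection queries first, then retained hits."""

    members: tuple[SequenceRecord, ...]
    origin: dict[str, str]  # id -> 'query' | 'hit'

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValidationError("sequence set member ids must be unique")


def _summary(net: AssociationNetwork, counts, h, reason=None) -> HitSummary:
    qs = tuple(
        sorted(
            q for q in net.graph.neighbors(h) if not net.graph.edges[q, h]["is_self"]
        )
    )
    return HitSummary(
        subject_id=h,
        description=net.graph.nodes[h].get("description", ""),
        association_count=counts.get(h, 0),
        queries=qs,
        drop_reason=reason,
    )


def apply_screening(
    net: AssociationNetwork,
    criteria: ScreeningCriteria,
    pregate_net: AssociationNetwork | None = None,
) -> ScreeningReport:
    """Partition hit nodes into retained and dropped.

    ``net`` must be built with ``criteria.gate``. Passing the pre-gate
    network (same results, empty gate) lets the report also list hits
    whose evidence was entirely gated away, with drop reason ``gated``.
    Drop reason precedence: excluded > gated > below_min_associations.
    """
    counts = association_counts(net)
    retained: list[HitSummary] = []
    dropped: list[HitSummary] = []

    universe = set(net.hit_nodes)
    gated_away: set[str] = set()
    if pregate_net is not None:
        gated_away = set(pregate_net.hit_nodes) - universe
        universe |= gated_away

    for h in universe:
        source = net if h in net.hit_nodes else pregate_net
        count = counts.get(h, 0)
        if h in criteria.exclude_ids:
            dropped.append(_summary(source, counts, h, reason="excluded"))
        elif h in criteria.include_ids:
            retained.append(_summary(source, counts, h))
        elif h in gated_away:
            dropped.append(_summary(source, counts, h, reason="gated"))
        elif count < criteria.min_associations:
            dropped.append(
                _summary(source, counts, h, reason="below_min_associations")
            )
        else:
            retained.append(_summary(source, counts, h))

    key = lambda s: (-s.association_count, s.subject_id)
    return ScreeningReport(
        criteria=criteria,
        retained_hits=tuple(sorted(retained, key=key)),
        dropped_hits=tuple(sorted(dropped, key=key)),
    )


def reconstruct_hit_sequence(evidence: list[HitEvidence]) -> SequenceRecord:
    """Rebuild a subject's (partial) sequence from its best HSP segment.

    Takes the edge with the largest aligned length, strips gap characters
    and reverse-complements minus-strand segments. The record is flagged
    partial: an HSP covers only the aligned region of the subject.
    """
    with_segments = [e for e in evidence if e.subject_aligned_segment]
    if not with_segments:
        ids = sorted({e.subject_id for e in evidence}) or ["<none>"]
        raise ValidationError(
            f"no aligned-segment data to reconstruct {ids[0]!r} "
            "(XML input carries segments; tabular does not)"
        )
    best = max(with_segments, key=lambda e: e.align_length)
    residues = best.subject_aligned_segment.replace("-", "").upper()
    if best.strand == "minus":
        residues = str(Seq(residues).reverse_complement())
    return SequenceRecord(
        id=best.subject_id,
        description=best.subject_description,
        residues=residues,
        source_format="fasta",
        partial=True,
    )


def select_sequences(
    report: ScreeningReport,
    collection: Collection,
    subject_db: dict[str, SequenceRecord] | None = None,
    net: AssociationNetwork | None = None,
) -> SequenceSet:
    """Assemble the alignment input: queries first, then retained hits.

    Hit residues come from ``subject_db`` when available, otherwise they
    are reconstructed from HSP segments on the network edges. Queries
    named in the criteria's exclude toggle are left out.
    """
    members: list[SequenceRecord] = []
    origin: dict[str, str] = {}
    for rec in collection.records:
        if rec.id in report.criteria.exclude_ids:
            continue
        members.append(rec)
        origin[rec.id] = "query"

    unresolvable: list[str] = []
    for summary in report.retained_hits:
        sid = summary.subject_id
        if sid in origin:
            continue  # a retained subject that is also a supplied query
        if subject_db is not None and sid in subject_db:
            rec = subject_db[sid]
            members.append(rec)
            origin[sid] = "hit"
            continue
        if net is not None and sid in net.graph:
            evidence = [
                net.graph.edges[q, sid]["evidence"]
                for q in net.graph.neighbors(sid)
            ]
            try:
                members.append(reconstruct_hit_sequence(evidence))
                origin[sid] = "hit"
                continue
            except ValidationError:
                pass
        unresolvable.append(sid)

    if unresolvable:
        raise ValidationError(
            "no sequence source (subject database or aligned segments) for "
            f"retained hits: {sorted(unresolvable)!r}"
        )
    return SequenceSet(members=tuple(members), origin=origin)


def load_subject_db(records) -> dict[str, SequenceRecord]:
    """Index subject FASTA records by id for select_sequences."""
    return {r.id: r for r in records}
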