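"""Parsers for BLASTN result files (NCBI XML and tabular outfmt 6/7).

Both formats are reduced to one uniform model: per query, an ordered list
of hits, one :class:`HitEvidence` per (query, subject) pair. A subject
reported with several HSPs (or several tabular rows) is collapsed to the
single best piece of evidence — the association network treats a hit as
atomic evidence, so there is exactly one edge per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from lxml import etree

from .errors import ParseError, ValidationError

#: blastn -outfmt 6 default column layout.
DEFAULT_TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class HitEvidence:
    """Best-HSP evidence that one subject was returned for one query."""

    query_id: str
    subject_id: str
    rank: int
    evalue: float
    bit_score: float
    percent_identity: float
    align_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_description: str = ""
    subject_aligned_segment: str | None = None

    def __post_init__(self):
        if self.rank < 1:
            raise ValidationError(f"hit {self.subject_id!r}: rank must be >= 1")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.subject_id!r}: negative e-value")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"hit {self.subject_id!r}: percent identity outside [0, 100]"
            )
        if self.align_length < 1:
            raise ValidationError(f"hit {self.subject_id!r}: align_length < 1")

    @property
    def strand(self) -> str:
        """'minus' iff subject coordinates are reported descending."""
        return "minus" if self.s_start > self.s_end else "plus"


@dataclass(frozen=True)
class QueryResult:
    """All deduplicated hits of one query, in rank order (ranks 1..n)."""

    query_id: str
    hits: tuple[HitEvidence, ...]

    def __post_init__(self):
        subjects = [h.subject_id for h in self.hits]
        if len(subjects) != len(set(subjects)):
            raise ValidationError(
                f"query {self.query_id!r}: duplicate subjects after dedupe"
            )
        for i, h in enumerate(self.hits, start=1):
            if h.rank != i:
                raise ValidationError(
                    f"query {self.query_id!r}: ranks not contiguous 1..n"
                )


def dedupe_evidence(candidates) -> HitEvidence:
    """Collapse all evidence rows/HSPs for one (query, subject) pair.

    Selection: highest bit score, then lowest e-value, then largest
    alignment length, then first occurrence in input order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("dedupe_evidence: no candidates")
    best = candidates[0]
    for cand in candidates[1:]:
        if (cand.bit_score, -cand.evalue, cand.align_length) > (
            best.bit_score, -best.evalue, best.align_length
        ):
            best = cand
    return best


def _rerank(query_id: str, per_subject: dict[str, list[HitEvidence]]) -> QueryResult:
    """Dedupe per subject and assign contiguous ranks by first appearance."""
    hits = []
    for i, (_, cands) in enumerate(per_subject.items(), start=1):
        hits.append(replace(dedupe_evidence(cands), rank=i))
    return QueryResult(query_id=query_id, hits=tuple(hits))


# ---------------------------------------------------------------------------
# NCBI XML
# ---------------------------------------------------------------------------

def _xml_text(parent, tag: str, default: str | None = None) -> str:
    node = parent.find(tag)
    if node is None or node.text is None:
        if default is not None:
            return default
        raise ParseError(f"BLAST XML: missing element <{tag}>")
    return node.text


def parse_blast_xml(stream) -> list[QueryResult]:
    """Parse an NCBI BLAST XML report (single- or multi-iteration).

    Subject identity is Hit_accession when present, else Hit_id. The
    query id is the first token of the query definition, matching how
    tabular qseqid is produced. The best HSP per hit supplies the numeric
    fields and the gapped subject row (``subject_aligned_segment``).
    """
    data = stream if isinstance(stream, (str, bytes)) else stream.read()
    if isinstance(data, str):
        data = data.encode()
    try:
        root = etree.fromstring(data, parser=etree.XMLParser(resolve_entities=False))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc
    if root.tag != "BlastOutput":
        raise ParseError(
            f"root element is <{root.tag}>, not <BlastOutput> (NCBI BLAST XML)"
        )
    iterations = root.find("BlastOutput_iterations")
    if iterations is None:
        raise ParseError("BLAST XML: missing <BlastOutput_iterations>")

    results: list[QueryResult] = []
    for it in iterations.findall("Iteration"):
        qdef = _xml_text(it, "Iteration_query-def", default="")
        query_id = qdef.split()[0] if qdef.split() else _xml_text(it, "Iteration_query-ID")
        per_subject: dict[str, list[HitEvidence]] = {}
        hits_el = it.find("Iteration_hits")
        for hit in hits_el.findall("Hit") if hits_el is not None else []:
            acc = _xml_text(hit, "Hit_accession", default="")
            subject_id = acc if acc else _xml_text(hit, "Hit_id")
            hit_def = _xml_text(hit, "Hit_def", default="")
            # Drop a leading token that just repeats the subject id.
            tokens = hit_def.split(None, 1)
            if tokens and tokens[0] == subject_id:
                description = tokens[1] if len(tokens) > 1 else ""
            else:
                description = hit_def
            hsps = hit.find("Hit_hsps")
            if hsps is None:
                raise ParseError(f"BLAST XML: hit {subject_id!r} has no <Hit_hsps>")
            for hsp in hsps.findall("Hsp"):
                identity = int(_xml_text(hsp, "Hsp_identity"))
                alen = int(_xml_text(hsp, "Hsp_align-len"))
                per_subject.setdefault(subject_id, []).append(
                    HitEvidence(
                        query_id=query_id,
                        subject_id=subject_id,
                        subject_description=description,
                        rank=1,  # provisional; reassigned after dedupe
                        evalue=float(_xml_text(hsp, "Hsp_evalue")),
                        bit_score=float(_xml_text(hsp, "Hsp_bit-score")),
                        percent_identity=round(100.0 * identity / alen, 3),
                        align_length=alen,
                        q_start=int(_xml_text(hsp, "Hsp_query-from")),
                        q_end=int(_xml_text(hsp, "Hsp_query-to")),
                        s_start=int(_xml_text(hsp, "Hsp_hit-from")),
                        s_end=int(_xml_text(hsp, "Hsp_hit-to")),
                        subject_aligned_segment=_xml_text(hsp, "Hsp_hseq", default="")
                        or None,
                    )
                )
        results.append(_rerank(query_id, per_subject))
    return results


# ---------------------------------------------------------------------------
# Tabular (outfmt 6/7)
# ---------------------------------------------------------------------------

_NUMERIC_TABULAR = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


def parse_blast_tabular(stream, columns=DEFAULT_TABULAR_COLUMNS) -> list[QueryResult]:
    """Parse BLAST tabular output (tab-separated; '#' lines are comments).

    Rows are grouped by qseqid preserving file order; per (query, subject)
    the best row is kept and ranks follow deduplicated first appearance.
    """
    columns = tuple(columns)
    for required in ("qseqid", "sseqid"):
        if required not in columns:
            raise ValidationError(f"tabular column layout lacks {required!r}")
    lines = stream.splitlines() if isinstance(stream, str) else stream.read().splitlines()

    grouped: dict[str, dict[str, list[HitEvidence]]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(columns):
            raise ParseError(
                f"expected {len(columns)} tab-separated fields, got {len(fields)}",
                line=lineno,
            )
        row: dict[str, object] = {}
        for name, value in zip(columns, fields):
            conv = _NUMERIC_TABULAR.get(name, str)
            try:
                row[name] = conv(value)
            except ValueError as exc:
                raise ParseError(
                    f"field {name!r}: cannot parse {value!r} as {conv.__name__}",
                    line=lineno,
                ) from exc
        q, s = str(row["qseqid"]), str(row["sseqid"])
        evidence = HitEvidence(
            query_id=q,
            subject_id=s,
            rank=1,  # provisional; reassigned after dedupe
            evalue=float(row.get("evalue", 0.0)),
            bit_score=float(row.get("bitscore", 0.0)),
            percent_identity=float(row.get("pident", 100.0)),
            align_length=int(row.get("length", 1)),
            q_start=int(row.get("qstart", 1)),
            q_end=int(row.get("qend", 1)),
            s_start=int(row.get("sstart", 1)),
            s_end=int(row.get("send", 1)),
        )
        grouped.setdefault(q, {}).setdefault(s, []).append(evidence)

    return [_rerank(q, per_subject) for q, per_subject in grouped.items()]


def parse_blast(stream, format: str, **kwargs) -> list[QueryResult]:
    """Dispatch on ``format`` in {'xml', 'tab'}."""
    if format == "xml":
        return parse_blast_xml(stream)
    if format == "tab":
        return parse_blast_tabular(stream, **kwargs)
    raise ValidationError(f"unknown BLAST result format {format!r}")

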