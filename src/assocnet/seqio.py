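"""Sequence collection import/export.

Collections are the unit pushed through the screening pipeline: a named,
ordered set of nucleotide records with a permanent note of how they were
imported. Three input formats are supported — FASTA, GenBank flat files
and "raw" text (one sequence per non-empty line) — plus FASTA output.
"""

from __future__ import annotations

import datetime
import io
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import ParseError, ValidationError

# IUPAC nucleotide one-letter codes, including U and ambiguity letters.
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

_FASTA_WRAP = 60


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with its identity and provenance.

    ``residues`` is stored uppercase, gap-free and whitespace-free;
    ``partial`` marks sequences reconstructed from alignment segments
    rather than taken from a database.
    """

    id: str
    residues: str
    description: str = ""
    accession: str | None = None
    source_format: str = "fasta"
    partial: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Collection:
    """A named, ordered set of records with import provenance."""

    name: str
    records: tuple[SequenceRecord, ...]
    import_params: dict
    created_at: datetime.datetime = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
    )

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def _as_lines(stream) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def _clean_residues(raw: str, where: str, line: int | None = None) -> str:
    residues = "".join(raw.split()).upper()
    bad = set(residues) - IUPAC_NT
    if bad:
        raise ParseError(
            f"{where}: characters {sorted(bad)!r} outside the IUPAC nucleotide "
            "alphabet",
            line=line,
        )
    return residues


def read_fasta(stream) -> list[SequenceRecord]:
    """Parse FASTA text into records.

    The id is the first whitespace-delimited header token, the description
    the remainder. Sequence data before any header, or a header with an
    empty body, is a parse error naming the line.
    """
    records: list[SequenceRecord] = []
    header: tuple[str, str, int] | None = None  # id, description, line no
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        hid, desc, lineno = header
        if not chunks:
            raise ParseError(f"record {hid!r} has an empty body", line=lineno)
        records.append(
            SequenceRecord(
                id=hid,
                description=desc,
                residues=_clean_residues("".join(chunks), f"record {hid!r}"),
                source_format="fasta",
            )
        )

    for lineno, line in enumerate(_as_lines(stream), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            flush()
            head = stripped[1:].strip()
            if not head:
                raise ParseError("empty FASTA header", line=lineno)
            parts = head.split(None, 1)
            header = (parts[0], parts[1] if len(parts) > 1 else "", lineno)
            chunks = []
        else:
            if header is None:
                raise ParseError("sequence data before any '>' header", line=lineno)
            chunks.append(stripped)
    flush()
    return records


def read_genbank(stream) -> list[SequenceRecord]:
    """Parse one or more GenBank flat-file entries.

    Only identity and residues are used downstream, so the reader is
    minimal: LOCUS name -> id, ACCESSION -> accession, DEFINITION ->
    description, ORIGIN -> residues. Feature tables are ignored.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        return []
    if "LOCUS" not in text:
        raise ParseError("no LOCUS line found; not GenBank flat-file text")
    records: list[SequenceRecord] = []
    # Parse entry by entry ('//'-terminated) so errors can name the entry.
    entry_lines: list[str] = []
    entries: list[str] = []
    for line in text.splitlines():
        entry_lines.append(line)
        if line.strip() == "//":
            entries.append("\n".join(entry_lines) + "\n")
            entry_lines = []
    if any(l.strip() for l in entry_lines):
        entries.append("\n".join(entry_lines) + "\n//\n")
    parsed = []
    for entry in entries:
        locus = next(
            (l.split()[1] for l in entry.splitlines()
             if l.startswith("LOCUS") and len(l.split()) > 1),
            "<unknown>",
        )
        try:
            import warnings

            with warnings.catch_warnings():
                # only LOCUS/DEFINITION/ACCESSION/ORIGIN are consumed here,
                # so cosmetic locus-line layout warnings are noise
                warnings.simplefilter("ignore")
                parsed.extend(SeqIO.parse(io.StringIO(entry), "genbank"))
        except ValueError as exc:
            raise ParseError(f"entry {locus!r}: malformed GenBank text: {exc}") from exc
    for rec in parsed:
        try:
            residues = str(rec.seq)
        except Exception as exc:  # UndefinedSequenceError: no ORIGIN block
            raise ParseError(
                f"entry {rec.name!r}: missing or empty ORIGIN block"
            ) from exc
        if not residues:
            raise ParseError(f"entry {rec.name!r}: missing or empty ORIGIN block")
        accessions = rec.annotations.get("accessions") or []
        description = rec.description
        if description == ".":  # Biopython's stand-in for a missing DEFINITION
            description = ""
        records.append(
            SequenceRecord(
                id=rec.name,
                accession=accessions[0] if accessions else None,
                description=description,
                residues=_clean_residues(residues, f"entry {rec.name!r}"),
                source_format="genbank",
            )
        )
    return records


def read_raw(stream) -> list[SequenceRecord]:
    """Parse raw text: one sequence per non-empty line, auto-named raw_N."""
    records: list[SequenceRecord] = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        n = len(records) + 1
        records.append(
            SequenceRecord(
                id=f"raw_{n}",
                residues=_clean_residues(line, f"raw line {lineno}", line=lineno),
                source_format="raw",
            )
        )
    return records


def write_fasta(records, stream) -> None:
    """Write records as FASTA, 60-column wrapped.

    Round-trips with :func:`read_fasta` on (id, description, residues).
    """
    for rec in records:
        header = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
        stream.write(header + "\n")
        for i in range(0, len(rec.residues), _FASTA_WRAP):
            stream.write(rec.residues[i : i + _FASTA_WRAP] + "\n")


def fasta_string(records) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


def create_collection(name: str, records, import_params: dict | None = None) -> Collection:
    """Assemble a Collection, enforcing non-emptiness and id uniqueness.

    ``source_format`` and ``record_count`` are always present in the stored
    import parameters.
    """
    records = tuple(records)
    if not records:
        raise ValidationError(f"collection {name!r}: no records to import")
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in records:
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
    if dupes:
        raise ValidationError(
            f"collection {name!r}: duplicate record ids {sorted(set(dupes))!r}"
        )
    params = dict(import_params or {})
    params.setdefault(
        "source_format",
        ",".join(sorted({r.source_format for r in records})),
    )
    params["record_count"] = len(records)
    return Collection(name=name, records=records, import_params=params)


READERS = {"fasta": read_fasta, "genbank": read_genbank, "raw": read_raw}


def read_collection(name: str, stream, format: str, extra_params: dict | None = None) -> Collection:
    """One-step import: parse ``stream`` in ``format`` and build a Collection."""
    if format not in READERS:
        raise ValidationError(f"unknown import format {format!r}")
    records = READERS[format](stream)
    params = {"source_format": format}
    params.update(extra_params or {})
    return create_collection(name, records, params)
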