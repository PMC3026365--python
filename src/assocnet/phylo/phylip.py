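"""Sequential PHYLIP alignment I/O, relaxed and strict dialects.

Relaxed (default): full names, two spaces, one sequence per line — the
form modern tools accept and the one that preserves accessions. Strict:
classic 10-character padded names with a sanitization map returned to
the caller; truncation collisions are an error, never silent.
"""

from __future__ import annotations

import io

from ..errors import ParseError, ValidationError
from .align import AlignmentResult

_STRICT_WIDTH = 10


def write_phylip(aln: AlignmentResult, stream, dialect: str = "relaxed") -> dict[str, str]:
    """Write a sequential PHYLIP alignment; returns the name map
    (original -> written) for the strict dialect (empty when relaxed)."""
    if dialect not in ("relaxed", "strict"):
        raise ValidationError(f"unknown PHYLIP dialect {dialect!r}")
    name_map: dict[str, str] = {}
    names: list[str] = []
    if dialect == "strict":
        seen: dict[str, list[str]] = {}
        for rid, _ in aln.rows:
            short = rid.replace(" ", "_")[:_STRICT_WIDTH]
            seen.setdefault(short, []).append(rid)
        collisions = {k: v for k, v in seen.items() if len(v) > 1}
        if collisions:
            raise ValidationError(
                "strict PHYLIP name collisions after 10-character truncation: "
                + "; ".join(f"{k!r} <- {sorted(v)!r}" for k, v in sorted(collisions.items()))
            )
        for rid, _ in aln.rows:
            short = rid.replace(" ", "_")[:_STRICT_WIDTH]
            if short != rid:
                name_map[rid] = short
            names.append(short.ljust(_STRICT_WIDTH))
    else:
        for rid, _ in aln.rows:
            if any(ch.isspace() for ch in rid):
                raise ValidationError(
                    f"relaxed PHYLIP cannot hold whitespace in name {rid!r}"
                )
            names.append(rid)

    stream.write(f" {len(aln.rows)} {aln.width}\n")
    for written, (rid, row) in zip(names, aln.rows):
        sep = "" if dialect == "strict" else "  "
        stream.write(f"{written}{sep}{row}\n")
    return name_map


def phylip_string(aln: AlignmentResult, dialect: str = "relaxed") -> str:
    buf = io.StringIO()
    write_phylip(aln, buf, dialect)
    return buf.getvalue()


def read_phylip(stream, dialect: str = "relaxed") -> AlignmentResult:
    """Read a sequential PHYLIP alignment written by :func:`write_phylip`."""
    if dialect not in ("relaxed", "strict"):
        raise ValidationError(f"unknown PHYLIP dialect {dialect!r}")
    text = stream if isinstance(stream, str) else stream.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty PHYLIP input")
    header = lines[0].split()
    if len(header) != 2:
        raise ParseError("PHYLIP header must be 'n_sequences n_columns'", line=1)
    try:
        n, width = int(header[0]), int(header[1])
    except ValueError as exc:
        raise ParseError("non-integer PHYLIP header fields", line=1) from exc
    body = lines[1:]
    if len(body) != n:
        raise ParseError(
            f"header promises {n} sequences but body has {len(body)} lines"
        )
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(body, start=2):
        if dialect == "strict":
            if len(line) <= _STRICT_WIDTH:
                raise ParseError("strict PHYLIP line shorter than the 10-char name field", line=lineno)
            name = line[:_STRICT_WIDTH].strip()
            seq = "".join(line[_STRICT_WIDTH:].split())
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError("expected 'name sequence'", line=lineno)
            name = parts[0]
            seq = "".join(parts[1].split())
        if len(seq) != width:
            raise ParseError(
                f"sequence {name!r} has {len(seq)} columns, header says {width}",
                line=lineno,
            )
        rows.append((name, seq))
    return AlignmentResult(rows=rows, params={"format": "phylip", "dialect": dialect})
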