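"""Built-in alignment stage: Needleman-Wunsch pairwise and center-star MSA.

These exist so the whole pipeline runs with no external binaries at desk
scale; production-quality alignments should come through the external
aligner adapter (ClustalW/MAFFT class tools). The center-star heuristic
aligns every sequence to the highest-scoring center and merges gaps into
the center coordinate system ("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError

#: Default linear-gap scoring: match +1, mismatch -1, gap -2.
DEFAULT_SCORES = {"match": 1, "mismatch": -1, "gap": -2}

GAP = "-"


@dataclass
class AlignmentResult:
    """Equal-length aligned rows; de-gapping a row gives its input back."""

    rows: list[tuple[str, str]]  # (id, aligned residues with '-')
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rows:
            raise ValidationError("alignment has no rows")
        width = len(self.rows[0][1])
        if width < 1:
            raise ValidationError("alignment has zero columns")
        for rid, row in self.rows:
            if len(row) != width:
                raise ValidationError(
                    f"row {rid!r}: length {len(row)} != alignment width {width}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


def nw_pairwise(a: str, b: str, scores: dict | None = None):
    """Global (Needleman-Wunsch) alignment with linear gap penalties.

    Traceback ties are broken diagonal > up > left, so the result is a
    unique, deterministic optimum. Returns (aligned_a, aligned_b, score).
    """
    if not a or not b:
        raise ValidationError("nw_pairwise: sequences must be non-empty")
    s = dict(DEFAULT_SCORES, **(scores or {}))
    match, mismatch, gap = s["match"], s["mismatch"], s["gap"]
    n, m = len(a), len(b)

    f = np.empty((n + 1, m + 1), dtype=np.int64)
    f[0, :] = np.arange(m + 1) * gap
    f[:, 0] = np.arange(n + 1) * gap
    sub = np.where(
        (np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
         == np.frombuffer(b.encode(), dtype=np.uint8)[None, :]),
        match,
        mismatch,
    )
    for i in range(1, n + 1):
        diag = f[i - 1, :-1] + sub[i - 1]
        up = f[i - 1, 1:] + gap
        row = f[i]
        prev = row[0]
        best_du = np.maximum(diag, up)
        for j in range(1, m + 1):
            prev = max(best_du[j - 1], prev + gap)
            row[j] = prev

    # Traceback, diagonal > up > left on ties.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and f[i, j] == f[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and f[i, j] == f[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(f[n, m])


def _merge_into_center(center: str, new_center: str):
    """Return gap-insertion index lists turning each input into the union
    gap pattern. Both arguments de-gap to the same residue string."""
    union: list[str] = []
    ins_old: list[int] = []  # columns to insert into rows following `center`
    ins_new: list[int] = []
    i = j = 0
    while i < len(center) or j < len(new_center):
        ci = center[i] if i < len(center) else None
        cj = new_center[j] if j < len(new_center) else None
        if ci is not None and cj is not None and ci == cj:
            union.append(ci); i += 1; j += 1
        elif ci == GAP:
            union.append(GAP); ins_new.append(len(union) - 1); i += 1
        elif cj == GAP:
            union.append(GAP); ins_old.append(len(union) - 1); j += 1
        else:  # both residues (equal by construction) — consumed above
            union.append(ci); i += 1; j += 1
    return "".join(union), ins_old, ins_new


def _apply_insertions(row: str, positions: list[int]) -> str:
    chars = list(row)
    for pos in positions:  # positions are ascending union-frame indices
        chars.insert(pos, GAP)
    return "".join(chars)


def star_align(seqs, scores: dict | None = None) -> AlignmentResult:
    """Center-star multiple alignment.

    ``seqs`` is a SequenceSet or any iterable of objects with ``id`` and
    ``residues``. The center is the sequence with the highest total
    pairwise score to all others (ties: first in ascending id order).
    """
    members = list(getattr(seqs, "members", seqs))
    if len(members) < 2:
        raise ValidationError("star_align: need at least 2 sequences")
    ids = [m.id for m in members]
    if len(ids) != len(set(ids)):
        raise ValidationError("star_align: duplicate sequence ids")
    s = dict(DEFAULT_SCORES, **(scores or {}))

    # Choose the center by total pairwise NW score.
    total = {m.id: 0 for m in members}
    pair_score: dict[tuple[str, str], int] = {}
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            _, _, sc = nw_pairwise(members[i].residues, members[j].residues, s)
            total[members[i].id] += sc
            total[members[j].id] += sc
            pair_score[(members[i].id, members[j].id)] = sc
    best_total = max(total.values())
    center_id = min(mid for mid, t in total.items() if t == best_total)
    center = next(m for m in members if m.id == center_id)
    others = [m for m in members if m.id != center_id]

    center_row = center.residues
    aligned: dict[str, str] = {}
    for other in others:
        c_aln, o_aln, _ = nw_pairwise(center.residues, other.residues, s)
        union, ins_old, ins_new = _merge_into_center(center_row, c_aln)
        for rid in aligned:
            aligned[rid] = _apply_insertions(aligned[rid], ins_old)
        aligned[other.id] = _apply_insertions(o_aln, ins_new)
        center_row = union

    rows = [(m.id, center_row if m.id == center_id else aligned[m.id]) for m in members]
    return AlignmentResult(
        rows=rows,
        params={"method": "star", "center": center_id, **s},
    )
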