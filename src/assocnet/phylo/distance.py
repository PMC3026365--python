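"""Pairwise evolutionary distances from a multiple alignment.

Two models: the raw proportion of differing sites (p-distance) and the
Jukes-Cantor 1969 correction d = -(3/4) ln(1 - 4p/3), which accounts for
multiple substitutions at a site under equal rates and base frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SaturationError, ValidationError
from .align import AlignmentResult

_COMPARABLE = frozenset("ACGTU")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T, atol=0.0, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValidationError("distances must be non-negative")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{x:.9f}" for x in self.d[i])
            lines.append(f"{name}  {row}")
        return "\n".join(lines) + "\n"


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of mismatches over sites where both rows have an
    unambiguous base; gap or ambiguity columns are excluded."""
    if len(row_i) != len(row_j):
        raise ValidationError("p_distance: rows have different lengths")
    comparable = 0
    mismatches = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a in _COMPARABLE and b in _COMPARABLE:
            comparable += 1
            if a != b:
                mismatches += 1
    if comparable == 0:
        raise SaturationError(
            "p_distance undefined: no sites where both rows have a base"
        )
    return mismatches / comparable


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction of a p-distance; undefined for p >= 0.75."""
    if p < 0:
        raise ValidationError("p-distance cannot be negative")
    if p >= 0.75:
        raise SaturationError(
            f"JC69 saturates at p = {p}: 1 - 4p/3 <= 0, distance undefined"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def distance_matrix(aln: AlignmentResult, model: str = "jc69") -> DistanceMatrix:
    """All pairwise distances under ``model`` in {'p', 'jc69'}."""
    if model not in ("p", "jc69"):
        raise ValidationError(f"unknown distance model {model!r}")
    ids = aln.ids()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.rows[i][1], aln.rows[j][1])
            d[i, j] = d[j, i] = jc69_distance(p) if model == "jc69" else p
    return DistanceMatrix(ids=ids, d=d)
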