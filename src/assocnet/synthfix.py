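"""Synthetic fixtures with planted association structure.

Emulates an environmental 16S-style screening input: a collection of
query sequences, a subject database, and simulated BLASTN output whose
rows correspond exactly to the 1-entries of a planted query x subject
incidence matrix. The planted matrix is the ground truth every other
module is tested against: association counts must equal its column sums,
and screening at threshold m must retain exactly the subjects whose
column sum is >= m.

Each subject is a mutated copy of the first query that hits it, so the
percent identity reported for that pair reflects realized substitutions.
Bit scores are 2 x (matching sites) and e-values the deterministic
monotone transform 10^(-bit/10) floored at 1e-180 — consumers only rely
on ordering and gating, never on BLAST's Karlin-Altschul statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .phylo.tree import Tree, TreeNode
from .seqio import SequenceRecord, fasta_string

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    n_queries: int
    n_subjects: int
    seed: int
    incidence: object | None = None  # binary matrix, or density in (0,1]
    seq_length: int = 200
    mutation_rate: float = 0.02

    def __post_init__(self):
        if self.n_queries < 1 or self.n_subjects < 1:
            raise ValidationError("fixture dimensions must be >= 1")
        if not (0.0 <= self.mutation_rate <= 0.3):
            raise ValidationError("mutation_rate must lie in [0, 0.3]")
        if self.seq_length < 10:
            raise ValidationError("seq_length must be >= 10")
        if isinstance(self.incidence, float) and not (0.0 < self.incidence <= 1.0):
            raise ValidationError("incidence density must lie in (0, 1]")


@dataclass(frozen=True)
class FixtureBundle:
    queries: tuple[SequenceRecord, ...]
    subjects: tuple[SequenceRecord, ...]
    queries_fasta: str
    subjects_fasta: str
    blast_tab: str
    blast_xml: str
    planted: np.ndarray  # realized incidence, n_queries x n_subjects

    def query_ids(self) -> list[str]:
        return [r.id for r in self.queries]

    def subject_ids(self) -> list[str]:
        return [r.id for r in self.subjects]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        # substitute with one of the three other bases
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _realize_incidence(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.incidence is None or isinstance(spec.incidence, float):
        density = spec.incidence if isinstance(spec.incidence, float) else 0.3
        planted = (rng.random((spec.n_queries, spec.n_subjects)) < density).astype(int)
        # every subject must be hit at least once
        for j in range(spec.n_subjects):
            if planted[:, j].sum() == 0:
                planted[rng.integers(0, spec.n_queries), j] = 1
    else:
        planted = np.asarray(spec.incidence, dtype=int)
        if planted.shape != (spec.n_queries, spec.n_subjects):
            raise ValidationError(
                f"incidence shape {planted.shape} != "
                f"({spec.n_queries}, {spec.n_subjects})"
            )
        if not np.isin(planted, (0, 1)).all():
            raise ValidationError("incidence matrix must be binary")
        if (planted.sum(axis=0) == 0).any():
            raise ValidationError("incidence has an all-zero subject column")
    return planted


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Deterministically realize a fixture bundle from a spec + seed."""
    rng = np.random.default_rng(spec.seed)
    planted = _realize_incidence(spec, rng)
    L = spec.seq_length

    queries = tuple(
        SequenceRecord(
            id=f"q{i + 1:03d}",
            description="synthetic query",
            residues=_random_seq(rng, L),
        )
        for i in range(spec.n_queries)
    )
    subjects = []
    for j in range(spec.n_subjects):
        parent = queries[int(np.nonzero(planted[:, j])[0][0])]
        subjects.append(
            SequenceRecord(
                id=f"s{j + 1:04d}",
                description="synthetic subject",
                residues=_mutate(rng, parent.residues, spec.mutation_rate),
            )
        )
    subjects = tuple(subjects)

    # One simulated hit row per planted pair, ranked per query by bit score.
    rows_by_query: dict[str, list[dict]] = {q.id: [] for q in queries}
    for i, q in enumerate(queries):
        for j in np.nonzero(planted[i])[0]:
            s = subjects[int(j)]
            qa = np.frombuffer(q.residues.encode(), dtype=np.uint8)
            sa = np.frombuffer(s.residues.encode(), dtype=np.uint8)
            matches = int((qa == sa).sum())
            mismatches = L - matches
            bit = 2.0 * matches
            evalue = max(10.0 ** (-bit / 10.0), 1e-180)
            rows_by_query[q.id].append(
                {
                    "qseqid": q.id,
                    "sseqid": s.id,
                    "pident": 100.0 * matches / L,
                    "length": L,
                    "mismatch": mismatches,
                    "bit": bit,
                    "evalue": evalue,
                    "hseq": s.residues,
                }
            )
    for rows in rows_by_query.values():
        rows.sort(key=lambda r: (-r["bit"], r["sseqid"]))

    tab = io.StringIO()
    tab.write("# synthetic BLASTN tabular output (outfmt 6 columns)\n")
    for q in queries:
        for r in rows_by_query[q.id]:
            tab.write(
                f"{r['qseqid']}\t{r['sseqid']}\t{r['pident']:.3f}\t{r['length']}\t"
                f"{r['mismatch']}\t0\t1\t{L}\t1\t{L}\t{r['evalue']:.6g}\t"
                f"{r['bit']:.1f}\n"
            )

    return FixtureBundle(
        queries=queries,
        subjects=subjects,
        queries_fasta=fasta_string(queries),
        subjects_fasta=fasta_string(subjects),
        blast_tab=tab.getvalue(),
        blast_xml=_emit_xml(queries, rows_by_query, L),
        planted=planted,
    )


def _emit_xml(queries, rows_by_query, L: int) -> str:
    """NCBI BLAST XML mirroring exactly the tabular rows.

    Hit_def repeats the subject id so that both formats parse to an empty
    subject description (tabular carries none), keeping exports at byte
    parity.
    """
    out = io.StringIO()
    out.write('<?xml version="1.0"?>\n')
    out.write(
        '<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" '
        '"http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">\n'
    )
    out.write("<BlastOutput>\n")
    out.write("  <BlastOutput_program>blastn</BlastOutput_program>\n")
    out.write("  <BlastOutput_version>synthetic</BlastOutput_version>\n")
    out.write("  <BlastOutput_db>synthetic_subjects</BlastOutput_db>\n")
    out.write("  <BlastOutput_iterations>\n")
    for it_num, q in enumerate(queries, start=1):
        out.write("    <Iteration>\n")
        out.write(f"      <Iteration_iter-num>{it_num}</Iteration_iter-num>\n")
        out.write(f"      <Iteration_query-ID>Query_{it_num}</Iteration_query-ID>\n")
        out.write(
            f"      <Iteration_query-def>{q.id} {q.description}</Iteration_query-def>\n"
        )
        out.write(f"      <Iteration_query-len>{L}</Iteration_query-len>\n")
        out.write("      <Iteration_hits>\n")
        for hit_num, r in enumerate(rows_by_query[q.id], start=1):
            matches = L - r["mismatch"]
            out.write("        <Hit>\n")
            out.write(f"          <Hit_num>{hit_num}</Hit_num>\n")
            out.write(f"          <Hit_id>lcl|{r['sseqid']}</Hit_id>\n")
            out.write(f"          <Hit_def>{r['sseqid']}</Hit_def>\n")
            out.write(f"          <Hit_accession>{r['sseqid']}</Hit_accession>\n")
            out.write(f"          <Hit_len>{L}</Hit_len>\n")
            out.write("          <Hit_hsps>\n            <Hsp>\n")
            out.write("              <Hsp_num>1</Hsp_num>\n")
            out.write(f"              <Hsp_bit-score>{r['bit']:.1f}</Hsp_bit-score>\n")
            out.write(f"              <Hsp_evalue>{r['evalue']:.6g}</Hsp_evalue>\n")
            out.write("              <Hsp_query-from>1</Hsp_query-from>\n")
            out.write(f"              <Hsp_query-to>{L}</Hsp_query-to>\n")
            out.write("              <Hsp_hit-from>1</Hsp_hit-from>\n")
            out.write(f"              <Hsp_hit-to>{L}</Hsp_hit-to>\n")
            out.write(f"              <Hsp_identity>{matches}</Hsp_identity>\n")
            out.write(f"              <Hsp_align-len>{L}</Hsp_align-len>\n")
            out.write(f"              <Hsp_hseq>{r['hseq']}</Hsp_hseq>\n")
            out.write("            </Hsp>\n          </Hit_hsps>\n")
            out.write("        </Hit>\n")
        out.write("      </Iteration_hits>\n")
        out.write("    </Iteration>\n")
    out.write("  </BlastOutput_iterations>\n")
    out.write("</BlastOutput>\n")
    return out.getvalue()


def planted_counts(bundle: FixtureBundle) -> dict[str, int]:
    """Ground-truth association counts: column sums of the planted matrix."""
    sums = bundle.planted.sum(axis=0)
    return {sid: int(sums[j]) for j, sid in enumerate(bundle.subject_ids())}


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_bl: float = 0.05,
    max_bl: float = 1.0,
) -> Tree:
    """Random unrooted binary tree with U[min_bl, max_bl] branch lengths.

    Grown by random leaf attachment (every topology reachable); the
    anchor node has degree 3, matching NJ output shape. Used as the
    additive-matrix oracle for tree-inference tests.
    """
    if n_leaves < 3:
        raise ValidationError("random_binary_tree needs >= 3 leaves")

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    labels = [f"t{i + 1:02d}" for i in range(n_leaves)]
    root = TreeNode(
        children=[TreeNode(label=labels[k], length=bl()) for k in range(3)]
    )
    edges: list[tuple[TreeNode, TreeNode]] = [(root, c) for c in root.children]
    for k in range(3, n_leaves):
        parent, child = edges[int(rng.integers(0, len(edges)))]
        # split the edge: parent -> mid -> {child, new leaf}
        mid = TreeNode(length=child.length / 2.0)
        child.length = child.length / 2.0
        leaf = TreeNode(label=labels[k], length=bl())
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, leaf]
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, leaf)])
    return Tree(root=root)
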