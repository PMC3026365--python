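# Methods

## The association network

The unit of evidence is one (query, subject) pair. A subject reported
with several HSPs, or several tabular rows, is collapsed to its single
best piece of evidence: highest bit score, then lowest e-value, then
largest aligned length, then first occurrence. This keeps exactly one
edge per pair, which is what the association count needs — the count is
"how many distinct supplied queries list this subject", not "how many
local alignments exist".

Subject identity is the verbatim `sseqid` / `Hit_accession` string
(falling back to `Hit_id` in XML); no version stripping or other
normalization is applied, because silently merging distinct accessions
would inflate counts. Query identity is the first whitespace token of
the query definition, matching how BLAST's tabular `qseqid` is formed,
so XML- and tabular-derived networks are comparable.

Per-edge gates (max e-value, min bit score, min percent identity, max
rank) combine conjunctively and are applied **while building the
network, before counting**: an association whose evidence falls below
threshold should not count toward a subject's support. The pre-gate
network is available by building with an empty gate; the screening
report uses it to label subjects whose evidence was entirely gated away
(drop reason `gated`).

Self hits — edges whose subject id equals any query id — are stored and
flagged but excluded from counts by default (a flag re-includes them):
queries trivially re-finding themselves, or each other, would add a
constant to every count. Rank is stored as an edge attribute but never
weighted: the association definition is rank-free by design; low rank is
precisely what the method is meant to see past.

## Screening

A hit is retained iff `assoc ≥ min_associations` and it is not
explicitly excluded, or it is explicitly included. Toggles dominate the
threshold in both directions, and an id toggled both ways is an error,
never a silent choice. Drop reasons are single-valued with fixed
precedence (excluded → gated → below_min_associations) so reports are
deterministic. The default threshold is 2: one association is ordinary
BLAST output; two or more distinct queries agreeing on a subject is the
signal the network exists to find.

Sequence selection always carries the supplied queries (minus explicit
excludes) plus one record per retained hit. Hit residues come from a
subject FASTA database when available; otherwise they are reconstructed
from the best HSP's subject row (gaps stripped, minus-strand segments
reverse-complemented) and flagged `partial`, since an HSP covers only
the aligned region. Reports record which route was used.

## Built-in phylogenetics stages

These exist so the full pipeline runs with no external binaries;
production users plug ClustalW/MAFFT-class aligners and PHYLIP/PhyML
-class tree programs in through file-exchange adapters, which are
recorded in provenance but deliberately never exercised by the tests.

- **Pairwise alignment**: Needleman–Wunsch, linear gap model, defaults
  match +1 / mismatch −1 / gap −2. Traceback ties break diagonal > up >
  left, making the optimum unique and byte-reproducible.
- **Multiple alignment**: center-star. The center maximizes the total
  pairwise score (ties: smallest id); every other sequence is aligned to
  the center and gaps are merged into the center coordinate system
  ("once a gap, always a gap"). Every row de-gaps exactly to its input —
  a property the suite checks on arbitrary instances.
- **Distances**: p-distance over sites where both rows have an
  unambiguous base (gaps and ambiguity codes excluded; zero comparable
  sites is an error, not a zero). The JC69 correction
  d = −(3/4)·ln(1 − 4p/3) assumes equal rates and base frequencies and
  saturates at p ≥ 0.75, which is reported as an error rather than
  clamped. U and T are compared literally, not merged.
- **Neighbor joining**: Saitou–Nei with the Studier–Keppler Q criterion;
  branch lengths l_i = d(i,j)/2 + (R_i − R_j)/(2(n−2)); reduction
  d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Q ties break on the
  lexicographically smallest cluster-id pair, where a cluster's id is
  its smallest leaf label; children are ordered the same way. On
  additive input the generating topology and all path lengths are
  recovered (checked to 1e-9 over random 4–20-leaf trees). Negative
  branch lengths, which NJ can produce on non-additive input, are kept
  by default and clamped to zero under a flag. Two taxa split the single
  distance evenly. One numerical subtlety: Q is computed vectorized and
  is not bitwise symmetric, so the minimum is taken over the same upper
  triangle the tie-break scan visits.

## Formats

- **FASTA**: 60-column wrap; `id description` headers; read∘write is the
  identity on (id, description, residues).
- **PHYLIP**: sequential layout only. The default *relaxed* dialect
  writes full names (modern tools accept them and accessions survive);
  the *strict* dialect writes classic 10-character padded names and
  returns a sanitization map, with truncation collisions a hard error.
- **Newick**: the writer emits shortest round-tripping float
  representations and a fixed child order, so equal trees produce equal
  bytes; labels containing Newick metacharacters are sanitized with the
  map returned to the caller. Parsing is delegated to dendropy, whose
  errors carry line/column positions.
- **GraphML / TSV / JSON** network exports sort hits by descending
  association count then id, and edges by query then rank, so identical
  networks export to identical bytes regardless of input order.

## Pipeline, queue, provenance

A run is import → blast parse → network + screening (optional halt
here, mirroring the generate-report-and-stop workflow) → sequence
selection → alignments → trees, with many-to-one fan-out: one screening
report can feed several alignment configurations, and one alignment
several tree configurations, all recorded against the same upstream
artifact checksums.

Artifacts contain no wall-clock timestamps; timestamps live only in job
and provenance metadata. This is what makes the determinism contract
possible: the same configuration always produces byte-identical
artifacts, and replaying a provenance record (which stores every
parameter actually consumed, defaults included, plus input/output
SHA-256 checksums) reproduces them exactly. Provenance files are
immutable; a rerun of the same run id writes a numbered sibling.

The queue is a single JSON state file rewritten atomically
(write-temp-then-rename). Jobs move queued → running → done|failed and
nowhere else; a stage failure marks that job failed with its error
message and touches nothing else; a process restart sees exactly the
persisted states. Single-worker FIFO execution is the default and the
concurrency contract (at most one running job per worker, atomic
transitions) is part of the interface rather than any particular
mechanism.

## The fixture generator

`synthfix` emulates a small environmental-collection screening problem:
random query sequences (default length 200 nt), a planted binary
query × subject incidence matrix (given explicitly or realized from a
density, default 0.3, with every subject guaranteed at least one hit),
and simulated BLASTN output with exactly one row per planted pair. Each
subject is a mutated copy (default per-site substitution rate 0.02,
i.e. ≈98 % identity — close relatives of the kind 16S screening targets)
of the *first* query that hits it; the reported percent identity is the
realized Hamming identity for that pair. Bit scores are 2 × matching
sites and e-values the deterministic monotone transform 10^(−bit/10)
floored at 1e-180.

What this does and does not show: the fixture makes the planted column
sums the unambiguous ground truth for association counting and
screening, and its XML emitter mirrors the tabular rows exactly for
parser-parity checks. It does **not** model BLAST's Karlin–Altschul
statistics, partial/overlapping HSPs, minus-strand hits (exercised by
unit tests directly), or the fact that in real data a subject's
similarity to its *other* associated queries varies freely — so passing
tests demonstrate the bookkeeping and algorithms, not BLAST score
realism.

Everything is driven by one integer seed through a counter-based
generator (`numpy.random.default_rng`), so bundles are byte-identical
across runs and platforms.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
fixtures up to 50 queries × 200 subjects for count-recovery checks,
100-trial monotonicity sweeps, 50 random 4–20-leaf trees for NJ, 100
instances per format round-trip, and a 3 × 10 pipeline run for the
determinism/provenance/queue checks. These sizes exercise every code
path; the algorithms themselves are O(n²)–O(n³) and have no scale
switches.

## Known limitations

- Center-star alignment is a heuristic stand-in; for publication-grade
  alignments use the aligner adapter.
- Hit reconstruction from HSP segments yields partial sequences; trees
  mixing full-length queries with partial hits share only the aligned
  region's signal.
- JC69 is the only substitution correction offered; saturated pairs are
  errors by design.
- Live BLAST execution is an adapter contract only; the package parses
  files and never performs network queries.
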