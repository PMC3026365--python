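# assocnet

Screening environmental DNA sequences (typically 16S rRNA phylotypes) by
the **network of their collective BLASTN results**, then carrying the
selected sequences through alignment, distance estimation and
neighbor-joining tree inference — as a scriptable library and CLI with a
persistent job queue and permanent per-stage provenance.

## Why association networks?

Picking database relatives by top BLASTN rank is fragile: unequal rates
of change and convergence mean neither the top hit nor the most similar
sequence is always the closest relative. The alternative — throwing many
hits per query into one tree — makes alignments poor and trees hard to
read.

`assocnet` applies the association principle instead: if queries *A*,
*B* and *C* each return database sequence *a* as a hit, at whatever
rank, then *a* is *associated* with all three. Formally, for a query set
Q and per-query hit lists H(q), the association count of a subject *s* is

    assoc(s) = |{ q ∈ Q : s ∈ H(q) }|

computed over a bipartite graph with one evidence-carrying edge per
(query, subject) pair (best HSP: bit score, e-value, % identity, rank).
Subjects hit by many supplied queries are phylogenetically interesting
even when they rank low in every individual search. Screening keeps
subjects with `assoc(s) ≥ m` (default m = 2), after optional per-edge
evidence gates (max e-value, min bit score, min identity, max rank) and
explicit per-sequence include/exclude toggles.

Downstream, the built-in stages are classical: center-star multiple
alignment over Needleman–Wunsch pairwise alignments (+1/−1/−2 linear
gaps), p-distances with the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), and Saitou–Nei neighbor joining with the
Studier–Keppler criterion Q(i,j) = (n−2)·d(i,j) − R_i − R_j. Adapters
let production runs substitute external aligners and tree programs while
keeping the same file contracts (FASTA/PHYLIP in, PHYLIP/Newick out).

## Worked example

Generate a synthetic collection with planted association structure
(3 queries × 8 subjects, half the pairs planted), build the network and
screen it:

```sh
$ assocnet fixture --queries 3 --subjects 8 --density 0.5 --seed 11 --out fix
fixture written to fix (3x8, seed 11)

$ assocnet network fix/blast.tab --format tab
3 queries, 8 hits, 11 edges
s0006   2
s0007   2
s0008   2
s0001   1
...

$ assocnet screen fix/blast.tab --format tab --min-assoc 2
retained 3 / 8 hits
subject  status    reason                   associations  queries
s0006    retained  -                        2             q002,q003
s0007    retained  -                        2             q001,q002
s0008    retained  -                        2             q001,q003
s0001    dropped   below_min_associations   1             q001
...
```

Subjects s0006–s0008 are each hit by two distinct queries, so they pass
the m = 2 threshold; the singly-associated subjects are dropped. The
full pipeline then aligns the 3 queries + 3 retained subjects and infers
a neighbor-joining tree:

```sh
$ cat run.yaml
run_id: demo
collection: {name: demo, format: fasta, path: fix/queries.fasta}
blast: {format: tab, path: fix/blast.tab}
subject_db: {path: fix/subjects.fasta}
screening: {min_associations: 2}

$ assocnet run run.yaml --workspace ws
run demo: 5 stages
  collections/demo.fasta
  ...
  reports/demo.screening.json
  alignments/demo.aln1.phy
  trees/demo.aln1.tree1.nwk
  trees/demo.aln1.tree1.svg

$ cat ws/trees/demo.aln1.tree1.nwk
((q001:-0.009042...,s0007:0.039658...):0.012467...,((q002:0.005882...,
s0006:-0.000814...):0.586842...,q003:0.565119...):0.051057...,s0008:0.010809...);
```

Each retained subject attaches next to a query it was planted from
(s0007 with q001, s0006 with q002) with short branches — the tree
recovers the planted relatedness. Every stage's parameters, inputs and
output checksums are stored under `ws/provenance/demo.json`; re-running
the same config (or replaying the record) reproduces every artifact
byte for byte. Jobs can also be queued and drained asynchronously:

```sh
assocnet queue add full "$(cat run.json)" --workspace ws
assocnet queue work --workspace ws
```

## Layout

- `src/assocnet/seqio.py` — FASTA/GenBank/raw import, collections
- `src/assocnet/blast_io.py` — BLASTN XML and tabular parsers, HSP dedupe
- `src/assocnet/network.py` — association network, gates, GraphML/TSV/JSON export
- `src/assocnet/screening.py` — threshold + toggle screening, sequence selection
- `src/assocnet/phylo/` — NW, center-star MSA, p/JC69 distances, NJ, Newick/PHYLIP/SVG, adapters
- `src/assocnet/pipeline.py` — staged runs, job queue, provenance
- `src/assocnet/synthfix.py` — planted-structure fixture generator
- `docs/methods.md` — models, parameters, numerical choices, limitations
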