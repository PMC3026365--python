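import pytest

from assocnet.blast_io import (
    HitEvidence,
    dedupe_evidence,
    parse_blast_tabular,
    parse_blast_xml,
)
from assocnet.errors import ParseError
from assocnet.synthfix import FixtureSpec, generate_fixture


def ev(subject="s1", bit=100.0, evalue=1e-30, alen=100, **kw):
    base = dict(
        query_id="q1", subject_id=subject, rank=1, evalue=evalue,
        bit_score=bit, percent_identity=98.0, align_length=alen,
        q_start=1, q_end=100, s_start=1, s_end=100,
    )
    base.update(kw)
    return HitEvidence(**base)


class TestDedupe:
    def test_highest_bit_wins(self):
        assert dedupe_evidence([ev(bit=100), ev(bit=90)]).bit_score == 100

    def test_evalue_breaks_bit_ties(self):
        best = dedupe_evidence([ev(bit=100, evalue=1e-30), ev(bit=100, evalue=1e-40)])
        assert best.evalue == 1e-40

    def test_align_length_breaks_remaining_ties(self):
        best = dedupe_evidence([ev(alen=80), ev(alen=120)])
        assert best.align_length == 120

    def test_single_row_identity(self):
        single = ev()
        assert dedupe_evidence([single]) is single

    def test_idempotent(self):
        best = dedupe_evidence([ev(bit=100), ev(bit=90)])
        assert dedupe_evidence([best]) is best


class TestTabular:
    def test_single_row_field_mapping(self):
        row = "q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t181\n"
        (result,) = parse_blast_tabular(row)
        (hit,) = result.hits
        assert (hit.query_id, hit.subject_id) == ("q1", "s1")
        assert hit.evalue == 1e-50 and hit.bit_score == 181
        assert hit.percent_identity == 98.5 and hit.rank == 1

    def test_duplicate_pair_keeps_best_row(self):
        rows = (
            "q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t181\n"
            "q1\ts1\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-40\t150\n"
        )
        (result,) = parse_blast_tabular(rows)
        assert len(result.hits) == 1
        assert result.hits[0].bit_score == 181

    def test_comment_only_stream_is_empty(self):
        assert parse_blast_tabular("# header\n# another\n") == []

    def test_ranks_contiguous_after_dedupe(self):
        rows = "".join(
            f"q1\ts{i}\t98.0\t100\t2\t0\t1\t100\t1\t100\t1e-50\t{200 - i}\n"
            for i in range(5)
        )
        (result,) = parse_blast_tabular(rows + rows)  # duplicated block
        assert [h.rank for h in result.hits] == [1, 2, 3, 4, 5]

    def test_wrong_field_count_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_blast_tabular(
                "q1\ts1\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t181\nq1\ts2\t98\n"
            )

    def test_unparseable_numeric_field(self):
        with pytest.raises(ParseError, match="pident"):
            parse_blast_tabular("q1\ts1\tNA\t100\t1\t0\t1\t100\t1\t100\t1e-50\t181\n")

    def test_minus_strand_from_descending_subject_coords(self):
        row = "q1\ts1\t98.5\t100\t1\t0\t1\t100\t100\t1\t1e-50\t181\n"
        (result,) = parse_blast_tabular(row)
        assert result.hits[0].strand == "minus"


@pytest.fixture(scope="module")
def bundle():
    return generate_fixture(FixtureSpec(n_queries=3, n_subjects=5, seed=5, incidence=0.5))


class TestXml:

    def test_iterations_become_query_results(self, bundle):
        results = parse_blast_xml(bundle.blast_xml)
        assert [r.query_id for r in results] == bundle.query_ids()

    def test_segments_populated_from_hseq(self, bundle):
        results = parse_blast_xml(bundle.blast_xml)
        subject_by_id = {s.id: s.residues for s in bundle.subjects}
        for r in results:
            for h in r.hits:
                assert h.subject_aligned_segment == subject_by_id[h.subject_id]

    def test_multiple_hsps_collapse_to_best(self):
        xml = _xml_with_two_hsps(bits=(80.0, 95.0))
        (result,) = parse_blast_xml(xml)
        (hit,) = result.hits
        assert hit.bit_score == 95.0

    def test_zero_hit_iteration_is_empty_not_error(self):
        xml = _xml_frame("")
        (result,) = parse_blast_xml(xml)
        assert result.hits == ()

    def test_non_blast_xml_rejected(self):
        with pytest.raises(ParseError, match="BlastOutput"):
            parse_blast_xml("<root><child/></root>")

    def test_malformed_xml_rejected(self):
        with pytest.raises(ParseError):
            parse_blast_xml("<BlastOutput><unclosed>")


class TestParity:
    def test_xml_and_tabular_agree_on_shared_fields(self):
        bundle = generate_fixture(
            FixtureSpec(n_queries=4, n_subjects=8, seed=9, incidence=0.4)
        )
        by_pair = {}
        for r in parse_blast_tabular(bundle.blast_tab):
            for h in r.hits:
                by_pair[(h.query_id, h.subject_id)] = h
        for r in parse_blast_xml(bundle.blast_xml):
            for h in r.hits:
                t = by_pair.pop((h.query_id, h.subject_id))
                assert (t.rank, t.evalue, t.bit_score, t.percent_identity) == (
                    h.rank, h.evalue, h.bit_score, h.percent_identity
                )
        assert not by_pair


def _hsp(bits: float) -> str:
    return f"""<Hsp><Hsp_num>1</Hsp_num>
<Hsp_bit-score>{bits}</Hsp_bit-score><Hsp_evalue>1e-30</Hsp_evalue>
<Hsp_query-from>1</Hsp_query-from><Hsp_query-to>100</Hsp_query-to>
<Hsp_hit-from>1</Hsp_hit-from><Hsp_hit-to>100</Hsp_hit-to>
<Hsp_identity>98</Hsp_identity><Hsp_align-len>100</Hsp_align-len>
<Hsp_hseq>ACGT</Hsp_hseq></Hsp>"""


def _xml_frame(hits: str) -> str:
    return f"""<?xml version="1.0"?>
<BlastOutput><BlastOutput_program>blastn</BlastOutput_program>
<BlastOutput_iterations><Iteration>
<Iteration_iter-num>1</Iteration_iter-num>
<Iteration_query-def>q1 test query</Iteration_query-def>
<Iteration_hits>{hits}</Iteration_hits>
</Iteration></BlastOutput_iterations></BlastOutput>"""


def _xml_with_two_hsps(bits) -> str:
    hit = (
        "<Hit><Hit_num>1</Hit_num><Hit_id>lcl|s1</Hit_id>"
        "<Hit_def>s1</Hit_def><Hit_accession>s1</Hit_accession>"
        f"<Hit_len>100</Hit_len><Hit_hsps>{_hsp(bits[0])}{_hsp(bits[1])}</Hit_hsps></Hit>"
    )
    return _xml_frame(hit)
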