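import pytest

from assocnet.blast_io import parse_blast_tabular, parse_blast_xml
from assocnet.errors import ValidationError
from assocnet.network import EdgeGate, build_network
from assocnet.screening import (
    ScreeningCriteria,
    apply_screening,
    load_subject_db,
    reconstruct_hit_sequence,
    select_sequences,
)
from assocnet.seqio import create_collection, read_fasta
from assocnet.synthfix import FixtureSpec, generate_fixture


@pytest.fixture
def abc_net(abc_results):
    return build_network(abc_results)


class TestThreshold:
    @pytest.mark.parametrize("m, retained", [(1, True), (2, True), (3, True), (4, False)])
    def test_triply_associated_hit_against_thresholds(self, abc_net, m, retained):
        report = apply_screening(abc_net, ScreeningCriteria(min_associations=m))
        assert ("a" in report.retained_ids()) is retained
        if not retained:
            (entry,) = [h for h in report.dropped_hits if h.subject_id == "a"]
            assert entry.drop_reason == "below_min_associations"

    def test_threshold_one_retains_everything(self, abc_net):
        report = apply_screening(abc_net, ScreeningCriteria(min_associations=1))
        assert not report.dropped_hits
        assert set(report.retained_ids()) == set(abc_net.hit_nodes)

    def test_monotone_in_threshold(self, abc_net):
        prev = None
        for m in (1, 2, 3, 4, 5):
            now = set(
                apply_screening(abc_net, ScreeningCriteria(min_associations=m)).retained_ids()
            )
            if prev is not None:
                assert now <= prev
            prev = now


class TestToggles:
    def test_include_overrides_threshold(self, abc_net):
        crit = ScreeningCriteria(min_associations=4, include_ids=frozenset({"a"}))
        assert "a" in apply_screening(abc_net, crit).retained_ids()

    def test_exclude_overrides_threshold(self, abc_net):
        crit = ScreeningCriteria(min_associations=1, exclude_ids=frozenset({"a"}))
        report = apply_screening(abc_net, crit)
        (entry,) = [h for h in report.dropped_hits if h.subject_id == "a"]
        assert entry.drop_reason == "excluded"

    def test_overlapping_toggles_rejected(self):
        with pytest.raises(ValidationError, match="'a'"):
            ScreeningCriteria(include_ids=frozenset({"a"}), exclude_ids=frozenset({"a"}))


class TestPartitionAndDeterminism:
    def test_retained_plus_dropped_cover_hits_exactly(self, abc_net):
        report = apply_screening(abc_net, ScreeningCriteria(min_associations=2))
        retained = set(report.retained_ids())
        dropped = {h.subject_id for h in report.dropped_hits}
        assert retained | dropped == set(abc_net.hit_nodes)
        assert not (retained & dropped)

    def test_rescreening_reproduces_report_bytes(self, abc_net):
        crit = ScreeningCriteria(min_associations=2, exclude_ids=frozenset({"other1"}))
        a = apply_screening(abc_net, crit).to_json()
        b = apply_screening(abc_net, crit).to_json()
        assert a == b

    def test_gated_drop_reason_with_pregate_universe(self, abc_results):
        gate = EdgeGate(min_bit_score=500.0)  # removes every edge
        net = build_network(abc_results, gate)
        pregate = build_network(abc_results)
        report = apply_screening(
            net, ScreeningCriteria(min_associations=1, gate=gate), pregate_net=pregate
        )
        assert not report.retained_hits
        assert {h.drop_reason for h in report.dropped_hits} == {"gated"}
        assert {h.subject_id for h in report.dropped_hits} == set(pregate.hit_nodes)


class TestSelectSequences:
    @pytest.fixture
    def fixture_run(self):
        bundle = generate_fixture(
            FixtureSpec(n_queries=3, n_subjects=4, seed=13, incidence=0.6)
        )
        net = build_network(parse_blast_tabular(bundle.blast_tab))
        report = apply_screening(net, ScreeningCriteria(min_associations=1))
        coll = create_collection("fix", read_fasta(bundle.queries_fasta))
        return bundle, net, report, coll

    def test_cardinality_with_subject_db(self, fixture_run):
        bundle, _, report, coll = fixture_run
        db = load_subject_db(read_fasta(bundle.subjects_fasta))
        seqset = select_sequences(report, coll, subject_db=db)
        assert len(seqset.members) == len(coll) + len(report.retained_hits)
        assert [m.id for m in seqset.members[: len(coll)]] == coll.ids()
        assert set(seqset.origin.values()) == {"query", "hit"}

    def test_no_retained_hits_gives_queries_only(self, fixture_run):
        bundle, net, _, coll = fixture_run
        report = apply_screening(net, ScreeningCriteria(min_associations=99))
        seqset = select_sequences(report, coll)
        assert [m.id for m in seqset.members] == coll.ids()

    def test_reconstruction_from_xml_segments(self, fixture_run):
        bundle, _, _, coll = fixture_run
        net = build_network(parse_blast_xml(bundle.blast_xml))
        report = apply_screening(net, ScreeningCriteria(min_associations=1))
        seqset = select_sequences(report, coll, net=net)
        true_subjects = {s.id: s.residues for s in bundle.subjects}
        for m in seqset.members:
            if seqset.origin[m.id] == "hit":
                assert m.partial
                assert m.residues == true_subjects[m.id]

    def test_unresolvable_hits_listed(self, fixture_run):
        _, net, report, coll = fixture_run
        # tabular-derived network: no segments, and no subject db given
        with pytest.raises(ValidationError, match="s0"):
            select_sequences(report, coll, net=net)

    def test_excluded_query_left_out(self, fixture_run):
        bundle, net, _, coll = fixture_run
        crit = ScreeningCriteria(
            min_associations=99, exclude_ids=frozenset({coll.ids()[0]})
        )
        report = apply_screening(net, crit)
        seqset = select_sequences(report, coll)
        assert coll.ids()[0] not in [m.id for m in seqset.members]


class TestReconstruct:
    def _ev(self, segment, s_start=1, s_end=4, alen=4):
        from assocnet.blast_io import HitEvidence

        return HitEvidence(
            query_id="q", subject_id="s", rank=1, evalue=0.0, bit_score=10.0,
            percent_identity=100.0, align_length=alen, q_start=1, q_end=alen,
            s_start=s_start, s_end=s_end, subject_aligned_segment=segment,
        )

    def test_gaps_stripped(self):
        rec = reconstruct_hit_sequence([self._ev("AC-GT", alen=5)])
        assert rec.residues == "ACGT" and rec.partial

    def test_minus_strand_reverse_complemented(self):
        rec = reconstruct_hit_sequence([self._ev("AACG", s_start=4, s_end=1)])
        assert rec.residues == "CGTT"

    def test_largest_segment_selected(self):
        short = self._ev("ACGT", alen=80)
        long = self._ev("ACGTACGT", alen=120)
        assert reconstruct_hit_sequence([short, long]).residues == "ACGTACGT"

    def test_no_segment_data_rejected(self):
        ev = self._ev(None)
        with pytest.raises(ValidationError, match="segment"):
            reconstruct_hit_sequence([ev])
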