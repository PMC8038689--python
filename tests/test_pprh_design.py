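import random

import pytest

from pprh import catalog
from pprh.pprh_design import (
    DecompositionError,
    DesignError,
    assemble_editing_pprh,
    build_core,
    build_tail,
    decompose_pprh,
    design_candidates,
    try_decompose,
    validate_pprh,
)
from pprh.sequence_model import EditJunction, SeqRecord

T1 = {name: seq for name, (seq, _) in catalog.TABLE1_OLIGOS.items()}


class TestBuildCore:
    def test_exon6_core_matches_published_sequence(self):
        core = build_core(catalog.ARMS["E6"])
        assert core.full_core == "AGGAGGAAAAAGGCATCAAGTTTTTGAACTACGGAAAAAGGAGGA"
        # and it appears verbatim inside the published E6 editing PPRH
        assert core.full_core in T1["LDSHpE6I1DPstI"]

    def test_second_arm_is_reverse_not_complement(self):
        core = build_core(catalog.ARMS["promoter"])
        assert core.full_core.endswith("ACAGTGGGTGAAAAGGAAGGGG")

    def test_palindromic_arm(self):
        assert build_core("AAAA").full_core == "AAAATTTTTAAAA"

    def test_short_loop_rejected(self):
        with pytest.raises(DesignError):
            build_core("GGGGAAAA", loop_len=2)

    def test_ambiguous_arm_rejected(self):
        with pytest.raises(DesignError):
            build_core("GGGNAAAA")


@pytest.fixture(scope="module")
def junction_context():
    # restored reference: the published U20|D20 junction in neutral context
    seq = "TTTTCCCC" * 5 + catalog.U20 + catalog.D20 + "GGGGAAAA" * 5
    rec = SeqRecord(id="ref", seq=seq)
    jx = EditJunction(record_id="ref", coord=40 + 20)
    return rec, jx


class TestBuildTail:
    def test_plus_strand_ud_is_published_40mer(self, junction_context):
        rec, jx = junction_context
        tail = build_tail(rec, jx, "UD", 20, "+")
        assert tail.tail_sequence == catalog.U20 + catalog.D20

    def test_minus_strand_ud_is_published_control(self, junction_context):
        rec, jx = junction_context
        tail = build_tail(rec, jx, "UD", 20, "-")
        assert tail.tail_sequence == T1["UDPst1"]

    def test_mode_selects_windows(self, junction_context):
        rec, jx = junction_context
        assert build_tail(rec, jx, "U", 20, "+").tail_sequence == catalog.U20
        assert build_tail(rec, jx, "D", 20, "+").tail_sequence == catalog.D20

    def test_degenerate_window_rejected(self, junction_context):
        rec, jx = junction_context
        with pytest.raises(DesignError, match="degenerate"):
            build_tail(rec, jx, "UD", 0, "+")

    def test_junction_too_close_to_end(self):
        rec = SeqRecord(id="r", seq=catalog.D20 + "A" * 30)
        jx = EditJunction(record_id="r", coord=0)
        with pytest.raises(DesignError):
            build_tail(rec, jx, "UD", 20, "+")


class TestAssemble:
    @pytest.mark.parametrize(
        "name,arm_key,mode,strand",
        [
            ("LDSHpPrI1UPstI", "promoter", "D", "+"),
            ("LDSHpPrI1UDstI", "promoter", "UD", "+"),
            ("LDSHpE6I1DPstI", "E6", "D", "-"),
            ("LDSHpE6I1UDPstI", "E6", "UD", "-"),
            ("LDSHpE3I1UDPstI", "E3", "UD", "-"),
        ],
    )
    def test_published_designs_rebuild_byte_identically(
        self, junction_context, name, arm_key, mode, strand
    ):
        rec, jx = junction_context
        core = build_core(catalog.ARMS[arm_key])
        tail = build_tail(rec, jx, mode, 20, strand)
        pprh = assemble_editing_pprh(core, tail)
        assert pprh.full_seq == T1[name]

    def test_length_law(self):
        # |full| = |tail| + 5 + 2|arm| + 5
        expected = {
            "LDSHpPrI1UPstI": 74,
            "LDSHpPrI1UDstI": 94,
            "LDSHpE6I1DPstI": 70,
            "LDSHpE6I1UDPstI": 90,
            "LDSHpE3I1UDPstI": 84,
        }
        for name, length in expected.items():
            assert len(T1[name]) == length
            d = decompose_pprh(T1[name])
            assert length == len(d.tail) + 5 + 2 * len(d.arm1) + 5

    def test_tailless_pprh_is_bare_core(self):
        core = build_core(catalog.ARMS["E3"])
        pprh = assemble_editing_pprh(core, tail=None)
        assert pprh.full_seq == core.full_core


class TestDecompose:
    def test_exon6_six_t_run_split_by_mirror_constraint(self):
        d = decompose_pprh(T1["LDSHpE6I1DPstI"])
        assert d.tail == "CCCTTGCCCATGCCCGCGGT"
        assert d.linker == "TTTTT"
        assert d.arm1 == "AGGAGGAAAAAGGCATCAAG"
        assert d.loop == "TTTTT"
        assert d.arm2 == "GAACTACGGAAAAAGGAGGA"

    def test_exon3_arms_are_17mers(self):
        d = decompose_pprh(T1["LDSHpE3I1UDPstI"])
        assert (d.arm1, d.arm2) == ("GGACCAAGAGGTAAGGA", "AGGAATGGAGAACCAGG")

    @pytest.mark.parametrize("name", [n for n in T1 if n != "UDPst1"])
    def test_all_published_pprhs_reassemble(self, name):
        d = decompose_pprh(T1[name])
        assert d.arm2 == d.arm1[::-1]
        assert d.full_seq == T1[name]

    def test_mirror_violation_fails_with_diagnosis(self):
        with pytest.raises(DecompositionError) as exc:
            decompose_pprh("AAAATTTTTGGGG", min_arm=4)
        assert exc.value.best_attempt["violation"] == "arm2 is not the reverse of arm1"

    def test_tail_only_control_not_decomposable(self):
        assert try_decompose(T1["UDPst1"]) is None

    def test_random_74mer_not_decomposable(self):
        rng = random.Random(7)
        seq = "".join(rng.choice("ACGT") for _ in range(74))
        assert try_decompose(seq) is None

    def test_round_trip_over_randomized_designs(self, junction_context):
        """decompose(assemble(core, tail)) recovers the components exactly."""
        rec, jx = junction_context
        rng = random.Random(123)
        checked = 0
        while checked < 500:
            arm_len = rng.randint(12, 25)
            # purine-rich arm with occasional pyrimidine interruptions
            arm = "".join(
                rng.choice("AG") if rng.random() < 0.85 else rng.choice("CT")
                for _ in range(arm_len)
            )
            if arm[0] not in "AG" or arm[-1] not in "AG" or "TTTTT" in arm:
                continue
            mode = rng.choice(["U", "D", "UD"])
            strand = rng.choice("+-")
            core = build_core(arm)
            tail = build_tail(rec, jx, mode, 20, strand)
            pprh = assemble_editing_pprh(core, tail)
            d = decompose_pprh(pprh.full_seq)
            assert (d.tail, d.linker, d.arm1, d.loop, d.arm2) == (
                tail.tail_sequence,
                "TTTTT",
                arm,
                "TTTTT",
                arm[::-1],
            )
            checked += 1


class TestValidate:
    @pytest.mark.parametrize("name", [n for n in T1 if n != "UDPst1"])
    def test_published_editing_pprhs_pass(self, name):
        v = validate_pprh(T1[name])
        assert v.decomposable and v.mirror_ok

    def test_control_is_tail_only(self, junction_context):
        rec, jx = junction_context
        v = validate_pprh(T1["UDPst1"], reference=rec, junction=jx)
        assert not v.decomposable
        assert v.tail_only is True

    def test_tail_mapping_and_motif_checks(self, junction_context):
        rec, jx = junction_context
        v = validate_pprh(T1["LDSHpPrI1UDstI"], reference=rec, junction=jx)
        assert v.tail_maps_to_reference is True
        assert v.motif_in_tail is True

    def test_random_sequence_reported_not_raised(self):
        v = validate_pprh("ACGT" * 20)
        assert not v.decomposable
        assert v.failure


class TestDesignCandidates:
    def test_fixture_yields_candidates_for_all_embedded_arms(self, fixture_set):
        fx = fixture_set
        cands = design_candidates(fx.mutant, fx.restored, fx.junction, fx.mutant_gene)
        arms_found = {c.track.seq for c in cands}
        assert set(catalog.ARMS.values()) <= arms_found
        for c in cands:
            assert c.verdict.decomposable
            assert c.verdict.tail_maps_to_reference

    def test_trackless_record_yields_nothing(self, fixture_set):
        # neither strand of a CCA repeat reaches the purity gate (a plain
        # all-pyrimidine record would expose an all-purine minus strand)
        fx = fixture_set
        rec = SeqRecord(id=fx.mutant.id, seq="CCA" * 100)
        log = []
        assert design_candidates(rec, fx.restored, fx.junction, fx.mutant_gene, log=log) == []
        assert log  # the empty result is logged

    def test_deterministic_ranking(self, fixture_set):
        fx = fixture_set
        a = design_candidates(fx.mutant, fx.restored, fx.junction, fx.mutant_gene)
        b = design_candidates(fx.mutant, fx.restored, fx.junction, fx.mutant_gene)
        assert [c.pprh.name for c in a] == [c.pprh.name for c in b]
        assert [c.pprh.full_seq for c in a] == [c.pprh.full_seq for c in b]
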