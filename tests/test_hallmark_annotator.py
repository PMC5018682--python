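"""Hallmark motif finders, the composed report, and single-feature ablations."""

import dataclasses

import pytest

from opsin_charter import (DRY, LRTPXN, QAKK, FormatError, MotifPattern, OpsinParams,
                           annotate, build_topology, find_cys_pair, find_motif,
                           find_schiff_lysine, find_tuning_residue, make_opsin)


class TestFindMotif:
    def test_planted_motifs_found_at_planted_positions(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        for pattern, name in ((LRTPXN, "LRTPXN"), (DRY, "DRY"), (QAKK, "QAKK")):
            hit = find_motif(rec, topo, pattern)
            assert hit is not None
            assert hit.start == truth.motif_positions[name]

    def test_wildcard_position_matches_any_residue(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        hit = find_motif(rec, topo, LRTPXN)
        assert hit.matched == "LRTPGN"   # X matched the concrete G

    def test_region_gate_blocks_out_of_region_occurrences(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        # DRY is planted in CL2; demanding it in EL1 must come up empty
        elsewhere = MotifPattern("DRY_EL1", "DRY", ("EL1",))
        assert find_motif(rec, topo, elsewhere) is None

    def test_unknown_region_label_rejected(self):
        with pytest.raises(FormatError):
            MotifPattern("bad", "DRY", ("XL9",))


class TestSchiffLysine:
    def test_single_planted_lysine_found(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        pos, ambiguous = find_schiff_lysine(rec, topo)
        assert pos == truth.schiff_position + 1
        assert not ambiguous

    def test_absent_when_not_planted(self):
        rec, _ = make_opsin(13, OpsinParams(plant_schiff=False))
        topo = build_topology(rec)
        pos, _ = find_schiff_lysine(rec, topo)
        assert pos is None

    def test_multiple_lysines_pick_nearest_midpoint_with_flag(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        tm7 = topo.region("TM7")
        residues = list(rec.residues)
        residues[tm7[0] + 3] = "K"      # second K toward the TM7 edge
        from opsin_charter import SeqRecord

        doctored = SeqRecord(id="two_k", kind="protein", residues="".join(residues))
        topo2 = build_topology(doctored)
        pos, ambiguous = find_schiff_lysine(doctored, topo2)
        assert ambiguous
        assert pos == truth.schiff_position + 1   # planted K sits at the midpoint


class TestCysPairAndTuning:
    def test_planted_pair_found(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        pair, multiple = find_cys_pair(rec, topo)
        assert pair == (truth.cys_positions[0] + 1, truth.cys_positions[1] + 1)
        assert not multiple

    def test_absent_when_one_loop_lacks_cysteine(self):
        rec, _ = make_opsin(17, OpsinParams(plant_cys_pair=False))
        topo = build_topology(rec)
        pair, _ = find_cys_pair(rec, topo)
        assert pair is None

    def test_tyrosine_three_after_first_cysteine_reads_visible(self, complete_opsin):
        rec, truth = complete_opsin
        topo = build_topology(rec)
        pair, _ = find_cys_pair(rec, topo)
        pos, res, offset, in_tm3, klass = find_tuning_residue(rec, topo, pair)
        assert klass == "visible"
        assert res == "Y"
        assert offset == +3
        assert pos == truth.tuning_position + 1

    def test_phenylalanine_reads_uv(self):
        rec, truth = make_opsin(19, OpsinParams(tuning="F"))
        topo = build_topology(rec)
        pair, _ = find_cys_pair(rec, topo)
        _, res, _, _, klass = find_tuning_residue(rec, topo, pair)
        assert klass == "UV" and res == "F"

    def test_neither_reads_unknown(self):
        rec, _ = make_opsin(23, OpsinParams(tuning=None))
        topo = build_topology(rec)
        pair, _ = find_cys_pair(rec, topo)
        *_, klass = find_tuning_residue(rec, topo, pair)
        assert klass == "unknown"


FEATURE_FLAGS = {
    "plant_schiff": lambda r: r.schiff_lysine_pos is not None,
    "plant_lrtpxn": lambda r: r.lrtpxn is not None,
    "plant_dry": lambda r: r.dry is not None,
    "plant_qakk": lambda r: r.qakk is not None,
    "plant_cys_pair": lambda r: r.cys_pair is not None,
}


class TestAnnotate:
    def test_complete_opsin_reports_everything(self, complete_opsin):
        rec, _ = complete_opsin
        rep = annotate(rec)
        assert rep.has_7tm and not rep.low_confidence
        assert all(check(rep) for check in FEATURE_FLAGS.values())
        assert rep.spectral_class == "visible"
        assert rep.verdict_functional

    def test_qakk_ablation_leaves_verdict_functional(self):
        """A receptor missing only the G-protein-contact QAKK motif still
        passes the functional verdict (known functional homologs lack it)."""
        rec, _ = make_opsin(31, OpsinParams(plant_qakk=False))
        rep = annotate(rec)
        assert rep.qakk is None
        assert rep.verdict_functional

    def test_dry_ablation_breaks_verdict(self):
        rec, _ = make_opsin(33, OpsinParams(plant_dry=False))
        rep = annotate(rec)
        assert rep.dry is None
        assert not rep.verdict_functional

    @pytest.mark.parametrize("ablated", sorted(FEATURE_FLAGS))
    def test_single_ablation_flips_exactly_that_feature(self, ablated):
        """Each of the plantable hallmarks is independently detected: ablating
        one flips its flag and leaves the independent flags unchanged."""
        for seed in range(41, 61):
            rep_full = annotate(make_opsin(seed)[0])
            rep_abl = annotate(make_opsin(seed, OpsinParams(**{ablated: False}))[0])
            assert rep_full.has_7tm and rep_abl.has_7tm
            for name, check in FEATURE_FLAGS.items():
                if name == ablated:
                    assert check(rep_full) and not check(rep_abl)
                else:
                    assert check(rep_full) == check(rep_abl) == True

    def test_tuning_ablation_flips_spectral_class_only(self):
        for seed in range(3):
            rep_full = annotate(make_opsin(seed)[0])
            rep_abl = annotate(make_opsin(seed, OpsinParams(tuning=None))[0])
            assert rep_full.spectral_class == "visible"
            assert rep_abl.spectral_class == "unknown"
            for name, check in FEATURE_FLAGS.items():
                assert check(rep_full) == check(rep_abl) == True

    def test_reported_positions_fall_inside_their_regions(self):
        for seed in range(20):
            rec, _ = make_opsin(seed)
            rep = annotate(rec)
            topo = build_topology(rec)
            assert topo.label_at(rep.schiff_lysine_pos - 1) == "TM7"
            assert topo.label_at(rep.lrtpxn.start) == "CL1"
            assert topo.label_at(rep.dry.start) == "CL2"
            assert topo.label_at(rep.qakk.start) == "CL3"
            assert topo.label_at(rep.cys_pair[0] - 1) == "EL2"
            assert topo.label_at(rep.cys_pair[1] - 1) == "EL3"

    def test_annotate_is_deterministic(self, complete_opsin):
        rec, _ = complete_opsin
        assert dataclasses.asdict(annotate(rec)) == dataclasses.asdict(annotate(rec))

    def test_low_confidence_fallback_still_reports_motifs(self):
        """With a broken topology the motif search widens to the whole
        sequence and the report is flagged low-confidence."""
        rec, _ = make_opsin(37)
        topo = build_topology(rec)
        tm6_end = topo.region("TM6")[1]
        from opsin_charter import SeqRecord

        truncated = SeqRecord(id="trunc", kind="protein",
                              residues=rec.residues[:tm6_end + 5])
        rep = annotate(truncated)
        assert rep.low_confidence and not rep.has_7tm
        assert rep.lrtpxn is not None and rep.dry is not None
        assert not rep.verdict_functional
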