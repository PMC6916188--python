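import numpy as np
import pytest

import doublesub as ds
from doublesub import genetic_code as gc
from doublesub import null_models as nm

from conftest import make_triplet


class TestEligibleWindow:
    @pytest.mark.parametrize(
        "ci,cii,config,ok",
        [
            ("GCT", "CGA", nm.NM1_23, True),   # Ala fourfold + Arg twofold purine
            ("GCT", "CGT", nm.NM1_23, False),  # CGT third position pyrimidine
            ("GCT", "CGA", nm.NM1_12, True),
            ("AAA", "CGA", nm.NM1_23, False),  # Lys not fourfold
            ("GCT", "GGT", nm.NM2, True),      # Ala + Gly fourfold boxes
            ("GCT", "AAA", nm.NM2, False),
        ],
    )
    def test_examples(self, ci, cii, config, ok):
        assert ds.eligible_window(ci, cii, config) is ok

    def test_unknown_config_rejected(self):
        with pytest.raises(ValueError):
            ds.eligible_window("GCT", "CGA", "NM3")


class TestScanNulls:
    def test_double_on_one_branch(self):
        # ancestral (GCT, CGA); ingroup 1 carries T>A at codon-i pos 3 and
        # C>A at codon-ii pos 1 (both synonymous): one b instance.
        out = "GCTCGA"
        in1 = "GCAAGA"
        in2 = "GCTCGA"
        records = ds.scan_nulls([make_triplet(out, in1, in2)])
        key = nm.NullWindowKey(nm.NM1_23, ("T", "A"), ("C", "A"), "C")
        assert records[key].b == 1 and records[key].a1 == 0 and records[key].a2 == 0
        # the same event also appears under the NM1_12 keying (constant G
        # from codon-ii position 2)
        key12 = nm.NullWindowKey(nm.NM1_12, ("T", "A"), ("C", "A"), "G")
        assert records[key12].b == 1

    def test_single_change_counts_as_a1(self):
        out = "GCTCGA"
        in1 = "GCACGA"  # only the fourfold site changed
        in2 = "GCTCGA"
        records = ds.scan_nulls([make_triplet(out, in1, in2)])
        key = nm.NullWindowKey(nm.NM1_23, ("T", "A"), ("C", "A"), "C")
        assert records[key].a1 == 1 and records[key].b == 0

    def test_second_site_single_counts_as_a2(self):
        out = "GCTCGA"
        in1 = "GCTAGA"
        in2 = "GCTCGA"
        records = ds.scan_nulls([make_triplet(out, in1, in2)])
        key = nm.NullWindowKey(nm.NM1_23, ("T", "A"), ("C", "A"), "C")
        assert records[key].a2 == 1 and records[key].b == 0

    def test_anc_counts_per_branch(self):
        out = "GCTCGA"
        records = ds.scan_nulls([make_triplet(out, out, out)])
        key = nm.NullWindowKey(nm.NM1_23, ("T", "A"), ("C", "A"), "C")
        assert records[key].anc_count == 2

    def test_no_eligible_windows(self):
        out = "AAAAAA"
        assert ds.scan_nulls([make_triplet(out, out, out)]) == {}

    def test_nonsynonymous_change_excluded(self):
        # codon-ii first position C>G (CGA->GGA, Arg->Gly) is not
        # synonymous: the window-branch contributes nothing.
        out = "GCTCGA"
        in1 = "GCTGGA"
        in2 = "GCTCGA"
        records = ds.scan_nulls([make_triplet(out, in1, in2)])
        assert all(r.a1 == r.a2 == r.b == 0 for r in records.values())

    def test_all_counted_keys_are_realizable(self):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=6, n_genes=20, codons_per_gene=150))
        records = ds.scan_nulls([a for a in sim.alignments() if a.kind == "coding"])
        for key, rec in records.items():
            if rec.total == 0:
                continue
            assert (
                key.config,
                key.change1[0],
                key.change1[1],
                key.change2[0],
                key.change2[1],
                key.constant,
            ) in nm.REALIZABLE_KEYS

    def test_nm1_and_nm2_share_no_keys(self):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=6, n_genes=10, codons_per_gene=150))
        records = ds.scan_nulls([a for a in sim.alignments() if a.kind == "coding"])
        nm1_keys = {k for k in records if k.config in (nm.NM1_23, nm.NM1_12)}
        nm2_keys = {k for k in records if k.config == nm.NM2}
        assert not (nm1_keys & nm2_keys)


class TestMatchKey:
    def test_methods_worked_example(self):
        # GCC->GTA: adjacent changes at positions 2 and 3, constant G
        matched = ds.match_key(ds.classify("GCC", "GTA"))
        key = matched.key
        assert key.config == nm.NM1_23
        assert key.constant == "G"
        assert key.change1 == ("C", "T") and key.change2 == ("C", "A")
        assert matched.realizable

    def test_positions_12_map_to_nm1_12(self):
        matched = ds.match_key(ds.classify("AAA", "GGA"))
        key = matched.key
        assert key.config == nm.NM1_12
        assert key.change1 == ("A", "G") and key.change2 == ("A", "G")
        assert key.constant == "A"
        # A>G is never synonymous at a twofold first position: absent key
        assert not matched.realizable

    def test_nonadjacent_maps_to_nm2(self):
        matched = ds.match_key(ds.classify("TTG", "CTC"))
        assert matched.key.config == nm.NM2
        assert matched.key.constant == "T"
        assert matched.realizable

    def test_serine_like_changes_unrealizable(self):
        combo = ds.classify("TCT", "AGT")  # SER class
        assert not ds.match_key(combo).realizable

    def test_all_ns_combinations_have_realizable_nm2_keys(self, catalogue):
        for combo in catalogue:
            if combo.label == gc.NS:
                matched = ds.match_key(combo)
                assert matched.key.config == nm.NM2 and matched.realizable


class TestScanNoncoding:
    def test_three_frames(self):
        seq = "A" * 30
        frames = ds.scan_noncoding([make_triplet(seq, seq, seq, kind="intergenic")])
        assert [f.frame for f in frames] == [0, 1, 2]

    def test_identical_sequences_have_no_events(self):
        seq = "ACGTACGTACGT"
        frames = ds.scan_noncoding([make_triplet(seq, seq, seq, kind="intergenic")])
        for f in frames:
            assert f.result.singles.sum() == 0 and f.result.doubles.sum() == 0

    def test_adjacent_double_in_exactly_one_frame(self):
        # 9-base alignment; ingroup 1 differs at positions 0,1: an interior
        # adjacent pair would sit inside a codon of two frames, but at the
        # 5' edge only frame 0 retains it as a within-codon double.
        out = "AAACCCGGG"
        in1 = "GGACCCGGG"
        in2 = "AAACCCGGG"
        frames = ds.scan_noncoding([make_triplet(out, in1, in2, kind="intergenic")])
        doubles_per_frame = [int(f.result.doubles.sum()) for f in frames]
        assert doubles_per_frame.count(1) == 1
        hit = frames[doubles_per_frame.index(1)]
        rows = [r for r in hit.double_records() if r["b"] > 0]
        assert len(rows) == 1 and rows[0]["adjacent"]

    def test_stop_pseudocodons_are_counted(self):
        # no synonymy/stop constraints in non-coding scans
        out = "TAATAA"
        frames = ds.scan_noncoding([make_triplet(out, out, out, kind="intergenic")])
        assert frames[0].result.anc_counts.sum() == 4
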