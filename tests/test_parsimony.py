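import numpy as np
import pytest

import doublesub as ds
from doublesub import parsimony as pars
from doublesub.parsimony import NO_EVENT, SKIPPED, UNINFORMATIVE, TripletAlignmentError

from conftest import brute_force_tally, make_triplet, tally_as_dicts


class TestReadTripletFasta:
    def _write(self, tmp_path, records):
        path = tmp_path / "gene.fasta"
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path

    def test_valid_three_record_alignment(self, tmp_path):
        seq = "ATG" * 100
        path = self._write(tmp_path, [("out", seq), ("a", seq), ("b", seq)])
        aln = ds.read_triplet_fasta(path, outgroup_id="out")
        assert aln.length == 300 and aln.length // 3 == 100
        assert aln.outgroup_index == 0

    def test_two_records_rejected(self, tmp_path):
        path = self._write(tmp_path, [("out", "ATG"), ("a", "ATG")])
        with pytest.raises(TripletAlignmentError):
            ds.read_triplet_fasta(path, outgroup_id="out")

    def test_unequal_lengths_rejected(self, tmp_path):
        path = self._write(tmp_path, [("out", "ATGATG"), ("a", "ATG"), ("b", "ATGATG")])
        with pytest.raises(TripletAlignmentError):
            ds.read_triplet_fasta(path, outgroup_id="out")

    def test_missing_outgroup_rejected(self, tmp_path):
        path = self._write(tmp_path, [("x", "ATG"), ("a", "ATG"), ("b", "ATG")])
        with pytest.raises(TripletAlignmentError):
            ds.read_triplet_fasta(path, outgroup_id="out")


class TestInferCodonEvent:
    def test_single_substitution_on_ingroup_two(self):
        ev = ds.infer_codon_event("AAA", "AAA", "AGA")
        assert (ev.ancestral, ev.derived, ev.branch, ev.n_diff) == ("AAA", "AGA", 2, 1)

    def test_outgroup_matches_neither(self):
        assert ds.infer_codon_event("AAA", "AGA", "GGA") == UNINFORMATIVE

    def test_shared_derived_state_is_outgroup_lineage_change(self):
        assert ds.infer_codon_event("AAA", "GGA", "GGA") == UNINFORMATIVE

    def test_no_event(self):
        assert ds.infer_codon_event("AAA", "AAA", "AAA") == NO_EVENT

    def test_double_event(self):
        ev = ds.infer_codon_event("AAA", "AAA", "GGA")
        assert (ev.derived, ev.n_diff, ev.branch) == ("GGA", 2, 2)

    @pytest.mark.parametrize("codons", [("A-A", "AAA", "AAA"), ("AAA", "ANA", "AAA")])
    def test_gap_or_ambiguity_skipped(self, codons):
        assert ds.infer_codon_event(*codons) == SKIPPED


class TestTally:
    def test_single_double_and_intermediate_counts(self, catalogue):
        # one AAA->GGA double (ingroup 1), one AAA->GAA single (ingroup 2)
        out = "AAA" + "AAA" + "CCC"
        in1 = "GGA" + "AAA" + "CCC"
        in2 = "AAA" + "GAA" + "CCC"
        result = ds.tally([make_triplet(out, in1, in2)])
        combo = ds.classify("AAA", "GGA")
        rec = result.counts_record(combo)
        assert (rec.b, rec.a1, rec.a2) == (1, 1, 0)
        assert rec.anc_count == 4  # two resolved AAA columns x 2 lineages

    def test_zero_event_alignment(self):
        seq = "ATGGCT" * 10
        result = ds.tally([make_triplet(seq, seq, seq)])
        assert result.singles.sum() == result.doubles.sum() == 0
        assert result.anc_counts.sum() == 2 * 20

    def test_stop_ancestor_columns_skipped(self):
        out = "TAAAAA"
        result = ds.tally([make_triplet(out, out, out)])
        assert result.anc_counts.sum() == 2  # only the AAA column

    def test_empty_input(self):
        result = ds.tally([])
        assert result.anc_counts.sum() == 0 and not result.gene_counts

    def test_counts_conservation(self):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=8, n_genes=10, codons_per_gene=100))
        result = ds.tally([a for a in sim.alignments() if a.kind == "coding"])
        comp = result.composition()
        assert comp["single"] + comp["double"] + comp["triple"] <= comp["resolved"]
        assert comp["columns"] == comp["resolved"] + comp["skipped"] + comp["uninformative"]

    def test_ingroup_swap_invariance(self):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=9, n_genes=5, codons_per_gene=120))
        alns = [a for a in sim.alignments() if a.kind == "coding"]
        swapped = [
            pars.TripletAlignment(
                gene_id=a.gene_id,
                ids=(a.ids[0], a.ids[2], a.ids[1]),
                seqs=(a.seqs[0], a.seqs[2], a.seqs[1]),
                outgroup_id=a.outgroup_id,
                kind=a.kind,
            )
            for a in alns
        ]
        r1, r2 = ds.tally(alns), ds.tally(swapped)
        assert np.array_equal(r1.singles, r2.singles)
        assert np.array_equal(r1.doubles, r2.doubles)
        assert np.array_equal(r1.anc_counts, r2.anc_counts)

    def test_matches_brute_force_recount(self):
        sim = ds.simulate_triplet(
            ds.SimulationConfig(seed=10, n_genes=15, codons_per_gene=60, delta=0.1)
        )
        alns = [a for a in sim.alignments() if a.kind == "coding"]
        result = ds.tally(alns)
        assert tally_as_dicts(result) == brute_force_tally(alns)


class TestGeneRates:
    def test_site_counts_positive(self):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=3, n_genes=4, codons_per_gene=100))
        result = ds.tally([a for a in sim.alignments() if a.kind == "coding"])
        assert len(result.gene_counts) == 4
        for g in result.gene_counts:
            assert g.n_sites > g.s_sites > 0

    def test_ledger_dataframe_shape(self, main_catalogue):
        sim = ds.simulate_triplet(ds.SimulationConfig(seed=3, n_genes=4, codons_per_gene=100))
        result = ds.tally([a for a in sim.alignments() if a.kind == "coding"])
        frame = pars.ledger_dataframe(result, main_catalogue)
        assert len(frame) == len(main_catalogue)
        assert (frame["ANC"] >= frame[["a1", "a2", "b"]].sum(axis=1)).all()
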