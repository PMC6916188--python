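import numpy as np
import pytest

import doublesub as ds
from doublesub import simulate as sim
from doublesub.genetic_code import STOP_CODONS


class TestConfig:
    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            ds.SimulationConfig(delta=1.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ds.SimulationConfig(w_fast=0.0)
        with pytest.raises(ValueError):
            ds.SimulationConfig(codon_weights=[1.0] * 61 )

    def test_neutral_constructor(self):
        cfg = ds.SimulationConfig.neutral(seed=1)
        assert cfg.w_fast == cfg.w_slow == 1.0 and not cfg.reversion_boost


class TestGenerateAncestor:
    def test_deterministic_under_seed(self):
        cfg = ds.SimulationConfig(seed=42, n_genes=5, codons_per_gene=50)
        a = sim.generate_ancestor(cfg)
        b = sim.generate_ancestor(cfg)
        assert all(np.array_equal(x.ancestor, y.ancestor) for x, y in zip(a, b))

    def test_genes_are_stop_free(self):
        cfg = ds.SimulationConfig(seed=7, n_genes=10, codons_per_gene=200)
        for region in sim.generate_ancestor(cfg):
            if region.kind != "coding":
                continue
            seq = "".join("ACGT"[b] for b in region.ancestor)
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_degenerate_usage_weights(self):
        weights = np.zeros(61)
        weights[[c == "AAA" for c in __import__("doublesub").genetic_code.SENSE_CODONS].index(True)] = 1.0
        cfg = ds.SimulationConfig(seed=1, n_genes=2, codons_per_gene=10,
                                  codon_weights=weights, intergenic_fraction=0.0)
        for region in sim.generate_ancestor(cfg):
            assert set(region.ancestor.tolist()) == {0}  # all A

    def test_zero_genes_gives_intergenic_only(self):
        cfg = ds.SimulationConfig(seed=1, n_genes=0, codons_per_gene=100,
                                  intergenic_fraction=1.0)
        regions = sim.generate_ancestor(cfg)
        assert regions and all(r.kind == "intergenic" for r in regions)


class TestEvolveAndReplay:
    def test_zero_rate_branches_identical(self):
        cfg = ds.SimulationConfig(seed=2, n_genes=3, codons_per_gene=40,
                                  outgroup_rate=0.0, ingroup_rates=(0.0, 0.0))
        res = ds.simulate_triplet(cfg)
        for aln in res.alignments():
            assert aln.seqs[0] == aln.seqs[1] == aln.seqs[2]

    def test_fixed_seed_reproducible(self):
        a = ds.simulate_triplet(ds.SimulationConfig(seed=3, n_genes=4, codons_per_gene=60))
        b = ds.simulate_triplet(ds.SimulationConfig(seed=3, n_genes=4, codons_per_gene=60))
        for x, y in zip(a.alignments(), b.alignments()):
            assert x.seqs == y.seqs
        assert a.truth.events == b.truth.events

    def test_replay_reproduces_tips(self):
        res = ds.simulate_triplet(
            ds.SimulationConfig(seed=4, n_genes=5, codons_per_gene=80, delta=0.1)
        )
        by_key = {}
        for e in res.truth.events:
            by_key.setdefault((e.branch, e.region_id), []).append(e)
        for region in res.regions:
            for branch in sim.BRANCHES:
                events = by_key.get((branch, region.region_id), [])
                replayed = sim.replay(region.ancestor, events)
                assert np.array_equal(replayed, res.tips[branch][region.region_id])

    def test_no_stop_codons_in_coding_tips(self):
        res = ds.simulate_triplet(ds.SimulationConfig(seed=5, n_genes=5, codons_per_gene=100))
        for aln in res.alignments("coding"):
            for seq in aln.seqs:
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not codons & STOP_CODONS

    def test_simultaneous_fraction_matches_delta(self):
        # intergenic-only: no selection or stop filtering distorts acceptance
        cfg = ds.SimulationConfig.neutral(
            seed=6, n_genes=0, codons_per_gene=20000, delta=0.1, intergenic_fraction=1.0
        )
        res = ds.simulate_triplet(cfg)
        frac = res.truth.simultaneous_fraction()
        n = len(res.truth.events)
        assert n > 5000
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n) + 0.005

    def test_neutral_dn_ds_near_one_without_kappa_bias(self):
        # kappa = 1 so Nei-Gojobori site counts match the mutation kernel
        cfg = ds.SimulationConfig.neutral(
            seed=7, n_genes=100, codons_per_gene=300, delta=0.0, kappa=1.0,
            intergenic_fraction=0.0,
        )
        res = ds.simulate_triplet(cfg)
        tal = ds.tally(res.alignments())
        dn = sum(g.n_events for g in tal.gene_counts) / sum(
            g.n_sites for g in tal.gene_counts
        )
        dsr = sum(g.s_events for g in tal.gene_counts) / sum(
            g.s_sites for g in tal.gene_counts
        )
        assert dn / dsr == pytest.approx(1.0, abs=0.08)

    def test_selection_suppresses_nonsynonymous_changes(self):
        neutral = ds.simulate_triplet(
            ds.SimulationConfig.neutral(seed=8, n_genes=30, codons_per_gene=200,
                                        intergenic_fraction=0.0)
        )
        selected = ds.simulate_triplet(
            ds.SimulationConfig(seed=8, n_genes=30, codons_per_gene=200,
                                w_fast=0.1, w_slow=0.1, reversion_boost=False,
                                intergenic_fraction=0.0)
        )
        assert len(selected.truth.events) < 0.8 * len(neutral.truth.events)


class TestOutputs:
    def test_write_and_reload_roundtrip(self, tmp_path):
        res = ds.simulate_triplet(
            ds.SimulationConfig(seed=9, n_genes=3, codons_per_gene=50)
        )
        outdir = tmp_path / "sim"
        res.write(outdir)
        alignments = ds.read_manifest(outdir / "manifest.tsv")
        originals = {a.gene_id: a for a in res.alignments()}
        assert len(alignments) == len(originals)
        for aln in alignments:
            assert aln.seqs == originals[aln.gene_id].seqs
            assert aln.kind == originals[aln.gene_id].kind

    def test_truth_census_only_counts_nm1_sites(self):
        res = ds.simulate_triplet(
            ds.SimulationConfig.neutral(seed=10, n_genes=200, codons_per_gene=500,
                                        delta=0.3, intergenic_fraction=0.0)
        )
        census = sim.truth_null_double_census(res)
        assert census  # at delta = 0.2 some events land in eligible windows
        for key in census:
            assert key.config in ("NM1_23", "NM1_12")
        visible = sim.truth_null_double_census(res, visible_only=True)
        total = sum(census.values())
        total_visible = sum(visible.values())
        assert 0 < total_visible <= total
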