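"""Synthetic genomes, planted motifs, and ground-truth recovery."""

import math

import pytest

from wtbox.background import composition_profile
from wtbox.genesets import motif_presence_set
from wtbox.io import extract_upstream, filter_nuclear
from wtbox.motifs import compile_pattern, count_occurrences, find_occurrences
from wtbox.simulate import (
    SimulationConfig,
    is_non_self_overlapping,
    plant_in_upstream_windows,
    plant_motifs,
    simulate_genome_with_annotation,
    simulate_sequences,
)


class TestSimulateSequences:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(seed=42, n_sequences=5, sequence_length=300)
        a = simulate_sequences(cfg)
        b = simulate_sequences(cfg)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_different_seed_differs(self):
        a = simulate_sequences(SimulationConfig(seed=1, sequence_length=300))
        b = simulate_sequences(SimulationConfig(seed=2, sequence_length=300))
        assert a.records[0].residues != b.records[0].residues

    def test_empirical_gc_matches_target_within_3_se(self):
        n = 1_000_000
        gc = 0.3262
        cfg = SimulationConfig(seed=7, n_sequences=1, sequence_length=n, gc_fraction=gc)
        prof = composition_profile(simulate_sequences(cfg))
        se = math.sqrt(gc * (1 - gc) / n)
        assert abs(prof.gc_fraction - gc) < 3 * se

    def test_uniform_gc_gives_balanced_bases(self):
        cfg = SimulationConfig(seed=9, sequence_length=200_000, gc_fraction=0.5)
        prof = composition_profile(simulate_sequences(cfg))
        for base, count in prof.counts.items():
            assert count / prof.total_counted == pytest.approx(0.25, abs=0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, gc_fraction=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_sequences=-1)


class TestPlantMotifs:
    def test_planted_copies_are_found(self):
        cfg = SimulationConfig(
            seed=5, n_sequences=4, sequence_length=500, copies_per_sequence=3
        )
        rng = cfg.rng()
        seqs = simulate_sequences(cfg, rng)
        planted, truth = plant_motifs(seqs, "ACCGGTTC", cfg, rng)
        pat = compile_pattern("m", "ACCGGTTC")
        table = count_occurrences(pat, planted, "forward")
        for rec in planted:
            assert table.per_sequence_counts[rec.id] >= 3
        truth_starts = {
            (o.sequence_id, o.start) for o in truth
        }
        found = {
            (o.sequence_id, o.start)
            for rec in planted
            for o in find_occurrences(pat, rec, "forward")
        }
        assert truth_starts <= found

    def test_zero_copies_leaves_sequences_unchanged(self):
        cfg = SimulationConfig(
            seed=5, n_sequences=2, sequence_length=100, copies_per_sequence=0
        )
        rng = cfg.rng()
        seqs = simulate_sequences(cfg, rng)
        planted, truth = plant_motifs(seqs, "ACGTACGT", cfg, rng)
        assert truth == []
        assert [r.residues for r in planted] == [r.residues for r in seqs]

    def test_infeasible_planting_raises(self):
        cfg = SimulationConfig(
            seed=5, n_sequences=1, sequence_length=20, copies_per_sequence=5
        )
        rng = cfg.rng()
        seqs = simulate_sequences(cfg, rng)
        with pytest.raises(ValueError, match="non-overlapping"):
            plant_motifs(seqs, "ACGTA", cfg, rng)

    def test_degenerate_motif_rejected(self):
        cfg = SimulationConfig(seed=1, copies_per_sequence=1)
        seqs = simulate_sequences(cfg)
        with pytest.raises(ValueError, match="concrete"):
            plant_motifs(seqs, "NGACTTTN", cfg)

    def test_rate_planting_adds_to_background(self):
        """Observed count ~ planted + background across many sequences."""
        cfg = SimulationConfig(
            seed=11, n_sequences=200, sequence_length=2000,
            gc_fraction=0.5, planting_rate=2.0,
        )
        rng = cfg.rng()
        seqs = simulate_sequences(cfg, rng)
        planted, truth = plant_motifs(seqs, "AACGTGGC", cfg, rng)
        total_nt = 200 * 2000
        expect = len(truth) + total_nt * 0.25**8
        observed = count_occurrences(
            compile_pattern("m", "AACGTGGC"), planted, "forward"
        ).total
        # planted copies dominate; allow Poisson-scale slack on the background
        assert observed == pytest.approx(expect, abs=4 * math.sqrt(expect))


def test_non_self_overlap_helper():
    assert is_non_self_overlapping("AAATTTTT")
    assert is_non_self_overlapping("ACCGGTTC")
    assert not is_non_self_overlapping("GACTTTGA")  # prefix GA == suffix GA
    assert not is_non_self_overlapping("AA")


class TestGenomeWithAnnotation:
    def test_upstream_windows_have_full_length(self):
        cfg = SimulationConfig(
            seed=3, n_genes=10, sequence_length=20_000, window_clearance=500
        )
        genome, genes = simulate_genome_with_annotation(cfg)
        windows = extract_upstream(genome, genes, 500)
        assert len(windows) == 10
        assert all(rec.length == 500 for rec in windows)

    def test_organellar_genes_filtered(self):
        cfg = SimulationConfig(
            seed=3, n_genes=6, sequence_length=20_000,
            n_organellar_contigs=1, genes_per_organellar_contig=2,
        )
        genome, genes = simulate_genome_with_annotation(cfg)
        assert len(genes) == 8
        kept = filter_nuclear(genes)
        assert len(kept) == 6
        assert all(g.compartment == "nuclear" for g in kept)

    def test_infeasible_placement_raises(self):
        cfg = SimulationConfig(
            seed=3, n_genes=50, sequence_length=1_000, window_clearance=500
        )
        with pytest.raises(ValueError, match="clearance"):
            simulate_genome_with_annotation(cfg)

    def test_minus_strand_planted_motif_found_in_window(self):
        """A motif written on the gene strand upstream of a minus-strand gene
        appears on the forward strand of the extracted window."""
        cfg = SimulationConfig(
            seed=13, n_genes=4, sequence_length=30_000, window_clearance=600
        )
        genome, genes = simulate_genome_with_annotation(cfg)
        motif = "CCGACTTTTG"
        genome2 = plant_in_upstream_windows(genome, genes, motif, offset=50)
        windows = extract_upstream(genome2, genes, 500)
        pat = compile_pattern("m", motif)
        for gene in genes:
            hits = find_occurrences(pat, windows[gene.gene_id], "forward")
            starts = [h.start for h in hits]
            # gene-proximal end of the motif sits `offset` nt 5' of the TSS,
            # i.e. window positions [window-offset-len+2 .. window-offset+1]
            assert 500 - 50 - len(motif) + 2 in starts

    def test_ground_truth_gene_set_recovered(self):
        """Genes given a WT-box but no W-box are exactly the reported set."""
        cfg = SimulationConfig(
            seed=17, n_genes=12, sequence_length=40_000, window_clearance=600,
            gc_fraction=0.3262,
        )
        genome, genes = simulate_genome_with_annotation(cfg)
        # give half the genes a WT-box that is not a W-box (A 5' of core),
        # and give two of the others a W-box-embedded WT-box
        wt_genes = genes[:6]
        wbox_genes = genes[6:8]
        genome = plant_in_upstream_windows(genome, wt_genes, "AGACTTTA", offset=40)
        genome = plant_in_upstream_windows(genome, wbox_genes, "TTGACTTTT", offset=40)
        windows = extract_upstream(genome, genes, 500)
        wt = compile_pattern("wt", "NGACTTTN")
        wbox = compile_pattern("wbox", "TTGACY")
        got = motif_presence_set([wt], [wbox], windows, "both")
        # exact ground truth by independent window enumeration: the
        # background may create incidental hits, so truth is recomputed per
        # window rather than assumed from the planting plan
        from conftest import brute_force_hits

        truth = {
            rec.id.upper()
            for rec in windows
            if brute_force_hits("NGACTTTN", rec.residues, "both")
            and not brute_force_hits("TTGACY", rec.residues, "both")
        }
        assert got.members == truth
        # the planting plan is respected: WT-box planted windows carry the
        # motif, W-box planted windows are always excluded
        assert all(
            brute_force_hits("NGACTTTN", windows[g.gene_id].residues, "both")
            for g in wt_genes
        )
        assert not {g.gene_id.upper() for g in wbox_genes} & got.members
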