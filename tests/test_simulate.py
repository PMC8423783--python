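"""Generator determinism, feasibility checks and truth self-consistency."""

import dataclasses
import hashlib

import pytest

from t2taudit.chromosome import classify_t2t, find_gaps, scan_telomere
from t2taudit.comparative import region_repeat_fraction, uncovered_regions
from t2taudit.duplication import filter_hits, rank_genes, tdg_clusters
from t2taudit.model import GenomeInterval
from t2taudit.simulate import (DegradeSim, GapSim, SimConfig, SimulationError,
                               TDGSim, degrade_assembly, simulate_assembly,
                               simulate_hits, simulate_marker_map,
                               write_simulation)


def _digest(assembly):
    h = hashlib.sha256()
    for rec in assembly:
        h.update(rec.name.encode())
        h.update(rec.residues.encode())
    return h.hexdigest()


def _truth_genes(truth):
    return [(g.gene_id, GenomeInterval(g.seq_name, g.start, g.end, g.strand,
                                       "gene")) for g in truth.genes]


class TestDeterminism:
    def test_same_seed_identical_output(self, default_sim):
        config, assembly, truth = default_sim
        assembly2, truth2 = simulate_assembly(SimConfig(seed=config.seed))
        assert _digest(assembly2) == _digest(assembly)
        assert truth2 == truth

    def test_different_seed_different_sequence(self, default_sim):
        _, assembly, _ = default_sim
        assembly2, _ = simulate_assembly(SimConfig(seed=2))
        assert _digest(assembly2) != _digest(assembly)

    def test_marker_map_reproducible(self, default_sim):
        _, assembly, _ = default_sim
        a = simulate_marker_map(assembly, seed=9)
        b = simulate_marker_map(assembly, seed=9)
        assert a.markers == b.markers and a.order == b.order


class TestTruthSelfConsistency:
    def test_intervals_inside_sequences(self, default_sim):
        _, assembly, truth = default_sim
        lengths = assembly.lengths
        for iv in truth.repeats + truth.centromeres:
            assert 0 <= iv.start < iv.end <= lengths[iv.seq_name]
        for g in truth.genes:
            assert 0 <= g.start < g.end <= lengths[g.seq_name]

    def test_gap_truth_matches_residues(self, default_sim):
        _, assembly, truth = default_sim
        for gap in truth.gaps:
            rec = assembly[gap.seq_name]
            assert set(rec.residues[gap.start:gap.end]) == {"N"}
            assert rec.residues[gap.start - 1] != "N"
            assert rec.residues[gap.end] != "N"

    def test_zero_gap_config_gives_all_gapless(self):
        config = SimConfig(seed=3, gaps=GapSim(count=0))
        assembly, _ = simulate_assembly(config)
        for rec in assembly:
            status = classify_t2t(rec.name, scan_telomere(rec), find_gaps(rec))
            assert status.status == "gapless_T2T"

    def test_infeasible_config_raises(self):
        config = SimConfig(chromosome_length_range=(400_000, 420_000))
        with pytest.raises(SimulationError):
            simulate_assembly(config)


class TestHits:
    def test_planted_cluster_sizes_recovered(self):
        config = SimConfig(seed=7, tdg=TDGSim(sizes=(2, 5, 38)))
        assembly, truth = simulate_assembly(config)
        hits = simulate_hits(truth, seed=8)
        pairs = filter_hits(hits, truth.protein_lengths)
        clusters = tdg_clusters(pairs, rank_genes(_truth_genes(truth)))
        assert sorted(c.n_genes for c in clusters) == [2, 5, 38]
        got = sorted(sorted(c.members) for c in clusters)
        assert got == sorted(sorted(v) for v in truth.clusters.values())

    def test_decoy_pairs_fail_filters(self, default_sim):
        _, _, truth = default_sim
        clean = simulate_hits(truth, seed=8)
        noisy = simulate_hits(truth, false_pair_rate=0.5, seed=8)
        assert len(noisy) > len(clean)
        assert filter_hits(noisy, truth.protein_lengths) == \
            filter_hits(clean, truth.protein_lengths)

    def test_uniform_weak_evalues_filter_to_nothing(self, default_sim):
        _, _, truth = default_sim
        hits = [dataclasses.replace(h, evalue=1.0)
                for h in simulate_hits(truth, seed=8)]
        assert filter_hits(hits, truth.protein_lengths) == []

    def test_hsp_split_mode_passes_by_pooling(self, default_sim):
        _, _, truth = default_sim
        whole = simulate_hits(truth, seed=8)
        split = simulate_hits(truth, seed=8, hsp_split=True)
        assert len(split) == 2 * len(whole)
        assert filter_hits(split, truth.protein_lengths) == \
            filter_hits(whole, truth.protein_lengths)


class TestDegrade:
    def test_no_collapse_no_new_regions(self, default_sim):
        config, assembly, truth = default_sim
        cfg = dataclasses.replace(config,
                                  degrade=DegradeSim(collapse_fraction=0.0))
        result = degrade_assembly(assembly, truth, cfg, seed=3)
        assert result.new_regions == []
        assert uncovered_regions(assembly.lengths, result.blocks) == []

    def test_deleted_blocks_recovered_bit_exactly(self, default_sim):
        config, assembly, truth = default_sim
        result = degrade_assembly(assembly, truth, config, seed=3)
        regions = uncovered_regions(assembly.lengths, result.blocks)
        got = sorted((r.interval.seq_name, r.interval.start, r.interval.end)
                     for r in regions)
        want = sorted((r.seq_name, r.start, r.end) for r in result.new_regions)
        assert got == want and len(got) >= config.n_chromosomes

    def test_collapsed_centromeres_are_repeat_rich(self, default_sim):
        config, assembly, truth = default_sim
        result = degrade_assembly(assembly, truth, config, seed=3)
        regions = region_repeat_fraction(
            uncovered_regions(assembly.lengths, result.blocks), truth.repeats)
        cen = {c.seq_name: c for c in truth.centromeres}
        in_cen = [r for r in regions
                  if r.interval.start >= cen[r.interval.seq_name].start
                  and r.interval.end <= cen[r.interval.seq_name].end]
        assert in_cen and all(r.repeat_fraction >= 0.85 for r in in_cen)

    def test_degraded_contigs_reassemble_chromosome_prefix(self, default_sim):
        config, assembly, truth = default_sim
        result = degrade_assembly(assembly, truth, config, seed=3)
        block = result.blocks[0]
        rec = result.degraded[block.target.seq_name]
        chrom = assembly[block.query.seq_name]
        assert rec.residues == chrom.residues[block.query.start:block.query.end]


class TestMarkerMap:
    def test_full_mislabeling_breaks_assignment(self, default_sim):
        from t2taudit.anchoring import assign_contigs
        _, assembly, _ = default_sim
        mm = simulate_marker_map(assembly, mislabel_rate=1.0, seed=6)
        placements = assign_contigs(mm.markers)
        truth = {c: chrom for chrom, lst in mm.order.items() for c, _ in lst}
        accuracy = sum(p.chromosome == truth[c]
                       for c, p in placements.items()) / len(placements)
        assert accuracy < 0.5

    def test_contig_assembly_matches_lengths(self, default_sim):
        _, assembly, _ = default_sim
        mm = simulate_marker_map(assembly, seed=6)
        contigs = mm.contig_assembly(assembly)
        assert contigs.lengths == mm.contig_lengths
        assert contigs.cumulative_size == assembly.cumulative_size


def test_fixture_writer_round_trips(tmp_path, default_sim):
    from t2taudit.model import read_fasta, read_genes, read_intervals
    _, assembly, truth = default_sim
    write_simulation(assembly, truth, tmp_path)
    back = read_fasta(tmp_path / "genome.fasta")
    assert _digest(back) == _digest(assembly)
    genes = read_genes(tmp_path / "genes.gff3")
    assert [(gid, iv.start, iv.end) for gid, iv in genes] == \
        [(g.gene_id, g.start, g.end) for g in truth.genes]
    repeats = read_intervals(tmp_path / "repeats.bed", "bed")
    assert sorted((iv.seq_name, iv.start, iv.end, iv.feature_class)
                  for iv in repeats) == \
        sorted((iv.seq_name, iv.start, iv.end, iv.feature_class)
               for iv in truth.repeats)
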