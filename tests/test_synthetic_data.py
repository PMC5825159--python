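"""Generator contracts: determinism, planted structure, read statistics, NB expression."""

import numpy as np
import pytest

from crossbind.intervals import GenomicInterval
from crossbind.motifs import MotifPattern, scan_sequence
from crossbind.synthetic_data import (
    ExpressionPlan,
    MotifPlan,
    SimulationConfig,
    derive_rng,
    peak_sequences,
    plant_peaks_and_motifs,
    replicate_peaks,
    simulate_expression,
    simulate_genome,
    simulate_reads,
    write_fasta,
    read_fasta,
)


def small_config(**kw):
    defaults = dict(
        genome_length=2_000_000,
        n_chromosomes=2,
        peaks_per_class={"specific": 3, "CNS-common": 2, "endoderm-common": 2, "all-common": 2},
        spurious_per_tissue=2,
        n_genes=100,
        expression_plan=ExpressionPlan(n_specific_extra=5),
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = small_config()
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(simulate_genome(cfg), f1)
        write_fasta(simulate_genome(cfg), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_fasta_round_trip(self, tmp_path):
        cfg = small_config(genome_length=50_000)
        genome = simulate_genome(cfg)
        f = tmp_path / "g.fa"
        write_fasta(genome, f)
        back = read_fasta(f)
        assert set(back) == set(genome)
        assert all(np.array_equal(back[c], genome[c]) for c in genome)

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0)

    def test_base_composition_near_uniform_on_megabase(self):
        cfg = small_config(genome_length=1_000_000, n_chromosomes=1)
        chrom = simulate_genome(cfg)["chr1"]
        for base in b"ACGT":
            freq = float(np.mean(chrom == base))
            assert abs(freq - 0.25) < 0.01  # ~7 sigma at n=1e6

    def test_different_seeds_differ(self):
        g1 = simulate_genome(small_config(seed=1, genome_length=10_000, n_chromosomes=1))
        g2 = simulate_genome(small_config(seed=2, genome_length=10_000, n_chromosomes=1))
        assert not np.array_equal(g1["chr1"], g2["chr1"])


class TestPlanting:
    def test_fixed_spacing_recorded_in_truth(self):
        cfg = small_config(
            peaks_per_class={"specific": 0, "CNS-common": 0, "endoderm-common": 0,
                             "all-common": 10},
            spurious_per_tissue=0,
            motif_plans=(MotifPlan("SOX2", "ACAAW", ("fixed", 0), "ZEB1", "CWCACCTG",
                                   ("fixed", 12)),),
        )
        genome = simulate_genome(cfg)
        _, truth = plant_peaks_and_motifs(genome, cfg)
        spacings = [s for (_, _, _, s) in truth.planted_spacings]
        assert len(spacings) == 10
        assert all(s == 12 for s in spacings)

    def test_all_common_peaks_identical_across_tissues(self):
        cfg = small_config(
            peaks_per_class={"specific": 0, "CNS-common": 0, "endoderm-common": 0,
                             "all-common": 5},
            spurious_per_tissue=0,
        )
        genome = simulate_genome(cfg)
        peaksets, _ = plant_peaks_and_motifs(genome, cfg)
        reference = peaksets["cortex"].intervals
        assert len(reference) == 5
        for tissue in ("spinal_cord", "stomach", "lung"):
            assert peaksets[tissue].intervals == reference

    def test_rescanning_recovers_at_least_planted_occurrences(self):
        cfg = small_config()
        genome = simulate_genome(cfg)
        peaksets, truth = plant_peaks_and_motifs(genome, cfg)
        pattern = MotifPattern("SOX2", "ACAAW")
        planted_per_peak = {}
        for name, _, _ in truth.planted_offsets:
            planted_per_peak[name] = planted_per_peak.get(name, 0) + 1
        for name, n_planted in planted_per_peak.items():
            iv = truth.peak_intervals[name]
            seq = genome[iv.chrom][iv.start:iv.end].tobytes().decode()
            hits = scan_sequence(seq, pattern)
            assert len(hits) >= n_planted

    def test_planted_offset_matches_scanned_hit(self):
        cfg = small_config(motif_plans=(MotifPlan("SOX2", "ACAAW", ("fixed", 0)),))
        genome = simulate_genome(cfg)
        _, truth = plant_peaks_and_motifs(genome, cfg)
        pattern = MotifPattern("SOX2", "ACAAW")
        for name, _, offset in truth.planted_offsets:
            iv = truth.peak_intervals[name]
            seq = genome[iv.chrom][iv.start:iv.end].tobytes().decode()
            assert offset in {h.offset for h in scan_sequence(seq, pattern)}

    def test_motif_longer_than_peak_rejected(self):
        with pytest.raises(ValueError, match="longer than peak"):
            small_config(peak_width=6, motif_plans=(MotifPlan("Z", "CWCACCTG"),))

    def test_every_true_peak_has_exactly_one_class_label(self):
        cfg = small_config()
        genome = simulate_genome(cfg)
        peaksets, truth = plant_peaks_and_motifs(genome, cfg)
        n_expected = 3 * 4 + 2 + 2 + 2
        assert len(truth.peak_class_labels) == n_expected
        spurious_names = {n for lst in truth.spurious.values() for n, _ in lst}
        assert not spurious_names & set(truth.peak_class_labels)

    def test_peak_gene_links_within_association_window(self):
        cfg = small_config()
        genome = simulate_genome(cfg)
        _, truth = plant_peaks_and_motifs(genome, cfg)
        tss = truth.gene_annotation.set_index("gene")["tss"]
        for peak, gene in truth.peak_gene_links.items():
            iv = truth.peak_intervals[peak]
            assert abs(int(tss[gene]) - iv.center) <= cfg.association_window


class TestReads:
    def test_background_total_within_poisson_envelope(self):
        from crossbind.intervals import PeakSet

        cfg = small_config(genome_length=1_000_000, n_chromosomes=1, background_rate=0.01)
        reads = simulate_reads(PeakSet((), tissue="cortex"), {"chr1": 1_000_000}, cfg, 0)
        # Poisson mean 10,000, sigma 100
        assert abs(reads.library_size - 10_000) <= 300

    def test_zero_reads_per_peak_leaves_background_only(self):
        from crossbind.intervals import PeakSet

        cfg = small_config(reads_per_peak=0.0, background_rate=0.001)
        genome_sizes = cfg.genome_sizes
        peaksets, truth = plant_peaks_and_motifs(simulate_genome(cfg), cfg)
        with_peaks = simulate_reads(replicate_peaks(truth, "cortex", 0), genome_sizes, cfg, 0)
        background = simulate_reads(PeakSet((), tissue="cortex"), genome_sizes, cfg, 0)
        assert with_peaks.library_size == background.library_size

    def test_modal_pileup_position_at_peak_midpoint(self):
        cfg = small_config(
            genome_length=5_000_000,
            peaks_per_class={"specific": 25, "CNS-common": 0, "endoderm-common": 0,
                             "all-common": 0},
            spurious_per_tissue=0,
            reads_per_peak=500.0,
            expression_plan=ExpressionPlan(n_specific_extra=0),
        )
        peaksets, truth = plant_peaks_and_motifs(simulate_genome(cfg), cfg)
        reads = simulate_reads(peaksets["cortex"], cfg.genome_sizes, cfg, 0)
        for iv in peaksets["cortex"]:
            starts = reads.starts[iv.chrom]
            sub = starts[(starts > iv.start - 200) & (starts < iv.end + 200)]
            cover = np.zeros(iv.width + 400, dtype=int)
            for s in sub:
                a = max(0, s - (iv.start - 200))
                cover[a:a + 50] += 1
            modal = (iv.start - 200) + int(np.argmax(cover))
            assert abs(modal - iv.center) <= 30  # within the smoothing scale of sigma=33bp

    def test_replicate_streams_independent_and_stable(self):
        cfg = small_config()
        peaksets, truth = plant_peaks_and_motifs(simulate_genome(cfg), cfg)
        peaks = replicate_peaks(truth, "cortex", 0)
        r0a = simulate_reads(peaks, cfg.genome_sizes, cfg, 0)
        r0b = simulate_reads(peaks, cfg.genome_sizes, cfg, 0)
        r1 = simulate_reads(peaks, cfg.genome_sizes, cfg, 1)
        assert all(np.array_equal(r0a.starts[c], r0b.starts[c]) for c in r0a.starts)
        assert any(not np.array_equal(r0a.starts[c], r1.starts[c]) for c in r0a.starts)


class TestExpression:
    def test_seed_determinism(self):
        cfg = small_config()
        _, truth = plant_peaks_and_motifs(simulate_genome(cfg), cfg)
        em1 = simulate_expression(truth, cfg)
        em2 = simulate_expression(truth, cfg)
        assert em1.counts.equals(em2.counts)
        assert em1.gene_lengths.equals(em2.gene_lengths)

    def test_planted_fold_realized_within_factor_two(self):
        cfg = small_config(n_genes=300, expression_plan=ExpressionPlan(n_specific_extra=30))
        _, truth = plant_peaks_and_motifs(simulate_genome(cfg), cfg)
        em = simulate_expression(truth, cfg)
        rpkms = em.rpkm_matrix()
        in_band = 0
        total = 0
        for organ, genes in truth.specific_genes.items():
            own = em.samples_of(organ)
            others = [s for s in em.counts.columns if s not in own]
            for g in genes:
                fold = (rpkms.loc[g, own].mean() + 0.1) / (rpkms.loc[g, others].mean() + 0.1)
                total += 1
                in_band += 4 <= fold <= 16
        assert in_band / total >= 0.95

    def test_single_replicate_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(expression_plan=ExpressionPlan(n_replicates=1))


class TestRngDerivation:
    def test_streams_deterministic_and_distinct(self):
        a = derive_rng(5, "reads", "cortex", 0).integers(0, 1 << 30, 10)
        b = derive_rng(5, "reads", "cortex", 0).integers(0, 1 << 30, 10)
        c = derive_rng(5, "reads", "cortex", 1).integers(0, 1 << 30, 10)
        d = derive_rng(6, "reads", "cortex", 0).integers(0, 1 << 30, 10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert not np.array_equal(a, d)
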