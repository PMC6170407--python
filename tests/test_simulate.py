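import dataclasses

import numpy as np
import pytest
from scipy import stats

import bidirscan as b
from bidirscan.simulate import SimulationError, reverse_complement

TINY = dict(n_chroms=1, chrom_length=200_000, n_genes=8, n_reads=20_000)


class TestGenome:
    def test_zero_genes_gives_empty_annotation(self):
        cfg = b.SimulationConfig(seed=0, **{**TINY, "n_genes": 0})
        truth = b.simulate_genome(cfg)
        assert truth.genes == [] and truth.planted_motif_sites == []
        assert len(truth.genome["chr1"]) == cfg.chrom_length

    def test_degenerate_bidirectional_fraction(self):
        cfg = b.SimulationConfig(
            seed=0, n_chroms=1, chrom_length=2_000_000, n_genes=50,
            frac_bidirectional=1.0,
        )
        truth = b.simulate_genome(cfg)
        assert len(truth.genes) == 50
        assert all(truth.bidirectional_labels.values())

    def test_seed_determinism_byte_identical(self):
        cfg = b.SimulationConfig(seed=7, **TINY)
        t1, t2 = b.simulate_genome(cfg), b.simulate_genome(cfg)
        assert t1.genome == t2.genome
        assert t1.genes == t2.genes
        assert t1.planted_motif_sites == t2.planted_motif_sites
        assert t1.bidirectional_labels == t2.bidirectional_labels
        assert t1.hotspot_genes == t2.hotspot_genes

    def test_infeasible_packing_is_an_explicit_error(self):
        cfg = b.SimulationConfig(
            seed=0, n_chroms=1, chrom_length=50_000, n_genes=10
        )
        with pytest.raises(SimulationError, match="infeasible packing"):
            b.simulate_genome(cfg)

    def test_planted_motifs_read_as_the_motif_on_their_strand(self):
        cfg = b.SimulationConfig(seed=3, **TINY, frac_bidirectional=1.0)
        truth = b.simulate_genome(cfg)
        assert truth.planted_motif_sites
        for contig, start, strand in truth.planted_motif_sites:
            seq = truth.genome[contig][start : start + len(cfg.motif_dna)]
            if strand == "-":
                seq = reverse_complement(seq)
            assert seq == cfg.motif_dna

    def test_label_calibration_within_3_binomial_sd(self):
        cfg = b.SimulationConfig(seed=11, frac_bidirectional=0.3)
        truth = b.simulate_genome(cfg)
        frac = np.mean(list(truth.bidirectional_labels.values()))
        sd = np.sqrt(0.3 * 0.7 / cfg.n_genes)
        assert abs(frac - 0.3) < 3 * sd

    def test_genes_do_not_overlap(self):
        cfg = b.SimulationConfig(seed=5, **TINY)
        truth = b.simulate_genome(cfg)
        spans = sorted(
            (g.contig, *g.span) for g in truth.genes
        )
        for (c1, lo1, hi1), (c2, lo2, hi2) in zip(spans, spans[1:]):
            assert c1 != c2 or hi1 <= lo2


class TestClipReads:
    def test_null_enrichment_motif_density_matches_background(self):
        cfg = b.SimulationConfig(seed=2, crosslink_enrichment=1.0)
        truth = b.simulate_genome(cfg)
        reads = b.simulate_clip_reads(truth, cfg)
        assert len(truth.planted_motif_sites) >= 100
        site_bp = 0
        regions = {}
        for contig, start, strand in truth.planted_motif_sites:
            lo = max(0, start - cfg.read_length)
            hi = start + len(cfg.motif_dna) + cfg.read_length
            regions.setdefault((contig, strand), []).append((lo, hi))
            site_bp += hi - lo
        in_sites = 0
        for r in reads:
            for lo, hi in regions.get((r.contig, r.strand), ()):
                if lo <= r.five_prime < hi:
                    in_sites += 1
                    break
        total_bp = sum(truth.contig_lengths.values()) * 2
        expected = len(reads) * site_bp / total_bp
        # ratio of observed to expected within 2 sigma of 1 under Poisson
        assert abs(in_sites - expected) < 2 * np.sqrt(expected)

    def test_zero_background_concentrates_all_reads_on_the_site(self):
        cfg = b.SimulationConfig(
            seed=4, n_chroms=1, chrom_length=100_000, n_genes=1,
            frac_bidirectional=1.0, motifs_per_target=1,
            background_rate=0.0, n_reads=2000,
        )
        truth = b.simulate_genome(cfg)
        reads = b.simulate_clip_reads(truth, cfg)
        (contig, start, strand) = truth.planted_motif_sites[0]
        lo = start - cfg.read_length
        hi = start + len(cfg.motif_dna) + cfg.read_length
        assert reads
        for r in reads:
            assert r.strand == strand and r.start < hi and r.end > lo

    def test_enrichment_ratio_recovered_within_25_percent(self):
        cfg = b.SimulationConfig(
            seed=9, crosslink_enrichment=20.0, background_rate=0.001,
            n_reads=200_000,
        )
        truth = b.simulate_genome(cfg)
        reads = b.simulate_clip_reads(truth, cfg)
        site_bp = 0
        regions = {}
        for contig, start, strand in truth.planted_motif_sites:
            lo = max(0, start - cfg.read_length)
            hi = start + len(cfg.motif_dna) + cfg.read_length
            regions.setdefault((contig, strand), []).append((lo, hi))
            site_bp += hi - lo
        in_sites = sum(
            1
            for r in reads
            if any(
                lo <= r.five_prime < hi
                for lo, hi in regions.get((r.contig, r.strand), ())
            )
        )
        total_bp = sum(truth.contig_lengths.values()) * 2
        # Poisson-thinning oracle: expected per-bp intensity ratio E vs 1
        density_in = in_sites / site_bp
        density_out = (len(reads) - in_sites) / (total_bp - site_bp)
        assert density_out > 0
        ratio = density_in / density_out
        assert abs(ratio - cfg.crosslink_enrichment) / cfg.crosslink_enrichment < 0.25

    def test_conservation_matches_realized_draw(self):
        cfg = b.SimulationConfig(seed=6, **TINY)
        truth = b.simulate_genome(cfg)
        reads = b.simulate_clip_reads(truth, cfg)
        assert len(reads) == truth.realized_reads["clip"]

    def test_mismatched_config_rejected(self):
        cfg = b.SimulationConfig(seed=6, **TINY)
        truth = b.simulate_genome(cfg)
        other = dataclasses.replace(cfg, seed=99)
        with pytest.raises(SimulationError, match="different config"):
            b.simulate_clip_reads(truth, other)


class TestGroseqReads:
    def test_unidirectional_gene_has_no_upstream_antisense_unit_reads(self):
        cfg = b.SimulationConfig(
            seed=8, **{**TINY, "n_reads": 50_000}, frac_bidirectional=0.0,
            background_rate=0.0,
        )
        truth = b.simulate_genome(cfg)
        reads = b.simulate_groseq_reads(truth, cfg)
        assert reads and all(r.read_id.startswith("groseq-sense") for r in reads)

    def test_antisense_5prime_ends_confined_to_upstream_window(self):
        cfg = b.SimulationConfig(
            seed=8, **{**TINY, "n_reads": 50_000}, frac_bidirectional=1.0,
            background_rate=0.0,
        )
        truth = b.simulate_genome(cfg)
        reads = b.simulate_groseq_reads(truth, cfg)
        genes = {g.gene_id: g for g in truth.genes}
        anti = [r for r in reads if r.read_id.startswith("groseq-anti")]
        assert anti
        for r in anti:
            ok = False
            for g in genes.values():
                if g.contig != r.contig or g.strand == r.strand:
                    continue
                if g.strand == "+" and g.tss - cfg.antisense_span <= r.five_prime < g.tss:
                    ok = True
                if g.strand == "-" and g.tss < r.five_prime <= g.tss + cfg.antisense_span:
                    ok = True
            assert ok, f"antisense read outside every upstream window: {r}"

    def test_gene_body_counts_proportional_to_expression_weight(self):
        cfg = b.SimulationConfig(
            seed=12, n_chroms=1, chrom_length=200_000, n_genes=0,
            n_reads=100_000, background_rate=0.0, frac_bidirectional=0.0,
        )
        truth = b.simulate_genome(cfg)
        truth.genes = [
            b.GeneAnnotation("gA", "chr1", "+", 10_000, 12_000, 1.0),
            b.GeneAnnotation("gB", "chr1", "+", 50_000, 52_000, 2.0),
            b.GeneAnnotation("gC", "chr1", "+", 90_000, 92_000, 4.0),
        ]
        truth.bidirectional_labels = {"gA": False, "gB": False, "gC": False}
        reads = b.simulate_groseq_reads(truth, cfg)
        counts = {g.gene_id: 0 for g in truth.genes}
        for r in reads:
            for g in truth.genes:
                lo, hi = g.span
                if lo <= r.five_prime < hi:
                    counts[g.gene_id] += 1
        # multinomial expectation oracle: expected shares 1/7, 2/7, 4/7
        n = len(reads)
        for gid, w in (("gA", 1), ("gB", 2), ("gC", 4)):
            assert abs(counts[gid] - n * w / 7) / (n * w / 7) < 0.10

    def test_seed_determinism(self):
        cfg = b.SimulationConfig(seed=13, **TINY)
        truth = b.simulate_genome(cfg)
        r1 = b.simulate_groseq_reads(truth, cfg)
        truth2 = b.simulate_genome(cfg)
        r2 = b.simulate_groseq_reads(truth2, cfg)
        assert r1 == r2


class TestClones:
    def test_zero_rate_clones_identical_to_reference(self):
        cfg = b.SimulationConfig(seed=0, clone_mutation_rate=0.0)
        assert b.simulate_clones("ACGTCC", 5, cfg) == ["ACGTCC"] * 5

    def test_full_rate_full_bias_deaminates_every_cg(self):
        cfg = b.SimulationConfig(seed=0, clone_mutation_rate=1.0, transition_bias=1.0)
        (clone,) = b.simulate_clones("ACGTCCGG", 1, cfg)
        assert clone == "ATATTTAA"

    def test_empty_reference_rejected(self):
        cfg = b.SimulationConfig(seed=0)
        with pytest.raises(SimulationError):
            b.simulate_clones("", 3, cfg)

    def test_mutation_fraction_within_binomial_ci(self):
        rng = np.random.default_rng(21)
        ref = "".join(rng.choice(["C", "G", "A", "T"], size=200, p=[0.25, 0.25, 0.25, 0.25]))
        n_cg = sum(ref.count(x) for x in "CG")
        cfg = b.SimulationConfig(seed=21, clone_mutation_rate=0.3)
        clones = b.simulate_clones(ref, 200, cfg)
        n_mut = sum(
            1
            for clone in clones
            for rb, cb in zip(ref, clone)
            if rb in "CG" and rb != cb
        )
        trials = 200 * n_cg
        lo, hi = stats.binom.interval(0.95, trials, 0.3)
        assert lo <= n_mut <= hi
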