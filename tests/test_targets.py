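import itertools
import math

import numpy as np
import pytest

import bidirscan as b
from bidirscan.peaks import PeakCall
from bidirscan.targets import TargetError, _proximity_excluded


def read(start, end, strand, contig="c", unique=True):
    return b.ReadInterval(contig, start, end, strand, "r", unique)


def peak(start, contig="c", strand="+", count=10):
    return PeakCall(contig, start, start + 20, strand, count, 1e-9)


LEN = {"c": 100_000}


class TestRankWindows:
    def test_single_loaded_window_ranks_first(self):
        reads = [read(100 + i, 140 + i, "+") for i in range(50)]
        scores = b.rank_windows(reads, LEN, window=500)
        assert len(scores) == 1
        assert scores[0].rank == 1 and scores[0].unique_read_count == 50

    def test_tie_broken_by_lower_start_coordinate(self):
        reads = (
            [read(10, 40, "+") for _ in range(10)]
            + [read(5_000, 5_030, "+") for _ in range(5)]
            + [read(2_000, 2_030, "+") for _ in range(5)]
        )
        scores = b.rank_windows(reads, LEN, window=500)
        assert [(s.rank, s.start, s.unique_read_count) for s in scores] == [
            (1, 0, 10),
            (2, 2_000, 5),
            (3, 5_000, 5),
        ]

    def test_counts_conserved_and_ranks_are_a_permutation(self):
        rng = np.random.default_rng(2)
        reads = [
            read(int(s), int(s) + 30, "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(0, 99_000, size=5_000))
        ]
        scores = b.rank_windows(reads, LEN, window=500)
        assert sum(s.unique_read_count for s in scores) == 5_000
        assert sorted(s.rank for s in scores) == list(range(1, len(scores) + 1))

    def test_non_unique_reads_excluded_by_default(self):
        reads = [read(10, 40, "+"), read(15, 45, "+", unique=False)]
        scores = b.rank_windows(reads, LEN, window=500)
        assert scores[0].unique_read_count == 1

    def test_planted_locus_attains_rank_one(self):
        cfg = b.SimulationConfig(
            seed=33, n_chroms=1, chrom_length=500_000, n_genes=5,
            frac_bidirectional=1.0, motifs_per_target=1,
            crosslink_enrichment=50.0, n_reads=50_000,
        )
        truth = b.simulate_genome(cfg)
        reads = b.simulate_clip_reads(truth, cfg)
        top = b.rank_windows(reads, truth.contig_lengths, window=500)[0]
        assert any(
            top.start <= start < top.end
            for _, start, _ in truth.planted_motif_sites
        )

    def test_nonpositive_window_rejected(self):
        with pytest.raises(TargetError):
            b.rank_windows([], LEN, window=0)


class TestClusterPeaksToGenes:
    def test_peak_inside_only_gene(self):
        genes = [b.GeneAnnotation("g1", "c", "+", 10_000, 15_000)]
        out = b.cluster_peaks_to_genes([peak(12_000)], genes)
        assert out[0].is_target and out[0].n_peaks == 1

    def test_intergenic_peak_assigned_to_nothing(self):
        genes = [b.GeneAnnotation("g1", "c", "+", 10_000, 15_000)]
        out = b.cluster_peaks_to_genes([peak(50_000)], genes)
        assert not out[0].is_target and out[0].n_peaks == 0

    def test_promoter_flank_capture(self):
        genes = [b.GeneAnnotation("g1", "c", "+", 10_000, 15_000)]
        out = b.cluster_peaks_to_genes([peak(8_500)], genes, promoter_flank=2000)
        assert out[0].n_peaks == 1
        out = b.cluster_peaks_to_genes([peak(7_500)], genes, promoter_flank=2000)
        assert out[0].n_peaks == 0

    def test_divergent_promoter_tie_goes_to_lexicographically_smaller(self):
        # two genes sharing a divergent promoter, peak equidistant to both TSS
        ga = b.GeneAnnotation("gA", "c", "-", 9_000, 5_000)
        gb = b.GeneAnnotation("gB", "c", "+", 11_020, 15_000)
        out = {t.gene_id: t for t in b.cluster_peaks_to_genes([peak(10_000)], [ga, gb])}
        assert out["gA"].n_peaks == 1 and out["gB"].n_peaks == 0

    def test_density_uses_extended_span(self):
        genes = [b.GeneAnnotation("g1", "c", "+", 10_000, 12_000)]
        (t,) = b.cluster_peaks_to_genes([peak(10_500, count=40)], genes)
        assert t.clip_density == pytest.approx(40 / 4.0)  # 4 kb extended span


class TestGroupByDensity:
    def _targets(self, densities):
        return [
            b.TargetGene(f"g{i}", 1, d, is_target=True)
            for i, d in enumerate(densities)
        ]

    def test_nine_distinct_densities_split_evenly(self):
        out = b.group_by_density(self._targets(range(1, 10)))
        groups = [t.group for t in out]
        assert groups.count("low") == groups.count("medium") == groups.count("high") == 3
        by_density = {t.clip_density: t.group for t in out}
        assert by_density[1] == "low" and by_density[5] == "medium" and by_density[9] == "high"

    def test_all_equal_densities_all_low(self):
        out = b.group_by_density(self._targets([2.0] * 7))
        assert all(t.group == "low" for t in out)

    def test_mean_density_ordering_on_simulation(self, demo_result):
        grouped = {g: [] for g in ("low", "medium", "high")}
        for t in demo_result.targets:
            grouped[t.group].append(t.clip_density)
        means = {g: np.mean(v) for g, v in grouped.items()}
        assert means["low"] < means["medium"] < means["high"]

    def test_fewer_than_three_rejected(self):
        with pytest.raises(TargetError):
            b.group_by_density(self._targets([1.0, 2.0]))


class TestClassifyBidirectional:
    def _gene(self, gid="g1", strand="+", tss=50_000):
        if strand == "+":
            return b.GeneAnnotation(gid, "c", "+", tss, tss + 3_000)
        return b.GeneAnnotation(gid, "c", "-", tss, tss - 3_000)

    def _reads(self, gene, n_sense, n_anti):
        out = []
        sgn = 1 if gene.strand == "+" else -1
        anti = "-" if gene.strand == "+" else "+"
        for i in range(n_sense):
            p = gene.tss + sgn * (10 + i)
            out.append(read(p, p + 1, gene.strand))
        for i in range(n_anti):
            p = gene.tss - sgn * (10 + i)
            out.append(read(p, p + 1, anti))
        return out

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_covered_both_sides_is_bidirectional(self, strand):
        g = self._gene(strand=strand)
        (call,) = b.classify_bidirectional([g], self._reads(g, 50, 40))
        assert call.label == "bidirectional"
        assert call.sense_coverage == 50 and call.antisense_coverage == 40

    def test_no_antisense_is_other(self):
        g = self._gene()
        (call,) = b.classify_bidirectional([g], self._reads(g, 50, 0))
        assert call.label == "other"

    def test_tss_pair_within_2kb_both_excluded(self):
        g1 = b.GeneAnnotation("g1", "c", "+", 50_000, 53_000)
        g2 = b.GeneAnnotation("g2", "c", "+", 51_000, 54_000)
        calls = b.classify_bidirectional([g1, g2], self._reads(g1, 50, 50))
        assert all(c.excluded and c.exclusion_reason == "proximity" for c in calls)
        assert all(c.label is None for c in calls)

    def test_span_proximity_also_excludes(self):
        g1 = b.GeneAnnotation("g1", "c", "+", 50_000, 53_000)
        g2 = b.GeneAnnotation("g2", "c", "+", 54_000, 58_000)  # TSS 1 kb past g1 end
        excluded = _proximity_excluded([g1, g2], 2000)
        assert "g2" in excluded

    def test_far_apart_genes_not_excluded(self):
        g1 = b.GeneAnnotation("g1", "c", "+", 10_000, 13_000)
        g2 = b.GeneAnnotation("g2", "c", "+", 40_000, 43_000)
        assert _proximity_excluded([g1, g2], 2000) == set()

    def test_planted_labels_recovered_on_simulation(self, demo_result):
        truth = demo_result.truth
        correct = total = 0
        for call in demo_result.bidirectional:
            if call.excluded:
                continue
            total += 1
            predicted = call.label == "bidirectional"
            correct += predicted == truth.bidirectional_labels[call.gene_id]
        assert total > 0
        assert correct / total >= 0.95


class TestOverlapEnrichment:
    @staticmethod
    def brute_force_p(n, na, nb, k_obs):
        """Two-sided Fisher p by full hypergeometric enumeration."""
        p_obs = math.comb(na, k_obs) * math.comb(n - na, nb - k_obs)
        total = 0
        matched = 0
        for k in range(max(0, na + nb - n), min(na, nb) + 1):
            w = math.comb(na, k) * math.comb(n - na, nb - k)
            total += w
            if w <= p_obs:
                matched += w
        return matched / total

    def test_identical_sets_maximal_enrichment(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(10)}
        res = b.overlap_enrichment(a, a, universe)
        # both extreme tables (k=10 and k=0) have point probability
        # 1/C(20,10), so the two-sided sum is 2/C(20,10)
        assert res.p_value == pytest.approx(
            self.brute_force_p(20, 10, 10, 10), rel=1e-12
        )
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert math.isinf(res.odds_ratio)

    def test_disjoint_halves_maximal_depletion(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(10)}
        c = universe - a
        res = b.overlap_enrichment(a, c, universe)
        assert res.p_value == pytest.approx(
            self.brute_force_p(20, 10, 10, 0), rel=1e-12
        )
        assert res.odds_ratio == 0.0

    def test_matches_enumeration_for_all_small_universes(self):
        for n in range(2, 13):
            ids = [f"g{i}" for i in range(n)]
            universe = set(ids)
            for na, nb in itertools.product(range(1, n + 1), repeat=2):
                for k in range(max(0, na + nb - n), min(na, nb) + 1):
                    a = set(ids[:na])
                    bset = set(ids[na - k : na - k + nb])
                    assert len(a & bset) == k
                    res = b.overlap_enrichment(a, bset, universe)
                    expected = self.brute_force_p(n, na, nb, k)
                    assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_sampled_larger_universes(self):
        rng = np.random.default_rng(44)
        for _ in range(150):
            n = int(rng.integers(13, 51))
            na = int(rng.integers(1, n + 1))
            nb = int(rng.integers(1, n + 1))
            k = int(rng.integers(max(0, na + nb - n), min(na, nb) + 1))
            ids = [f"g{i}" for i in range(n)]
            a = set(ids[:na])
            bset = set(ids[na - k : na - k + nb])
            res = b.overlap_enrichment(a, bset, set(ids))
            assert res.p_value == pytest.approx(
                self.brute_force_p(n, na, nb, k), abs=1e-12
            )

    def test_empty_set_rejected(self):
        with pytest.raises(TargetError):
            b.overlap_enrichment(set(), {"g1"}, {"g1", "g2"})

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(TargetError):
            b.overlap_enrichment({"x"}, {"g1"}, {"g1", "g2"})


class TestCompareDistributions:
    def test_identical_samples_ks_zero_p_one(self):
        res = b.compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="ks")
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_exact_wilcoxon_separated_triples(self):
        res = b.compare_distributions([1, 2, 3], [4, 5, 6], test="wilcoxon")
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_ks_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        r1 = b.compare_distributions(x, y, test="ks")
        r2 = b.compare_distributions(np.exp(x), np.exp(y), test="ks")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_ttest_available(self):
        res = b.compare_distributions([1, 2, 3, 4], [2, 3, 4, 5], test="ttest")
        assert 0 < res.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(TargetError):
            b.compare_distributions([], [1.0], test="ks")
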