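"""Simulate a CLIP library and call crosslink peaks with the ZTNB model.

Builds a small synthetic genome in which bidirectional genes carry planted
CU-rich loading sites, simulates 100k crosslink reads at 20x enrichment,
and calls peaks on 20-bp bins. The recall figure says how many planted
sites were recovered; the peak p-values are conditional ZTNB tail
probabilities of each bin's count.
"""

import bidirscan as b

config = b.SimulationConfig(
    seed=11, n_chroms=1, chrom_length=1_000_000, n_genes=20,
    frac_bidirectional=1.0, motifs_per_target=1,
    crosslink_enrichment=20.0, n_reads=100_000,
)
truth = b.simulate_genome(config)
reads = b.simulate_clip_reads(truth, config)
track = b.build_track(reads, truth.contig_lengths, bin_size=20)
peaks = b.call_peaks(track, bin_size=20, p_threshold=2e-3)

recalled = sum(
    any(p.contig == c and p.strand == s and p.start < hi and p.end > lo
        for p in peaks)
    for c, lo, hi, s in truth.planted_peaks
)
print(f"{len(reads)} reads -> {len(peaks)} significant 20-bp bins")
print(f"planted loading sites recovered: {recalled}/{len(truth.planted_peaks)}")
for p in sorted(peaks, key=lambda p: p.p_value)[:3]:
    print(f"  top peak {p.contig}:{p.start}-{p.end} ({p.strand}) "
          f"count={p.count} p={p.p_value:.2e}")
print("A recall near 20/20 means the ZTNB background model separates the "
      "planted pile-ups from the uniform background.")
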