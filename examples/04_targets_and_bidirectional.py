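"""End-to-end study: targets, bidirectional classification, overlap test.

Runs the full pipeline on the 300-gene demo with 5x crosslink enrichment
at the planted loading sites. Because those sites live in bidirectionally
transcribed genes, the called target set should overlap the classified
bidirectional set far beyond chance — the Fisher p quantifies that.
"""

import bidirscan as b

config = b.SimulationConfig(seed=42, crosslink_enrichment=5.0)
result = b.run_full(config)

counts = result.manifest.counts
print(f"peaks: {counts['n_peaks']}; target genes: {counts['n_target_genes']} "
      f"of {len(result.truth.genes)}")
print(f"classified bidirectional: {counts['n_bidirectional']} "
      f"({counts['n_excluded']} excluded for TSS proximity)")
(a, b_), (c, d) = result.overlap.table
print(f"overlap table [[both, targets-only], [bidir-only, neither]] = "
      f"[[{a}, {b_}], [{c}, {d}]]")
print(f"Fisher two-sided p = {result.overlap.p_value:.2e}, "
      f"odds ratio = {result.overlap.odds_ratio:.1f}")
print(f"top ranked 500-bp window: {result.windows[0].contig}:"
      f"{result.windows[0].start} with {result.windows[0].unique_read_count} reads")
print("A p-value far below 0.01 recovers the planted coupling between "
      "crosslink loading and bidirectional transcription.")
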