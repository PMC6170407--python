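# bidirscan

Strand-aware analysis of where an RNA-guided DNA deaminase loads in the
genome. In activated B cells, activation-induced cytidine deaminase (AID)
is recruited to a small set of loci — immunoglobulin switch regions and
off-target promoters/enhancers — and the recruiting signal is carried by
nascent RNA: bidirectionally transcribed promoters expose both a sense
transcript and a short upstream-antisense RNA, and a CU-rich-binding
PTB-family protein bound to these RNAs tethers the deaminase to the locus.
`bidirscan` implements the computational side of that biology as a tested,
reusable pipeline:

* **Synthetic studies with ground truth** — genomes with non-overlapping
  genes, a configurable fraction of bidirectionally transcribed promoters,
  planted CU-rich loading sites, crosslink-IP (CLIP-like) and
  nascent-transcription (Gro-seq-like) read libraries, and mutated Sanger
  clones; every downstream stage is testable without external data.
* **Stranded coverage and metaprofiles** — 5'-end (crosslink-proxy) binned
  tracks per strand, strand-reoriented TSS/center profiles, RPKM, and
  10-kb binned Pearson correlation between tracks.
* **Peak calling** — nonzero 20-bp bin counts are modelled per strand by a
  zero-truncated negative binomial, `f(k) = NB(k; μ, r) / (1 − NB(0; μ, r))`
  for `k ≥ 1`, fitted by maximum likelihood; a bin's p-value is the
  conditional upper tail `P(X ≥ count | X ≥ 1)`, thresholded at `1e-5` or
  `2e-3`, optionally with Benjamini–Hochberg correction.
* **Target layer** — 500-bp window ranking by unique-read count, peak→gene
  clustering (gene body + 2-kb promoter), low/medium/high density tertiles,
  classification of genes as bidirectional from sense vs upstream-antisense
  coverage in 2-kb TSS windows (with a 2-kb proximity exclusion), and the
  statistics used to compare gene sets: two-sided Fisher exact,
  Kolmogorov–Smirnov, Wilcoxon rank-sum, and t tests.
* **Motifs** — RGYW/WRCY deamination-hotspot scanning (R = purine,
  Y = pyrimidine, W = A/T; WRCY is the reverse complement of RGYW),
  CU-content scoring, and seeded-EM consensus discovery against a
  dinucleotide-shuffled background (recovers `UCUCUCU` on simulated bound
  sequences).
* **Mutation analysis** — Needleman–Wunsch alignment of Sanger clones to a
  reference, C/G mutation frequency under both conventional denominators
  (per C/G base and per sequenced base), the 12-cell substitution spectrum,
  and the fraction of C/G mutations in hotspot context.

## Worked example

```python
import bidirscan as b

config = b.SimulationConfig(seed=42, crosslink_enrichment=5.0)
result = b.run_full(config)
print(result.manifest.counts)
```

Running `python examples/04_targets_and_bidirectional.py` (the same study)
prints:

```
peaks: 312; target genes: 105 of 300
classified bidirectional: 93 (0 excluded for TSS proximity)
overlap table [[both, targets-only], [bidir-only, neither]] = [[68, 37], [25, 170]]
Fisher two-sided p = 4.44e-20, odds ratio = 12.5
top ranked 500-bp window: chr1:1828500 with 44 reads
```

Of 300 simulated genes, 105 acquire at least one crosslink peak and 93 are
classified bidirectional from the nascent-transcription library; 68 genes
are in both sets. Because the simulator plants the CU-rich loading sites in
the bidirectional genes, the Fisher test recovers that coupling at
p ≈ 4e-20 — the synthetic restatement of the finding that deaminase
targets are preferentially bidirectionally transcribed. The other scripts
in `examples/` walk through peak calling, metaprofile orientation, motif
discovery, and the clone mutation spectrum one capability at a time.

A thin CLI mirrors the library for shell use:

```bash
bidirscan simulate --outdir sim --seed 7
bidirscan callpeaks --reads sim/clip_reads.bed --genome sim/genome.fa \
    --bin 20 --p 2e-3 --out peaks.bed
bidirscan shm --reference ref.fa --clones clones.fa --mode cg_bases
```

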