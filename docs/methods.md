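# Methods

This note documents the models, conventions and numerical choices behind
`bidirscan`, and what the synthetic studies do and do not establish about
real data.

## Coordinate and strand conventions

All coordinates are 0-based half-open (BED dialect). The TSS of a
minus-strand gene is its larger coordinate. A read's crosslink proxy is
its 5' end — `start` on the plus strand, `end − 1` on the minus strand —
and all binned tracks, window ranks, RPKM assignment and TSS coverage
counts use 5'-end counting. Full-fragment coverage is deliberately not
used: crosslink libraries are sequenced from short protected fragments
whose 5' end is the most position-faithful signal, and nascent-transcription
tracks use the same convention so the two are directly comparable.
Metaprofiles reorient each anchor so that "sense" is the anchor strand and
positive offsets are downstream; anchors closer than the flank to a contig
edge are dropped (and counted), never clipped, so every anchor contributes
the same window length.

## The synthetic study

The generator (`simulate`) is first-class, tested code, and its defaults
define the demo study: 2 contigs × 3 Mb, 300 non-overlapping genes
(2–4 kb) placed in equal slots with margins ≥ 5 kb so the ±5-kb
metaprofile flank and the 2-kb antisense span stay inside the contig;
30% of genes are labelled bidirectional. Bidirectional genes are the
*target* genes: each receives 3 copies of the DNA equivalent of the RNA
motif `UCUCUCU` (`TCTCTCT`, reverse-complemented on minus-strand genes) in
the 1-kb promoter-proximal region, plus an upstream-antisense transcription
unit spanning 2 kb on the opposite strand. This couples crosslink loading
to bidirectional transcription by construction — the association the
pipeline-level Fisher test must recover — and setting
`crosslink_enrichment = 1` severs it, giving a clean null for calibration.

Read libraries are drawn by normalising a per-bp intensity field to a
Poisson total around `n_reads` (so the realised library size fluctuates as
in a real experiment) and apportioning reads multinomially:

* **Crosslink library**: uniform background at `background_rate`
  (5e-4 reads/bp/strand before normalisation) on both strands;
  inside each planted site (motif ± read length, on the transcript strand)
  the intensity is `crosslink_enrichment × background_rate`. When
  `background_rate = 0` the site intensity is taken as a positive constant
  so that all mass sits on the sites (a multiplicative-only definition
  would leave the field identically zero).
* **Nascent-transcription library**: gene bodies emit sense reads at
  `expression_weight × 0.05` per bp (weights log-normal, σ = 0.75);
  bidirectional genes additionally emit the upstream-antisense unit at
  half the sense intensity; the same uniform background applies.
* **Sanger clones**: each C/G base of the reference mutates independently
  at `clone_mutation_rate` (default 0.30); a mutation is a transition
  (C→T, G→A) with probability `transition_bias` (default 0.9), otherwise
  one of the two transversions with equal probability. A/T bases never
  mutate: the modelled lesion is cytidine deamination, which acts on C:G
  pairs, and an A/T channel would only dilute the C/G-denominator
  statistics the analysis reports.

What the generator does *not* emulate: sequencing error, PCR duplicates,
splicing, mappability structure, non-uniform genomic composition, or the
pile-up shape of real crosslink truncations (site reads are uniform within
motif ± read length — no quantitative model of the pile-up shape exists to
copy). Passing tests therefore demonstrate the correctness and calibration
of the algorithms under a known generative model, not robustness to every
artefact of real libraries.

## Zero-truncated negative-binomial peak calling

Nonzero bin counts on each strand are modelled as NB(μ, r) truncated at
zero. The likelihood is maximised over (log μ, log r) by Nelder–Mead from
a method-of-moments start (tolerance 1e-8), with a deterministic 60×60
log-spaced grid search as fallback; log r is capped at log 1e6, beyond
which the fit is numerically Poisson and is flagged degenerate (as is an
all-equal-counts input, which carries no dispersion information). The
p-value of a bin with count c is the conditional tail
P(X ≥ c | X ≥ 1) = SF(c − 1) / (1 − P₀), with the NB survival function
evaluated through the regularised incomplete beta function for stability;
p(1) = 1 by construction. Strands are fitted and thresholded
independently; a strand with fewer than 30 nonzero bins is skipped with a
warning. Benjamini–Hochberg correction over each strand's nonzero bins is
optional, as is merging runs of adjacent significant bins (off by default:
each call is one bin, which keeps counts interpretable; merging is exposed
as a flag because the choice is not dictated by anything in the model).

## Consensus motif discovery

The finder replaces a general motif suite with a transparent seeded-EM
algorithm: (1) count all k-mers (k = 7 by default, matching the expected
CU-repeat) in the sequences and in per-sequence dinucleotide shuffles
(Altschul–Erikson edge shuffling, fixed RNG seed, so results are
deterministic); the seed is the k-mer maximising (fg + 1)/(bg + 1), ties
broken toward higher foreground support; (2) initialise a PWM from exact
seed occurrences with pseudocount 0.1; (3) refine by EM under a
one-occurrence-per-sequence model with uniform background; (4) apply a
column-shift move (±1, ±2 with brief re-EM), keeping the highest
one-occurrence likelihood — a repeat motif can otherwise converge one
column out of phase, and the in-phase PWM wins because every column is
informative. The result is flagged non-significant unless the seed is
supported by ≥ 5% of sequences (min 3) and by ≥ 3× its shuffled-background
count; a seed supported at least once per sequence is accepted regardless
of the background ratio, because a pure repeat is invariant under
dinucleotide shuffling and its background count is then uninformative.
No ZOOPS/ANR site models and no E-value calibration are attempted.

## Target layer and statistics

A *target* is a gene with at least one called peak; peaks are assigned to
genes whose body plus 2-kb TSS-upstream promoter they overlap, the nearest
TSS winning when several genes qualify (ties to the lexicographically
smaller gene id, so results are order-independent). Density grouping uses
empirical tertiles with boundary ties falling to the lower group.
Bidirectional classification counts 5' ends on the gene strand in
[TSS, TSS + 2 kb) and on the opposite strand in [TSS − 2 kb, TSS), both
gene-oriented; a gene is called bidirectional when both counts reach the
minimum (default 10 reads — at the demo depth of 2×10⁵ reads the uniform
background alone can reach 5 reads in a 2-kb window, so the lower bound of
5 used elsewhere as an illustration would misclassify; both minima are
exposed as parameters). Genes whose TSS lies within 2 kb of another
gene's TSS or annotated span are excluded outright, since their TSS-window
signal cannot be attributed to a single gene.

The overlap statistic is the two-sided Fisher exact test defined by
summation of hypergeometric point probabilities ≤ the observed table's
(delegated to `scipy.stats.fisher_exact` and verified against brute-force
enumeration to 1e-12). Note that for perfectly coincident sets the
two-sided p is *twice* the single-table probability whenever the fully
disjoint table is equally extreme — a property of the definition, not an
implementation artefact. The rank-sum test enumerates exactly when both
samples have ≤ 12 untied observations, otherwise uses the tie-corrected
normal approximation; KS and t tests come from scipy. Under the null
pipeline (enrichment 1) the overlap p-value is uniform up to the
discreteness of the hypergeometric support; a KS uniformity check across
50 replicate runs passes at the 1% level, though the statistic itself
fluctuates between seed blocks precisely because the support is discrete.

## Clone alignment and mutation summaries

Clones are aligned globally with match +1, mismatch −1, gap −2 (linear),
the row recurrence vectorised via a running-max identity; traceback ties
break deterministically: diagonal (match, then mismatch) over a
reference-consuming gap over a clone-consuming gap. Frequencies use two
denominators because both are in common use: mutations per C/G base
sequenced (headline) and per base sequenced; reference positions deleted
in a clone are removed from that clone's denominators, since an
unsequenced base cannot be scored. Each substitution event is counted
once; per-event counting on clones with multiple mutations is deliberate
and the per-clone distribution is recoverable from the alignments. A C/G
mutation is in hotspot context when its reference position falls inside
any RGYW/WRCY 4-mer window of the reference.

## Problem sizes and determinism

The shipped studies are desk-scale by design: 6 Mb genomes, 2×10⁵-read
libraries, 10⁵-bin calibration nulls, 50-replicate calibrations, 200
clones × 100 C/G bases for estimator recovery. Headline counts from the
genome-scale experiments this pipeline mirrors (tens of thousands of
peaks, thousands of target genes) require the original deposited data and
a mouse reference and are out of scope here. Every entry point is
deterministic given its seed: simulation stages draw from independent
per-stage RNG streams derived from `config.seed`, fitting contains no
randomness, motif discovery fixes its shuffle seed, and `run_full`
produces byte-identical outputs (checksummed in its manifest) when re-run
with the same config.

## Known limitations

The ZTNB size parameter has ~2.5% sampling error at 10⁴ draws, so
recovery-within-5% checks carry a small seed-dependent failure
probability. The dinucleotide-shuffle background is blind to pure repeats
(handled by the saturation rule above). Peak→gene assignment uses TSS
distance only; overlapping gene models beyond the 2-kb exclusion are not
otherwise disambiguated. The aligner is global with linear gap costs and
is not intended for clones with large structural differences.
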