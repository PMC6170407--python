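"""From peaks and reads to ranked windows, target genes, and statistics.

This layer turns raw peak/read evidence into the gene-level objects the
analysis reasons about: 500-bp window ranking of binding strength, peak to
gene clustering, low/medium/high density grouping, classification of genes
as bidirectionally transcribed from strand-specific coverage around the
TSS, and the overlap/distribution statistics (Fisher exact,
Kolmogorov-Smirnov, Wilcoxon rank-sum, t test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats import GeneAnnotation, ReadInterval
from .peaks import PeakCall


class TargetError(ValueError):
    pass


@dataclass(frozen=True)
class WindowScore:
    contig: str
    start: int
    end: int
    unique_read_count: int
    rank: int


@dataclass
class TargetGene:
    gene_id: str
    n_peaks: int
    clip_density: float  # peak-read count per kb of gene span + promoter flank
    group: str | None = None  # {"low", "medium", "high"}
    is_target: bool = False


@dataclass
class BidirectionalCall:
    gene_id: str
    sense_coverage: int
    antisense_coverage: int
    label: str | None  # {"bidirectional", "other"}; None when excluded
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class OverlapResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # may be inf when a margin cell is zero
    p_value: float
    universe_size: int


@dataclass
class DistributionComparison:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# window ranking


def rank_windows(
    reads: Iterable[ReadInterval],
    contig_lengths: Mapping[str, int],
    window: int = 500,
    unique_only: bool = True,
) -> list[WindowScore]:
    """Rank non-overlapping genomic tiles by pooled-strand 5'-end counts.

    A read is counted in the tile containing its 5' end; both strands are
    pooled. Only tiles with at least one read are returned; ranks are
    1..N ordered by (count desc, contig, start).
    """
    if window <= 0:
        raise TargetError("window must be positive")
    counts: dict[str, np.ndarray] = {
        c: np.zeros(math.ceil(L / window), dtype=np.int64)
        for c, L in contig_lengths.items()
    }
    for r in reads:
        if unique_only and not r.unique:
            continue
        if r.contig not in counts:
            raise TargetError(f"read on unknown contig {r.contig!r}")
        counts[r.contig][r.five_prime // window] += 1
    rows = []
    for contig in sorted(counts):
        arr = counts[contig]
        for b in np.flatnonzero(arr):
            start = int(b) * window
            rows.append(
                (
                    -int(arr[b]),
                    contig,
                    start,
                    min(start + window, contig_lengths[contig]),
                )
            )
    rows.sort()
    return [
        WindowScore(
            contig=contig,
            start=start,
            end=end,
            unique_read_count=-neg,
            rank=i,
        )
        for i, (neg, contig, start, end) in enumerate(rows, start=1)
    ]


# ---------------------------------------------------------------------------
# peak -> gene clustering


def _extended_span(gene: GeneAnnotation, flank: int) -> tuple[int, int]:
    """Gene span plus TSS-upstream promoter flank, clipped at zero."""
    lo, hi = gene.span
    if gene.strand == "+":
        return max(0, lo - flank), hi
    return lo, hi + flank


def cluster_peaks_to_genes(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneAnnotation],
    promoter_flank: int = 2000,
) -> list[TargetGene]:
    """Assign peaks to genes; a gene with >= 1 peak is a target.

    A peak belongs to a gene iff its bin overlaps the gene span extended by
    ``promoter_flank`` upstream of the TSS. A peak overlapping several
    genes goes to the one with the nearest TSS (ties break to the
    lexicographically smaller gene_id). ``clip_density`` is the summed
    peak-read count per kb of the extended span.
    """
    spans = {g.gene_id: _extended_span(g, promoter_flank) for g in genes}
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    n_peaks = {g.gene_id: 0 for g in genes}
    peak_reads = {g.gene_id: 0 for g in genes}
    for p in peaks:
        candidates = []
        for g in by_contig.get(p.contig, ()):
            lo, hi = spans[g.gene_id]
            if p.start < hi and p.end > lo:
                center = (p.start + p.end) / 2.0
                candidates.append((abs(center - g.tss), g.gene_id))
        if candidates:
            _, gid = min(candidates)
            n_peaks[gid] += 1
            peak_reads[gid] += p.count
    out = []
    for g in genes:
        lo, hi = spans[g.gene_id]
        out.append(
            TargetGene(
                gene_id=g.gene_id,
                n_peaks=n_peaks[g.gene_id],
                clip_density=peak_reads[g.gene_id] / ((hi - lo) / 1000.0),
                is_target=n_peaks[g.gene_id] >= 1,
            )
        )
    return out


def group_by_density(targets: Sequence[TargetGene]) -> list[TargetGene]:
    """Partition graded genes into low/medium/high tertiles of density.

    Boundaries are the 1/3 and 2/3 empirical quantiles; genes whose density
    equals a boundary fall into the lower group.
    """
    graded = [t for t in targets]
    if len(graded) < 3:
        raise TargetError("need at least 3 genes to grade")
    dens = np.array([t.clip_density for t in graded])
    q1, q2 = np.quantile(dens, [1 / 3, 2 / 3])
    out = []
    for t in graded:
        if t.clip_density <= q1:
            group = "low"
        elif t.clip_density <= q2:
            group = "medium"
        else:
            group = "high"
        out.append(replace(t, group=group))
    return out


# ---------------------------------------------------------------------------
# bidirectional classification


def classify_bidirectional(
    genes: Sequence[GeneAnnotation],
    reads: Iterable[ReadInterval],
    antisense_window: int = 2000,
    min_sense: int = 5,
    min_antisense: int = 5,
) -> list[BidirectionalCall]:
    """Classify genes by sense/upstream-antisense 5'-end coverage at the TSS.

    Gene-oriented: sense coverage counts 5' ends on the gene strand within
    ``[TSS, TSS + window)`` downstream; antisense coverage counts 5' ends
    on the opposite strand within ``[TSS - window, TSS)`` upstream. A gene
    is labelled bidirectional iff both minima are met. Genes whose TSS lies
    within ``antisense_window`` of another gene's TSS or annotated span are
    excluded (signal cannot be assigned to a single gene).
    """
    fives: dict[tuple[str, str], np.ndarray] = {}
    buckets: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        buckets.setdefault((r.contig, r.strand), []).append(r.five_prime)
    for key, vals in buckets.items():
        fives[key] = np.sort(np.asarray(vals, dtype=np.int64))

    def count(contig: str, strand: str, lo: int, hi: int) -> int:
        pos = fives.get((contig, strand))
        if pos is None or hi <= lo:
            return 0
        return int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))

    excluded = _proximity_excluded(genes, antisense_window)

    calls = []
    for g in genes:
        anti_strand = "-" if g.strand == "+" else "+"
        if g.strand == "+":
            s_lo, s_hi = g.tss, g.tss + antisense_window
            a_lo, a_hi = g.tss - antisense_window, g.tss
        else:
            s_lo, s_hi = g.tss - antisense_window + 1, g.tss + 1
            a_lo, a_hi = g.tss + 1, g.tss + 1 + antisense_window
        sense = count(g.contig, g.strand, max(0, s_lo), s_hi)
        anti = count(g.contig, anti_strand, max(0, a_lo), a_hi)
        if g.gene_id in excluded:
            calls.append(
                BidirectionalCall(
                    gene_id=g.gene_id,
                    sense_coverage=sense,
                    antisense_coverage=anti,
                    label=None,
                    excluded=True,
                    exclusion_reason="proximity",
                )
            )
        else:
            label = (
                "bidirectional"
                if sense >= min_sense and anti >= min_antisense
                else "other"
            )
            calls.append(
                BidirectionalCall(
                    gene_id=g.gene_id,
                    sense_coverage=sense,
                    antisense_coverage=anti,
                    label=label,
                )
            )
    return calls


def _proximity_excluded(
    genes: Sequence[GeneAnnotation], window: int
) -> set[str]:
    """Genes whose TSS is within ``window`` of another gene's TSS or span."""
    excluded: set[str] = set()
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, gs in by_contig.items():
        for g in gs:
            for other in gs:
                if other.gene_id == g.gene_id:
                    continue
                lo, hi = other.span
                dist = 0 if lo <= g.tss < hi else min(
                    abs(g.tss - lo), abs(g.tss - (hi - 1))
                )
                if dist <= window or abs(g.tss - other.tss) <= window:
                    excluded.add(g.gene_id)
                    break
    return excluded


# ---------------------------------------------------------------------------
# statistics


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Two-sided Fisher exact test for overlap of two gene sets.

    Two-sided p sums hypergeometric point probabilities <= that of the
    observed table (the conventional definition). The odds ratio is the
    sample odds ratio, infinite when a complementary cell is zero.
    """
    if not universe:
        raise TargetError("empty universe")
    if not set_a or not set_b:
        raise TargetError("gene sets must be non-empty")
    if not set_a <= universe or not set_b <= universe:
        raise TargetError("gene sets must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a) - both
    b_only = len(set_b) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    res = stats.fisher_exact(table, alternative="two-sided")
    return OverlapResult(
        table=((both, a_only), (b_only, neither)),
        odds_ratio=float(res.statistic),
        p_value=float(res.pvalue),
        universe_size=len(universe),
    )


def compare_distributions(
    x: Sequence[float], y: Sequence[float], test: str = "ks"
) -> DistributionComparison:
    """Compare two samples: 'ks', 'wilcoxon' (rank-sum) or 'ttest'.

    The rank-sum test enumerates exactly when both samples have <= 12
    untied observations, otherwise uses the tie-corrected normal
    approximation. KS uses the two-sample sup-difference of ECDFs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TargetError("empty sample")
    if test == "ks":
        if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
            stat, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(x, y, method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size <= 12 and y.size <= 12 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise TargetError(f"unknown test {test!r}")
    return DistributionComparison(
        test=test, statistic=stat, p_value=min(1.0, p), n1=int(x.size), n2=int(y.size)
    )
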