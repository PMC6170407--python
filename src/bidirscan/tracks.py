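"""Strand-specific binned coverage, metaprofiles, RPKM and correlation.

Coverage uses 5'-end counting: each read contributes one count to the bin
containing its crosslink-proxy position (start on '+', end-1 on '-'). This
matches the short-crosslinked-RNA character of CLIP libraries; nascent
transcription tracks use the same convention for uniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats import GeneAnnotation, IntervalScore, ReadInterval, write_bedgraph


class TrackError(ValueError):
    pass


@dataclass
class StrandedTrack:
    """Per-strand binned 5'-end counts over a set of contigs."""

    bin_size: int
    contig_lengths: dict[str, int]
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    library_size: int

    def counts(self, strand: str) -> dict[str, np.ndarray]:
        return self.plus if strand == "+" else self.minus

    def total_mass(self) -> int:
        return int(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )

    def collapsed(self) -> dict[str, np.ndarray]:
        """Strand-pooled counts per contig."""
        return {c: self.plus[c] + self.minus[c] for c in self.plus}

    def to_bedgraph(self, prefix: str | Path) -> None:
        """Write one bedGraph per strand (nonzero bins only)."""
        prefix = Path(prefix)
        for strand, label in (("+", "plus"), ("-", "minus")):
            scores = []
            for contig, arr in sorted(self.counts(strand).items()):
                for b in np.flatnonzero(arr):
                    start = int(b) * self.bin_size
                    end = min(start + self.bin_size, self.contig_lengths[contig])
                    scores.append(
                        IntervalScore(contig, start, end, strand, float(arr[b]))
                    )
            write_bedgraph(scores, f"{prefix}.{label}.bedgraph")


@dataclass
class MetaProfile:
    """Average strand-reoriented signal around a set of anchors."""

    anchor_kind: str  # {"tss", "center"}
    flank: int
    bin_size: int
    sense_mean: np.ndarray
    antisense_mean: np.ndarray
    n_anchors: int
    n_dropped: int = 0

    @property
    def positions(self) -> np.ndarray:
        """Relative bin-start offsets, negative = upstream of the anchor."""
        return np.arange(-self.flank, self.flank, self.bin_size)


@dataclass(frozen=True)
class GeneExpression:
    gene_id: str
    read_count: int
    rpkm: float
    log2_rpkm: float


# ---------------------------------------------------------------------------


def build_track(
    reads: Iterable[ReadInterval],
    contig_lengths: Mapping[str, int],
    bin_size: int = 20,
    unique_only: bool = False,
) -> StrandedTrack:
    """Bin read 5' ends into a per-strand track."""
    if bin_size <= 0:
        raise TrackError("bin_size must be positive")
    n_bins = {c: math.ceil(L / bin_size) for c, L in contig_lengths.items()}
    plus = {c: np.zeros(n, dtype=np.int64) for c, n in n_bins.items()}
    minus = {c: np.zeros(n, dtype=np.int64) for c, n in n_bins.items()}
    per_contig: dict[tuple[str, str], list[int]] = {}
    n_used = 0
    for r in reads:
        if unique_only and not r.unique:
            continue
        if r.contig not in contig_lengths:
            raise TrackError(f"read on unknown contig {r.contig!r}")
        if r.end > contig_lengths[r.contig]:
            raise TrackError(
                f"read {r.read_id!r} extends beyond contig {r.contig}"
            )
        per_contig.setdefault((r.contig, r.strand), []).append(r.five_prime)
        n_used += 1
    for (contig, strand), fives in per_contig.items():
        arr = plus[contig] if strand == "+" else minus[contig]
        binned = np.bincount(
            np.asarray(fives, dtype=np.int64) // bin_size, minlength=arr.size
        )
        arr += binned
    return StrandedTrack(
        bin_size=bin_size,
        contig_lengths=dict(contig_lengths),
        plus=plus,
        minus=minus,
        library_size=n_used,
    )


def metaprofile(
    track: StrandedTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 5000,
    anchor_kind: str = "tss",
) -> MetaProfile:
    """Mean strand-reoriented signal in ``[-flank, +flank)`` around anchors.

    Signal is reoriented so that "sense" is the anchor strand and positive
    offsets are downstream of the anchor. Anchors closer than ``flank`` to a
    contig edge are dropped (and counted), not clipped.
    """
    if not anchors:
        raise TrackError("empty anchor list")
    if flank % track.bin_size:
        raise TrackError("flank must be a multiple of bin_size")
    nb = flank // track.bin_size
    sense = np.zeros(2 * nb, dtype=float)
    anti = np.zeros(2 * nb, dtype=float)
    used = 0
    dropped = 0
    for contig, pos, strand in anchors:
        if contig not in track.contig_lengths:
            raise TrackError(f"anchor on unknown contig {contig!r}")
        L = track.contig_lengths[contig]
        if pos - flank < 0 or pos + flank > L:
            dropped += 1
            continue
        b0 = pos // track.bin_size
        lo, hi = b0 - nb, b0 + nb
        same = track.counts(strand)[contig][lo:hi]
        other = track.counts("-" if strand == "+" else "+")[contig][lo:hi]
        if strand == "-":
            same = same[::-1]
            other = other[::-1]
        sense += same
        anti += other
        used += 1
    if used == 0:
        raise TrackError("all anchors dropped (closer than flank to an edge)")
    return MetaProfile(
        anchor_kind=anchor_kind,
        flank=flank,
        bin_size=track.bin_size,
        sense_mean=sense / used,
        antisense_mean=anti / used,
        n_anchors=used,
        n_dropped=dropped,
    )


def rpkm(
    reads: Iterable[ReadInterval],
    genes: Sequence[GeneAnnotation],
    unique_only: bool = False,
    pseudocount: float = 1.0,
) -> list[GeneExpression]:
    """Reads-per-kilobase-per-million over gene bodies (5'-end assignment).

    A read is assigned to a gene iff its 5' end lies within the gene span on
    the gene strand. ``log2_rpkm`` = log2(rpkm + pseudocount), pseudocount in
    RPKM units.
    """
    reads = [r for r in reads if (r.unique or not unique_only)]
    library = len(reads)
    if library == 0:
        raise TrackError("empty read library")
    fives: dict[tuple[str, str], np.ndarray] = {}
    for key in {(r.contig, r.strand) for r in reads}:
        fives[key] = np.sort(
            np.array(
                [r.five_prime for r in reads if (r.contig, r.strand) == key],
                dtype=np.int64,
            )
        )
    counts = {}
    for g in genes:
        if g.length == 0:
            raise TrackError(f"zero-length gene {g.gene_id}")
        pos = fives.get((g.contig, g.strand))
        if pos is None:
            counts[g.gene_id] = 0
        else:
            lo, hi = g.span
            counts[g.gene_id] = int(
                np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            )
    out = []
    for g in genes:
        val = counts[g.gene_id] / ((g.length / 1000.0) * (library / 1e6))
        out.append(
            GeneExpression(
                gene_id=g.gene_id,
                read_count=counts[g.gene_id],
                rpkm=val,
                log2_rpkm=float(np.log2(val + pseudocount)),
            )
        )
    return out


def binned_correlation(
    track_a: StrandedTrack,
    track_b: StrandedTrack,
    bin_size: int = 10_000,
    transform: str = "raw",
) -> tuple[float, int]:
    """Pearson R between two strand-collapsed tracks rebinned to ``bin_size``.

    Bins where both tracks are zero are excluded (empty genome would inflate
    R). ``transform='log2p1'`` applies log2(x+1) before correlating.
    """
    if track_a.contig_lengths != track_b.contig_lengths:
        raise TrackError("tracks cover different contigs")
    if bin_size % track_a.bin_size or bin_size % track_b.bin_size:
        raise TrackError("bin_size must be a multiple of both track bin sizes")
    xs, ys = [], []
    ca, cb = track_a.collapsed(), track_b.collapsed()
    for contig, L in track_a.contig_lengths.items():
        n_big = math.ceil(L / bin_size)
        xs.append(_rebin(ca[contig], track_a.bin_size, bin_size, n_big))
        ys.append(_rebin(cb[contig], track_b.bin_size, bin_size, n_big))
    x = np.concatenate(xs).astype(float)
    y = np.concatenate(ys).astype(float)
    keep = (x > 0) | (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise TrackError("fewer than 3 usable bins for correlation")
    if transform == "log2p1":
        x, y = np.log2(x + 1), np.log2(y + 1)
    elif transform != "raw":
        raise TrackError(f"unknown transform {transform!r}")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(x.size)


def _rebin(arr: np.ndarray, small: int, big: int, n_big: int) -> np.ndarray:
    factor = big // small
    out = np.zeros(n_big, dtype=arr.dtype)
    idx = np.arange(arr.size) // factor
    np.add.at(out, idx, arr)
    return out
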