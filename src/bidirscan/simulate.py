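"""Synthetic genomes, stranded read libraries, and mutated Sanger clones.

The generator emulates the statistical structure of crosslink-IP (CLIP) and
nascent-transcription (Gro-seq) libraries over a small genome with known
ground truth:

* non-overlapping genes, a configurable fraction of which are
  *bidirectionally transcribed* (sense gene-body transcription plus an
  upstream-antisense unit on the opposite strand);
* CU-rich motif instances (DNA sense-strand equivalent of the RNA motif,
  default ``UCUCUCU`` -> ``TCTCTCT``) planted in the promoter-proximal
  region of bidirectional genes — these are the crosslink "loading sites";
* CLIP reads concentrated at planted motifs at ``crosslink_enrichment``
  times the uniform background, with 5' ends inside motif +/- read_length;
* Gro-seq reads proportional to transcription-unit activity, with the
  upstream-antisense unit emitted only for bidirectional genes;
* Sanger clones of a reference amplicon mutated at C/G pairs with a
  transition bias, emulating cytidine-deamination footprints.

Every entry point is deterministic given ``config.seed``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .formats import (
    GeneAnnotation,
    ReadInterval,
    write_bed6,
    write_fasta,
    write_gene_table,
    write_json,
    read_fasta,
    read_gene_table,
    read_json,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class SimulationError(ValueError):
    """Raised for infeasible or inconsistent simulation requests."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale demo defaults."""

    n_chroms: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 300
    frac_bidirectional: float = 0.3
    motif: str = "UCUCUCU"
    motifs_per_target: int = 3
    crosslink_enrichment: float = 20.0
    background_rate: float = 5e-4  # reads per bp per strand, pre-normalisation
    n_reads: int = 200_000
    read_length: int = 36
    antisense_span: int = 2000
    clone_mutation_rate: float = 0.30
    transition_bias: float = 0.9
    seed: int = 0
    # generator shape parameters not tied to a printed value
    gene_length_min: int = 2000
    gene_length_max: int = 4000
    promoter_motif_span: int = 1000
    groseq_gene_rate: float = 0.05  # reads/bp per unit expression weight
    antisense_ratio: float = 0.5  # antisense unit activity relative to sense
    hotspot_fraction: float = 0.2  # fraction of target genes flagged as hotspots

    def __post_init__(self) -> None:
        counts = {
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "motifs_per_target": self.motifs_per_target,
            "n_reads": self.n_reads,
            "read_length": self.read_length,
            "antisense_span": self.antisense_span,
        }
        for name, v in counts.items():
            if v < 0:
                raise SimulationError(f"{name} must be >= 0, got {v}")
        for name, v in {
            "frac_bidirectional": self.frac_bidirectional,
            "clone_mutation_rate": self.clone_mutation_rate,
            "transition_bias": self.transition_bias,
            "hotspot_fraction": self.hotspot_fraction,
        }.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        if self.crosslink_enrichment < 1.0:
            raise SimulationError("crosslink_enrichment must be >= 1")
        if self.background_rate < 0:
            raise SimulationError("background_rate must be >= 0")
        if self.chrom_length <= 10 * self.read_length:
            raise SimulationError("chrom_length must exceed 10 x read_length")
        if set(self.motif.upper()) - set("ACGU"):
            raise SimulationError("motif must be an RNA-alphabet string")

    @property
    def motif_dna(self) -> str:
        """The sense-strand DNA equivalent of the RNA motif."""
        return self.motif.upper().replace("U", "T")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticLocusSet:
    """Ground truth of one simulated study: the object every test recovers."""

    genome: dict[str, str]
    genes: list[GeneAnnotation]
    planted_motif_sites: list[tuple[str, int, str]]
    bidirectional_labels: dict[str, bool]
    planted_peaks: list[tuple[str, int, int, str]]
    hotspot_genes: set[str]
    config_key: str
    realized_reads: dict[str, int] = field(default_factory=dict)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def target_genes(self) -> set[str]:
        """Genes carrying planted crosslink motifs (the true loading sites)."""
        return {g for g, bidir in self.bidirectional_labels.items() if bidir}

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_json(
            {
                "planted_motif_sites": self.planted_motif_sites,
                "bidirectional_labels": self.bidirectional_labels,
                "planted_peaks": self.planted_peaks,
                "hotspot_genes": sorted(self.hotspot_genes),
                "config_key": self.config_key,
                "realized_reads": self.realized_reads,
            },
            outdir / "truth.json",
        )

    @classmethod
    def load(cls, outdir: str | Path) -> "SyntheticLocusSet":
        outdir = Path(outdir)
        side = read_json(outdir / "truth.json")
        return cls(
            genome=read_fasta(outdir / "genome.fa"),
            genes=read_gene_table(outdir / "genes.tsv"),
            planted_motif_sites=[tuple(x) for x in side["planted_motif_sites"]],
            bidirectional_labels=dict(side["bidirectional_labels"]),
            planted_peaks=[tuple(x) for x in side["planted_peaks"]],
            hotspot_genes=set(side["hotspot_genes"]),
            config_key=side["config_key"],
            realized_reads=dict(side["realized_reads"]),
        )


# ---------------------------------------------------------------------------
# genome


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per simulation stage
    return np.random.default_rng([config.seed, stream])


def simulate_genome(config: SimulationConfig) -> SyntheticLocusSet:
    """Generate contigs, non-overlapping genes, labels and planted motifs.

    Genes are laid out in equal slots per contig with a margin large enough
    to keep the antisense span and the 5-kb metaprofile flank inside the
    contig. Bidirectional genes receive ``motifs_per_target`` copies of the
    DNA motif in their promoter-proximal region and an upstream-antisense
    transcription unit is recorded for them.
    """
    rng = _rng(config, 0)
    arrays = {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=config.chrom_length)].copy()
        for i in range(config.n_chroms)
    }

    genes: list[GeneAnnotation] = []
    labels: dict[str, bool] = {}
    motif_sites: list[tuple[str, int, str]] = []
    peaks: list[tuple[str, int, int, str]] = []

    if config.n_genes > 0:
        if config.n_chroms == 0:
            raise SimulationError("cannot place genes on zero contigs")
        margin = config.antisense_span + 3000
        per_chrom = [
            config.n_genes // config.n_chroms
            + (1 if i < config.n_genes % config.n_chroms else 0)
            for i in range(config.n_chroms)
        ]
        motif_dna = config.motif_dna
        k = len(motif_dna)
        gene_idx = 0
        for ci, (contig, arr) in enumerate(arrays.items()):
            n_here = per_chrom[ci]
            if n_here == 0:
                continue
            slot = config.chrom_length // n_here
            if slot < config.gene_length_max + 2 * margin:
                raise SimulationError(
                    f"infeasible packing: {n_here} genes of up to "
                    f"{config.gene_length_max} bp (+{margin} bp margins) do not "
                    f"fit in {config.chrom_length} bp of {contig}"
                )
            for j in range(n_here):
                glen = int(
                    rng.integers(config.gene_length_min, config.gene_length_max + 1)
                )
                lo = j * slot + margin + int(
                    rng.integers(0, slot - glen - 2 * margin + 1)
                )
                hi = lo + glen
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"g{gene_idx:04d}"
                gene_idx += 1
                weight = float(rng.lognormal(0.0, 0.75))
                if strand == "+":
                    gene = GeneAnnotation(gid, contig, "+", lo, hi, weight)
                else:
                    # '-' gene: tss is the larger coordinate (hi-1), tes = lo
                    gene = GeneAnnotation(gid, contig, "-", hi - 1, lo, weight)
                genes.append(gene)
                labels[gid] = bool(rng.random() < config.frac_bidirectional)
                if labels[gid] and config.motifs_per_target > 0:
                    span = min(config.promoter_motif_span, glen)
                    chunk = span // config.motifs_per_target
                    if chunk < k:
                        raise SimulationError(
                            "motifs_per_target does not fit in the "
                            "promoter-proximal span"
                        )
                    for m in range(config.motifs_per_target):
                        off = m * chunk + int(rng.integers(0, chunk - k + 1))
                        if strand == "+":
                            start = gene.tss + off
                            arr[start : start + k] = np.frombuffer(
                                motif_dna.encode(), dtype=np.uint8
                            )
                        else:
                            start = gene.tss - off - k + 1
                            arr[start : start + k] = np.frombuffer(
                                reverse_complement(motif_dna).encode(),
                                dtype=np.uint8,
                            )
                        motif_sites.append((contig, start, strand))
                        peaks.append(
                            (
                                contig,
                                max(0, start - config.read_length),
                                min(len(arr), start + k + config.read_length),
                                strand,
                            )
                        )

    target_ids = [g for g, b in labels.items() if b]
    n_hot = math.ceil(config.hotspot_fraction * len(target_ids))
    hotspots = set(
        rng.choice(np.array(sorted(target_ids)), size=n_hot, replace=False).tolist()
    ) if n_hot else set()

    genome = {name: arr.tobytes().decode() for name, arr in arrays.items()}
    return SyntheticLocusSet(
        genome=genome,
        genes=genes,
        planted_motif_sites=motif_sites,
        bidirectional_labels=labels,
        planted_peaks=peaks,
        hotspot_genes=hotspots,
        config_key=config.fingerprint(),
    )


# ---------------------------------------------------------------------------
# read libraries


def _check_truth(truth: SyntheticLocusSet, config: SimulationConfig) -> None:
    if truth.config_key != config.fingerprint():
        raise SimulationError("truth object was generated from a different config")


def _emit(
    positions: np.ndarray,
    contig: str,
    contig_len: int,
    strand: str,
    read_length: int,
    prefix: str,
    start_index: int,
) -> list[ReadInterval]:
    """Turn 5'-end positions into read intervals extending downstream."""
    out = []
    for i, p in enumerate(positions):
        p = int(p)
        if strand == "+":
            start, end = p, min(contig_len, p + read_length)
        else:
            start, end = max(0, p + 1 - read_length), p + 1
        out.append(
            ReadInterval(contig, start, end, strand, f"{prefix}{start_index + i:07d}")
        )
    return out


def simulate_clip_reads(
    truth: SyntheticLocusSet, config: SimulationConfig
) -> list[ReadInterval]:
    """Crosslink-IP reads: uniform background plus motif-site pile-ups.

    Per-bp intensity is ``background_rate`` on both strands everywhere and
    ``crosslink_enrichment x background_rate`` inside planted sites (motif
    +/- read_length, on the transcript strand). The total read count is a
    Poisson draw around ``n_reads``; reads are apportioned multinomially.
    With ``background_rate == 0`` all mass sits on the planted sites.
    """
    _check_truth(truth, config)
    rng = _rng(config, 1)
    lengths = truth.contig_lengths

    cats: list[tuple[str, int, int, str, str]] = []  # contig, lo, hi, strand, kind
    weights: list[float] = []
    for contig, L in lengths.items():
        for strand in "+-":
            cats.append((contig, 0, L, strand, "bg"))
            weights.append(config.background_rate * L)
    for contig, start, strand in truth.planted_motif_sites:
        L = lengths[contig]
        lo = max(0, start - config.read_length)
        hi = min(L, start + len(config.motif_dna) + config.read_length)
        extra = (
            (config.crosslink_enrichment - 1.0) * config.background_rate
            if config.background_rate > 0
            else config.crosslink_enrichment
        )
        cats.append((contig, lo, hi, strand, "xl"))
        weights.append(extra * (hi - lo))

    return _draw_reads(rng, truth, config, cats, weights, library="clip")


def simulate_groseq_reads(
    truth: SyntheticLocusSet, config: SimulationConfig
) -> list[ReadInterval]:
    """Nascent-transcription reads proportional to unit activity.

    Each gene body emits sense-strand reads with per-bp intensity
    ``expression_weight x groseq_gene_rate``; bidirectional genes
    additionally emit an upstream-antisense unit spanning
    ``antisense_span`` bp upstream of the TSS on the opposite strand at
    ``antisense_ratio`` of the sense intensity. No motif concentration.
    """
    _check_truth(truth, config)
    rng = _rng(config, 2)
    lengths = truth.contig_lengths

    cats: list[tuple[str, int, int, str, str]] = []
    weights: list[float] = []
    for contig, L in lengths.items():
        for strand in "+-":
            cats.append((contig, 0, L, strand, "bg"))
            weights.append(config.background_rate * L)
    for gene in truth.genes:
        L = lengths[gene.contig]
        w = gene.expression_weight if gene.expression_weight is not None else 1.0
        lo, hi = gene.span
        cats.append((gene.contig, lo, hi, gene.strand, "sense"))
        weights.append(w * config.groseq_gene_rate * (hi - lo))
        if truth.bidirectional_labels.get(gene.gene_id, False):
            anti_strand = "-" if gene.strand == "+" else "+"
            if gene.strand == "+":
                a_lo = max(0, gene.tss - config.antisense_span)
                a_hi = gene.tss
            else:
                a_lo = gene.tss + 1
                a_hi = min(L, gene.tss + 1 + config.antisense_span)
            cats.append((gene.contig, a_lo, a_hi, anti_strand, "anti"))
            weights.append(
                w * config.groseq_gene_rate * config.antisense_ratio * (a_hi - a_lo)
            )

    return _draw_reads(rng, truth, config, cats, weights, library="groseq")


def _draw_reads(
    rng: np.random.Generator,
    truth: SyntheticLocusSet,
    config: SimulationConfig,
    cats: list[tuple[str, int, int, str, str]],
    weights: list[float],
    library: str,
) -> list[ReadInterval]:
    w = np.asarray(weights, dtype=float)
    n_total = int(rng.poisson(config.n_reads))
    truth.realized_reads[library] = n_total
    if n_total == 0:
        return []
    if w.sum() <= 0:
        raise SimulationError(
            f"{library}: no read-generating mass (all category weights zero)"
        )
    counts = rng.multinomial(n_total, w / w.sum())
    lengths = truth.contig_lengths
    reads: list[ReadInterval] = []
    serial = 0
    for (contig, lo, hi, strand, kind), n in zip(cats, counts):
        if n == 0:
            continue
        positions = rng.integers(lo, hi, size=n)
        reads.extend(
            _emit(
                positions,
                contig,
                lengths[contig],
                strand,
                config.read_length,
                f"{library}-{kind}-",
                serial,
            )
        )
        serial += int(n)
    return reads


# ---------------------------------------------------------------------------
# Sanger clones


def simulate_clones(
    reference: str, n_clones: int, config: SimulationConfig
) -> list[str]:
    """Mutate C/G bases of ``reference`` independently per clone.

    Each C/G position mutates with ``clone_mutation_rate``; a mutation is a
    transition (C->T, G->A) with probability ``transition_bias``, otherwise
    one of the two transversions with equal probability. A/T bases are left
    untouched (the deamination substrate is C:G).
    """
    if not reference:
        raise SimulationError("reference must be non-empty")
    reference = reference.upper()
    if set(reference) - set("ACGTN"):
        raise SimulationError("reference must be over A/C/G/T/N")
    rng = _rng(config, 3)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    cg_mask = (ref == ord("C")) | (ref == ord("G"))
    cg_idx = np.flatnonzero(cg_mask)
    # outcome tables: transition, transversion-1, transversion-2
    outcomes = {
        ord("C"): (ord("T"), ord("G"), ord("A")),
        ord("G"): (ord("A"), ord("C"), ord("T")),
    }
    clones = []
    for _ in range(n_clones):
        arr = ref.copy()
        hit = cg_idx[rng.random(cg_idx.size) < config.clone_mutation_rate]
        for pos in hit:
            ts, tv1, tv2 = outcomes[int(ref[pos])]
            u = rng.random()
            if u < config.transition_bias:
                arr[pos] = ts
            elif u < config.transition_bias + (1 - config.transition_bias) / 2:
                arr[pos] = tv1
            else:
                arr[pos] = tv2
        clones.append(arr.tobytes().decode())
    return clones


# ---------------------------------------------------------------------------
# on-disk bundle


def write_simulation(
    truth: SyntheticLocusSet,
    outdir: str | Path,
    clip_reads: list[ReadInterval] | None = None,
    groseq_reads: list[ReadInterval] | None = None,
) -> None:
    """Write the FASTA/TSV/BED6/JSON bundle for one simulated study."""
    outdir = Path(outdir)
    truth.save(outdir)
    if clip_reads is not None:
        write_bed6(clip_reads, outdir / "clip_reads.bed")
    if groseq_reads is not None:
        write_bed6(groseq_reads, outdir / "groseq_reads.bed")
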