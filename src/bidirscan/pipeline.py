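"""End-to-end orchestration: simulate -> tracks -> peaks -> targets -> motifs.

``run_full`` executes the whole synthetic study under one config and
returns every stage output plus a manifest capturing the config hash, the
seed, per-stage parameters and (when written to disk) file checksums, so a
run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .formats import ReadInterval, write_bed6, write_json
from .motifs import ConsensusResult, discover_consensus
from .mutations import MutationSummary, align_clones, mutation_summary
from .peaks import PeakCall, call_peaks
from .simulate import (
    SimulationConfig,
    SyntheticLocusSet,
    reverse_complement,
    simulate_clip_reads,
    simulate_clones,
    simulate_genome,
    simulate_groseq_reads,
)
from .targets import (
    BidirectionalCall,
    OverlapResult,
    TargetGene,
    WindowScore,
    classify_bidirectional,
    cluster_peaks_to_genes,
    group_by_density,
    overlap_enrichment,
    rank_windows,
)
from .tracks import StrandedTrack, build_track


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class StageParams:
    """Per-stage analysis parameters (defaults = the study's printed ones)."""

    bin_size: int = 20
    p_threshold: float = 2e-3
    bh_correct: bool = False
    window: int = 500
    promoter_flank: int = 2000
    antisense_window: int = 2000
    min_sense: int = 10
    min_antisense: int = 10
    motif_k: int = 7
    motif_iterations: int = 10
    motif_flank: int = 17
    n_motif_sequences: int = 200
    n_clones: int = 20
    amplicon_length: int = 300


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    stage_params: dict
    version: str
    counts: dict = field(default_factory=dict)
    file_checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    truth: SyntheticLocusSet
    clip_reads: list[ReadInterval]
    groseq_reads: list[ReadInterval]
    clip_track: StrandedTrack
    peaks: list[PeakCall]
    windows: list[WindowScore]
    targets: list[TargetGene]
    bidirectional: list[BidirectionalCall]
    overlap: OverlapResult
    motif: ConsensusResult | None
    mutations: MutationSummary
    manifest: RunManifest


def _peak_sequences(
    truth: SyntheticLocusSet,
    peaks: list[PeakCall],
    flank: int,
    limit: int,
) -> list[str]:
    """Transcript-strand sequences under the strongest peaks."""
    ordered = sorted(peaks, key=lambda p: (-p.count, p.contig, p.start, p.strand))
    seqs = []
    for p in ordered[:limit]:
        contig_seq = truth.genome[p.contig]
        lo = max(0, p.start - flank)
        hi = min(len(contig_seq), p.end + flank)
        s = contig_seq[lo:hi]
        seqs.append(s if p.strand == "+" else reverse_complement(s))
    return seqs


def run_full(
    config: SimulationConfig,
    params: StageParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the complete synthetic study under one config.

    Stages run in dependency order; any failure is re-raised as a
    ``PipelineError`` naming the stage, with upstream outputs already
    written when an output directory was given.
    """
    params = params or StageParams()

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    truth = stage("simulate.genome", lambda: simulate_genome(config))
    clip = stage("simulate.clip", lambda: simulate_clip_reads(truth, config))
    groseq = stage("simulate.groseq", lambda: simulate_groseq_reads(truth, config))
    lengths = truth.contig_lengths
    clip_track = stage(
        "tracks.build", lambda: build_track(clip, lengths, params.bin_size)
    )
    peaks = stage(
        "peaks.call",
        lambda: call_peaks(
            clip_track,
            bin_size=params.bin_size,
            p_threshold=params.p_threshold,
            correct=params.bh_correct,
        ),
    )
    windows = stage(
        "targets.rank_windows", lambda: rank_windows(clip, lengths, params.window)
    )
    target_genes = stage(
        "targets.cluster",
        lambda: group_by_density(
            cluster_peaks_to_genes(peaks, truth.genes, params.promoter_flank)
        ),
    )
    bidir = stage(
        "targets.bidirectional",
        lambda: classify_bidirectional(
            truth.genes,
            groseq,
            antisense_window=params.antisense_window,
            min_sense=params.min_sense,
            min_antisense=params.min_antisense,
        ),
    )

    def _overlap():
        universe = {c.gene_id for c in bidir if not c.excluded}
        set_a = {t.gene_id for t in target_genes if t.is_target} & universe
        set_b = {c.gene_id for c in bidir if c.label == "bidirectional"}
        return overlap_enrichment(set_a, set_b, universe)

    overlap = stage("targets.overlap", _overlap)

    def _motif():
        seqs = _peak_sequences(
            truth, peaks, params.motif_flank, params.n_motif_sequences
        )
        if len(seqs) < 20:
            return None
        return discover_consensus(
            seqs, k=params.motif_k, iterations=params.motif_iterations
        )

    motif = stage("motifs.discover", _motif)

    def _mutations():
        contig = next(iter(truth.genome))
        amplicon = truth.genome[contig][: params.amplicon_length]
        clones = simulate_clones(amplicon, params.n_clones, config)
        return mutation_summary(align_clones(amplicon, clones), amplicon)

    muts = stage("mutations.summary", _mutations)

    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=config.fingerprint(),
        seed=config.seed,
        stage_params=asdict(params),
        version=__version__,
        counts={
            "n_clip_reads": len(clip),
            "n_groseq_reads": len(groseq),
            "n_peaks": len(peaks),
            "n_ranked_windows": len(windows),
            "n_target_genes": sum(t.is_target for t in target_genes),
            "n_bidirectional": sum(
                c.label == "bidirectional" for c in bidir
            ),
            "n_excluded": sum(c.excluded for c in bidir),
            "overlap_p_value": overlap.p_value,
            "motif_consensus": motif.consensus if motif else None,
            "cg_mutation_frequency": muts.freq_cg_denominator,
        },
    )

    result = PipelineResult(
        truth=truth,
        clip_reads=clip,
        groseq_reads=groseq,
        clip_track=clip_track,
        peaks=peaks,
        windows=windows,
        targets=target_genes,
        bidirectional=bidir,
        overlap=overlap,
        motif=motif,
        mutations=muts,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.truth.save(outdir)
    write_bed6(result.clip_reads, outdir / "clip_reads.bed")
    write_bed6(result.groseq_reads, outdir / "groseq_reads.bed")
    pd.DataFrame(
        [
            {
                "contig": p.contig,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "count": p.count,
                "p_value": p.p_value,
                "q_value": p.q_value,
            }
            for p in result.peaks
        ]
    ).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(w) for w in result.windows]).to_csv(
        outdir / "windows.tsv", sep="\t", index=False
    )
    pd.DataFrame([asdict(t) for t in result.targets]).to_csv(
        outdir / "targets.tsv", sep="\t", index=False
    )
    pd.DataFrame([asdict(c) for c in result.bidirectional]).to_csv(
        outdir / "bidirectional.tsv", sep="\t", index=False
    )
    for name in (
        "peaks.tsv",
        "windows.tsv",
        "targets.tsv",
        "bidirectional.tsv",
        "clip_reads.bed",
        "groseq_reads.bed",
        "genome.fa",
        "genes.tsv",
    ):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        result.manifest.file_checksums[name] = digest
    write_json(result.manifest.to_dict(), outdir / "manifest.json")
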