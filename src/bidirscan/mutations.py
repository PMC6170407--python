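"""Clone-vs-reference mutation analysis for Sanger-sequenced amplicons.

Clones are globally aligned to the reference (match +1, mismatch -1,
gap -2) and per-column mutation records extracted. The headline statistic
is the C/G mutation frequency, reported under both denominators in use for
deamination assays: mutations over all C/G bases sequenced, and mutations
over all bases sequenced. The 12-cell substitution spectrum and the
fraction of C/G mutations falling inside RGYW/WRCY hotspot 4-mers are
reported alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifs import hotspot_positions

_VALID = set("ACGTN")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
GAP = "-"


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    ref_position: int
    ref_base: str
    clone_base: str
    kind: str  # {"substitution", "insertion", "deletion"}
    substitution_class: str | None = None  # {"transition", "transversion"}
    at_cg: bool = False


@dataclass
class CloneAlignment:
    clone_id: str
    aligned_reference: str
    aligned_clone: str
    score: int
    mutations: list[MutationRecord]

    @property
    def deleted_ref_positions(self) -> list[int]:
        return [m.ref_position for m in self.mutations if m.kind == "deletion"]


@dataclass
class MutationSummary:
    n_clones: int
    total_bases_sequenced: int
    total_cg_bases: int
    n_cg_mutations: int
    freq_cg_denominator: float
    freq_all_denominator: float
    spectrum: dict[str, int]
    hotspot_fraction: float
    mode: str = "cg_bases"

    @property
    def headline_frequency(self) -> float:
        return (
            self.freq_cg_denominator
            if self.mode == "cg_bases"
            else self.freq_all_denominator
        )

    @property
    def n_transitions(self) -> int:
        return sum(
            n for sub, n in self.spectrum.items()
            if (sub[0], sub[2]) in _TRANSITIONS
        )

    @property
    def n_substitutions(self) -> int:
        return sum(self.spectrum.values())


# ---------------------------------------------------------------------------
# alignment

MATCH, MISMATCH, GAP_PENALTY = 1, -1, -2


def align_clone(reference: str, clone: str, clone_id: str = "") -> CloneAlignment:
    """Global (Needleman-Wunsch) alignment of a clone to its reference.

    Scoring: match +1, mismatch -1, gap -2 (linear). Traceback ties break
    deterministically preferring diagonal (match, then mismatch) over a
    reference-consuming gap (deletion in the clone) over a clone-consuming
    gap (insertion).
    """
    if not reference or not clone:
        raise MutationError("reference and clone must be non-empty")
    ref = reference.upper()
    qry = clone.upper()
    for name, s in (("reference", ref), ("clone", qry)):
        bad = set(s) - _VALID
        if bad:
            raise MutationError(f"{name} contains non-ACGTN characters: {sorted(bad)}")

    n, m = len(ref), len(qry)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = GAP_PENALTY * np.arange(m + 1)
    H[:, 0] = GAP_PENALTY * np.arange(n + 1)
    qarr = np.frombuffer(qry.encode(), dtype=np.uint8)
    rarr = np.frombuffer(ref.encode(), dtype=np.uint8)
    # row recurrence: the left-gap dependency row[j-1] + GAP_PENALTY is a
    # running max of (candidate[j] - GAP_PENALTY * j), so each row vectorises
    shift = -GAP_PENALTY * np.arange(m + 1, dtype=np.int32)
    cand = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(qarr == rarr[i - 1], MATCH, MISMATCH).astype(np.int32)
        cand[0] = GAP_PENALTY * i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP_PENALTY, out=cand[1:])
        H[i] = np.maximum.accumulate(cand + shift) - shift

    # traceback, diagonal > up (deletion) > left (insertion)
    i, j = n, m
    a_ref: list[str] = []
    a_cln: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            MATCH if ref[i - 1] == qry[j - 1] else MISMATCH
        ):
            a_ref.append(ref[i - 1])
            a_cln.append(qry[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + GAP_PENALTY:
            a_ref.append(ref[i - 1])
            a_cln.append(GAP)
            i -= 1
        else:
            a_ref.append(GAP)
            a_cln.append(qry[j - 1])
            j -= 1
    aligned_ref = "".join(reversed(a_ref))
    aligned_cln = "".join(reversed(a_cln))
    return CloneAlignment(
        clone_id=clone_id,
        aligned_reference=aligned_ref,
        aligned_clone=aligned_cln,
        score=int(H[n, m]),
        mutations=_extract_mutations(aligned_ref, aligned_cln),
    )


def _extract_mutations(a_ref: str, a_cln: str) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    ref_pos = 0
    for rb, cb in zip(a_ref, a_cln):
        if rb != GAP and cb != GAP:
            if rb != cb and rb != "N" and cb != "N":
                records.append(
                    MutationRecord(
                        ref_position=ref_pos,
                        ref_base=rb,
                        clone_base=cb,
                        kind="substitution",
                        substitution_class=(
                            "transition" if (rb, cb) in _TRANSITIONS
                            else "transversion"
                        ),
                        at_cg=rb in "CG",
                    )
                )
            ref_pos += 1
        elif cb == GAP:
            records.append(
                MutationRecord(
                    ref_position=ref_pos,
                    ref_base=rb,
                    clone_base=GAP,
                    kind="deletion",
                    at_cg=rb in "CG",
                )
            )
            ref_pos += 1
        else:
            records.append(
                MutationRecord(
                    ref_position=max(0, ref_pos - 1),
                    ref_base=GAP,
                    clone_base=cb,
                    kind="insertion",
                )
            )
    return records


# ---------------------------------------------------------------------------
# summaries


def mutation_summary(
    alignments: Sequence[CloneAlignment],
    reference: str,
    mode: str = "cg_bases",
) -> MutationSummary:
    """Pool mutation statistics across clones.

    ``total_cg_bases`` counts the reference's C/G positions once per clone,
    minus positions deleted in that clone (an unsequenced base cannot be
    scored); ``total_bases_sequenced`` does the same over all positions.
    Both frequency denominators are always reported; ``mode`` selects the
    headline one ("cg_bases" or "all_bases").
    """
    if not alignments:
        raise MutationError("need at least one alignment")
    if mode not in ("cg_bases", "all_bases"):
        raise MutationError(f"unknown mode {mode!r}")
    ref = reference.upper()
    ref_cg = sum(1 for b in ref if b in "CG")
    hotspots = hotspot_positions(ref)

    total_bases = 0
    total_cg = 0
    n_cg_mut = 0
    n_cg_hot = 0
    spectrum: Counter[str] = Counter()
    for aln in alignments:
        deleted = aln.deleted_ref_positions
        deleted_cg = sum(1 for p in deleted if ref[p] in "CG")
        total_bases += len(ref) - len(deleted)
        total_cg += ref_cg - deleted_cg
        for rec in aln.mutations:
            if rec.kind != "substitution":
                continue
            spectrum[f"{rec.ref_base}>{rec.clone_base}"] += 1
            if rec.at_cg:
                n_cg_mut += 1
                if rec.ref_position in hotspots:
                    n_cg_hot += 1

    return MutationSummary(
        n_clones=len(alignments),
        total_bases_sequenced=total_bases,
        total_cg_bases=total_cg,
        n_cg_mutations=n_cg_mut,
        freq_cg_denominator=n_cg_mut / total_cg if total_cg else 0.0,
        freq_all_denominator=n_cg_mut / total_bases if total_bases else 0.0,
        spectrum=dict(spectrum),
        hotspot_fraction=n_cg_hot / n_cg_mut if n_cg_mut else 0.0,
        mode=mode,
    )


def spectrum_and_hotspots(
    alignments: Sequence[CloneAlignment], reference: str
) -> tuple[dict[str, int], float]:
    """Substitution spectrum and hotspot-context fraction of C/G mutations."""
    summary = mutation_summary(alignments, reference)
    return summary.spectrum, summary.hotspot_fraction


def align_clones(
    reference: str, clones: Sequence[str]
) -> list[CloneAlignment]:
    """Align a batch of clones, ids clone0001..cloneN."""
    return [
        align_clone(reference, c, clone_id=f"clone{i + 1:04d}")
        for i, c in enumerate(clones)
    ]
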