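"""Consensus motif discovery, CU-richness, and RGYW/WRCY hotspot scanning.

The deamination hotspot motifs are the degenerate 4-mers RGYW and WRCY
(R = purine, Y = pyrimidine, W = A/T); WRCY is the reverse complement of
RGYW, so scanning one strand finds both orientations of the same site.

Consensus discovery replaces an external motif suite with a seeded
expectation-maximisation finder: the best k-mer seed against a
dinucleotide-shuffled background initialises a PWM which is refined under a
one-occurrence-per-sequence model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_CLASSES = {
    "RGYW": ("AG", "G", "CT", "AT"),
    "WRCY": ("AT", "AG", "C", "CT"),
}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    motif_class: str


@dataclass
class PWM:
    """Column-stochastic position weight matrix over A/C/G/T."""

    probs: np.ndarray  # shape (width, 4)
    pseudocount: float

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self, alphabet: str = "RNA") -> str:
        letters = "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))
        return letters.replace("T", "U") if alphabet == "RNA" else letters


@dataclass
class ConsensusResult:
    consensus: str
    pwm: PWM
    enrichment: float  # log2 seed count ratio vs shuffled background
    n_sequences: int
    significant: bool
    seed: str


# ---------------------------------------------------------------------------
# hotspot scanning


def scan_hotspots(sequence: str) -> list[MotifHit]:
    """All RGYW/WRCY matches in ``sequence`` (N never matches).

    A 4-mer can satisfy both patterns (e.g. AGCT); it is then reported
    twice, once per class. Hits are sorted by position then class.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for pos in range(len(seq) - 3):
        window = seq[pos : pos + 4]
        for cls in ("RGYW", "WRCY"):
            if all(b in allowed for b, allowed in zip(window, _CLASSES[cls])):
                hits.append(MotifHit(position=pos, strand="+", motif_class=cls))
    return hits


def hotspot_positions(sequence: str) -> set[int]:
    """Reference positions covered by any RGYW/WRCY window."""
    covered: set[int] = set()
    for hit in scan_hotspots(sequence):
        covered.update(range(hit.position, hit.position + 4))
    return covered


def cu_content(sequence: str, window: int) -> float:
    """Maximum C+U(T) fraction over all windows of the given size."""
    seq = sequence.upper().replace("U", "T")
    if window <= 0 or window > len(seq):
        raise MotifError("window must be in [1, len(sequence)]")
    is_cu = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_cu = ((is_cu == ord("C")) | (is_cu == ord("T"))).astype(int)
    sums = np.convolve(is_cu, np.ones(window, dtype=int), mode="valid")
    return float(sums.max() / window)


# ---------------------------------------------------------------------------
# consensus discovery


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set(_ALPHABET):
        raise MotifError("sequences must be over A/C/G/U/T")
    return np.array([_INDEX[b] for b in seq], dtype=np.int8)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide counts (Altschul-Erikson style).

    Builds the multigraph of base transitions, draws a random last-edge
    tree to guarantee an Eulerian walk, and shuffles the remaining edges.
    """
    s = seq.upper().replace("U", "T")
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    # choose the final edge out of each vertex so the walk can terminate
    for _ in range(100):
        finals: dict[str, str] = {}
        ok = True
        for v, outs in edges.items():
            if v == last:
                continue
            finals[v] = outs[int(rng.integers(len(outs)))]
        # connectivity check: following final edges from v must reach `last`
        for v in edges:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last and cur in finals and cur not in seen:
                seen.add(cur)
                cur = finals[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - fallback for pathological composition
        return s
    pools = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in finals:
            rest.remove(finals[v])
        rng.shuffle(rest)
        pools[v] = rest
    out = [s[0]]
    cur = s[0]
    for _ in range(len(s) - 1):
        if pools.get(cur):
            nxt = pools[cur].pop()
        elif cur in finals:
            nxt = finals.pop(cur)
        else:  # pragma: no cover - defensive; Eulerian walk should complete
            return s
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _kmer_counts(encoded: list[np.ndarray], k: int) -> np.ndarray:
    """Occurrence counts (all positions) of every k-mer, base-4 indexed."""
    counts = np.zeros(4**k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for arr in encoded:
        if arr.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), k)
        counts += np.bincount(windows @ weights, minlength=4**k)
    return counts


def _kmer_string(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(out))


def discover_consensus(
    sequences: Sequence[str],
    k: int = 7,
    iterations: int = 10,
    shuffle_seed: int = 101,
    pseudocount: float = 0.1,
    min_fold: float = 3.0,
    min_frac: float = 0.05,
    alphabet: str = "RNA",
) -> ConsensusResult:
    """Seeded-EM consensus discovery on a set of bound sequences.

    1. the k-mer with the highest foreground count relative to a
       dinucleotide-shuffled background is the seed;
    2. a PWM is initialised from exact seed occurrences (pseudocount 0.1);
    3. ``iterations`` EM rounds refine it under a one-occurrence-per-
       sequence model with a uniform background;
    4. the consensus is the column argmax.

    The result is flagged non-significant when the seed is supported by
    fewer than ``min_frac`` of sequences or by less than ``min_fold`` of
    its shuffled-background count.
    """
    if len(sequences) < 20:
        raise MotifError("need at least 20 sequences")
    if min(len(s) for s in sequences) < k:
        raise MotifError("k exceeds the shortest sequence")
    encoded = [_encode(s) for s in sequences]
    rng = np.random.default_rng(shuffle_seed)
    shuffled = [_encode(dinucleotide_shuffle(s, rng)) for s in sequences]

    fg = _kmer_counts(encoded, k)
    bg = _kmer_counts(shuffled, k)
    ratio = (fg + 1) / (bg + 1)
    best = np.flatnonzero(ratio == ratio.max())
    seed_idx = int(best[np.argmax(fg[best])])  # ratio ties: most-supported seed
    seed = _kmer_string(seed_idx, k)
    fg_n, bg_n = int(fg[seed_idx]), int(bg[seed_idx])
    enrichment = float(np.log2((fg_n + 1) / (bg_n + 1)))
    # a pure repeat is invariant under dinucleotide shuffling, so a seed
    # supported once per sequence is significant regardless of background
    significant = fg_n >= max(min_frac * len(sequences), 3) and (
        fg_n >= min_fold * bg_n or fg_n >= len(sequences)
    )

    # PWM from seed occurrences
    counts = np.full((k, 4), pseudocount)
    seed_arr = _encode(seed)
    for arr in encoded:
        if arr.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        for w in windows[(windows == seed_arr).all(axis=1)]:
            counts[np.arange(k), w] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)

    pwm, loglik = _em_refine(encoded, pwm, iterations, pseudocount)
    # phase-shift move: a repeat motif can converge one column out of
    # phase; the in-phase PWM has every column informative, so it wins
    # on the one-occurrence-per-sequence likelihood
    for shift in (-2, -1, 1, 2):
        shifted = np.roll(pwm, shift, axis=0)
        if shift > 0:
            shifted[:shift] = 0.25
        else:
            shifted[shift:] = 0.25
        cand, cand_ll = _em_refine(encoded, shifted, min(iterations, 3), pseudocount)
        if cand_ll > loglik + 1e-9:
            pwm, loglik = cand, cand_ll

    result_pwm = PWM(probs=pwm, pseudocount=pseudocount)
    return ConsensusResult(
        consensus=result_pwm.consensus(alphabet),
        pwm=result_pwm,
        enrichment=enrichment,
        n_sequences=len(sequences),
        significant=significant,
        seed=seed.replace("T", "U") if alphabet == "RNA" else seed,
    )


def _em_refine(
    encoded: list[np.ndarray],
    pwm: np.ndarray,
    iterations: int,
    pseudocount: float,
) -> tuple[np.ndarray, float]:
    """EM under a one-occurrence-per-sequence model with uniform background.

    Returns the refined PWM and the model log-likelihood (sum over
    sequences of the log mean window likelihood ratio vs background).
    """
    k = pwm.shape[0]
    loglik = -np.inf
    for _ in range(iterations):
        counts = np.full((k, 4), pseudocount)
        log_pwm = np.log(pwm) - np.log(0.25)  # likelihood ratio vs uniform bg
        loglik = 0.0
        for arr in encoded:
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            scores = log_pwm[np.arange(k), windows].sum(axis=1)
            m = scores.max()
            expd = np.exp(scores - m)
            total = expd.sum()
            loglik += m + np.log(total / scores.size)
            post = expd / total
            np.add.at(counts, (np.arange(k)[None, :], windows), post[:, None])
        pwm = counts / counts.sum(axis=1, keepdims=True)
    return pwm, float(loglik)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (used to score consensus recovery)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
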