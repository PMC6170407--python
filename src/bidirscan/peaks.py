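"""Zero-truncated negative-binomial (ZTNB) peak calling over fixed bins.

Nonzero crosslink bin counts are modelled as a negative binomial truncated
at zero:

    f(k) = NB(k; mu, size) / (1 - NB(0; mu, size)),   k >= 1

with mean ``mu`` and dispersion ``size`` (NB "r"); size -> infinity is the
(zero-truncated) Poisson limit. Parameters are fit by maximum likelihood on
the nonzero bins of each strand; a bin's p-value is the conditional upper
tail P(X >= count | X >= 1). Strands are processed independently, and
Benjamini-Hochberg correction over each strand's nonzero bins is optional.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .tracks import StrandedTrack


class PeakError(ValueError):
    pass


MIN_FIT_BINS = 30
_LOG_SIZE_MAX = math.log(1e6)  # beyond this the fit is Poisson in practice


@dataclass
class ZTNBParams:
    mu: float
    size: float
    loglik: float
    n_bins_fit: int
    degenerate: bool = False


@dataclass(frozen=True)
class PeakCall:
    contig: str
    start: int
    end: int
    strand: str
    count: int
    p_value: float
    q_value: float | None = None


# ---------------------------------------------------------------------------
# model primitives


def _nb_logpmf(k: np.ndarray, mu: float, size: float) -> np.ndarray:
    p = size / (size + mu)
    return stats.nbinom.logpmf(k, size, p)


def _log_p0(mu: float, size: float) -> float:
    # log NB(0) = size * log(size / (size + mu))
    return size * (math.log(size) - math.log(size + mu))


def ztnb_logpmf(k: np.ndarray | int, mu: float, size: float) -> np.ndarray:
    """Log-pmf of the zero-truncated NB for k >= 1."""
    k = np.asarray(k)
    if np.any(k < 1):
        raise PeakError("ZTNB support starts at k = 1")
    log_trunc = np.log1p(-math.exp(_log_p0(mu, size)))
    return _nb_logpmf(k, mu, size) - log_trunc


def _neg_loglik(theta: np.ndarray, values: np.ndarray, freqs: np.ndarray) -> float:
    mu, size = np.exp(theta)
    log_trunc = np.log1p(-np.exp(_log_p0(mu, size)))
    ll = freqs @ (_nb_logpmf(values, mu, size) - log_trunc)
    return -float(ll)


def fit_ztnb(nonzero_counts: Sequence[int] | np.ndarray) -> ZTNBParams:
    """Maximum-likelihood (mu, size) for the ZTNB on positive counts.

    Optimises over (log mu, log size) with Nelder-Mead from a
    method-of-moments start, falling back to a fixed log-spaced grid search
    if the optimiser fails to improve. All-equal counts give a degenerate
    fit (size pinned at the Poisson-limit boundary) flagged on the result.
    """
    counts = np.asarray(nonzero_counts, dtype=np.int64)
    if counts.size == 0:
        raise PeakError("empty input")
    if np.any(counts < 1):
        raise PeakError("counts must be positive (zero-truncated model)")
    if counts.size < MIN_FIT_BINS:
        raise PeakError(f"need >= {MIN_FIT_BINS} nonzero bins, got {counts.size}")

    values, freqs = np.unique(counts, return_counts=True)
    freqs = freqs.astype(float)

    if values.size == 1:
        # no dispersion information: Poisson-limit boundary fit
        mu = _truncated_poisson_mle(float(values[0]))
        size = math.exp(_LOG_SIZE_MAX)
        ll = -_neg_loglik(np.log([mu, size]), values, freqs)
        return ZTNBParams(mu=mu, size=size, loglik=ll, n_bins_fit=int(counts.size),
                          degenerate=True)

    m = float(np.average(values, weights=freqs))
    v = float(np.average((values - m) ** 2, weights=freqs))
    mu0 = max(m - 1e-3, 1e-3)  # truncation inflates the mean; crude start
    size0 = mu0**2 / (v - mu0) if v > mu0 else 50.0
    size0 = min(max(size0, 1e-2), 1e4)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            _neg_loglik,
            x0=np.log([mu0, size0]),
            args=(values, freqs),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
    best_theta, best_nll = res.x, float(res.fun)

    if not res.success or not np.isfinite(best_nll):
        best_theta, best_nll = _grid_mle(values, freqs)

    mu, size = np.exp(best_theta)
    size = min(size, math.exp(_LOG_SIZE_MAX))
    return ZTNBParams(
        mu=float(mu),
        size=float(size),
        loglik=-best_nll,
        n_bins_fit=int(counts.size),
        degenerate=bool(np.log(size) >= _LOG_SIZE_MAX - 1e-9),
    )


def _grid_mle(values: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic log-spaced grid fallback for the ZTNB MLE."""
    m = float(np.average(values, weights=freqs))
    mus = np.log(np.geomspace(max(m / 20, 1e-3), m * 5, 60))
    sizes = np.log(np.geomspace(1e-2, 1e5, 60))
    best = (None, np.inf)
    for lm in mus:
        for ls in sizes:
            nll = _neg_loglik(np.array([lm, ls]), values, freqs)
            if nll < best[1]:
                best = (np.array([lm, ls]), nll)
    return best


def _truncated_poisson_mle(mean_obs: float) -> float:
    """MLE of lambda for a zero-truncated Poisson with observed mean."""
    if mean_obs <= 1.0:
        return 1e-6
    f = lambda lam: lam / (1 - math.exp(-lam)) - mean_obs
    return float(optimize.brentq(f, 1e-9, mean_obs + 10))


def ztnb_tail_p(count: int, params: ZTNBParams) -> float:
    """Conditional upper tail P(X >= count | X >= 1) under the fitted ZTNB."""
    if count < 1:
        raise PeakError("count must be >= 1")
    if count == 1:
        return 1.0
    p = params.size / (params.size + params.mu)
    # P(X >= count) = sf(count - 1); stable via the regularised beta function
    log_sf = np.log(special.betainc(count, params.size, 1.0 - p))
    log_trunc = np.log1p(-math.exp(_log_p0(params.mu, params.size)))
    return float(min(1.0, math.exp(log_sf - log_trunc)))


def _tail_p_vector(counts: np.ndarray, params: ZTNBParams) -> np.ndarray:
    p = params.size / (params.size + params.mu)
    sf = special.betainc(counts.astype(float), params.size, 1.0 - p)
    trunc = -np.expm1(_log_p0(params.mu, params.size))
    out = np.minimum(1.0, sf / trunc)
    out[counts == 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# peak calling


def call_peaks(
    track: StrandedTrack,
    bin_size: int = 20,
    p_threshold: float = 1e-5,
    correct: bool = False,
    merge: bool = False,
) -> list[PeakCall]:
    """Call enriched bins per strand under the ZTNB background model.

    Strands are fit and thresholded independently. With ``correct=True``
    the threshold applies to Benjamini-Hochberg q-values over each strand's
    nonzero bins. ``merge=True`` fuses runs of adjacent significant bins on
    the same strand into single calls (keeping the best p and summed count).
    A strand with fewer than 30 nonzero bins is skipped with a warning.
    """
    if bin_size != track.bin_size:
        raise PeakError(
            f"track binned at {track.bin_size} bp; rebuild it at {bin_size} bp"
        )
    calls: list[PeakCall] = []
    for strand in "+-":
        per_contig = track.counts(strand)
        nonzero = [
            (contig, np.flatnonzero(arr)) for contig, arr in per_contig.items()
        ]
        all_counts = np.concatenate(
            [per_contig[c][idx] for c, idx in nonzero]
        ) if nonzero else np.array([], dtype=np.int64)
        if all_counts.size < MIN_FIT_BINS:
            warnings.warn(
                f"strand {strand}: only {all_counts.size} nonzero bins; skipped"
            )
            continue
        params = fit_ztnb(all_counts)
        pvals = _tail_p_vector(all_counts, params)
        if correct:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            sig = qvals < p_threshold
        else:
            qvals = np.full_like(pvals, np.nan)
            sig = pvals < p_threshold
        offset = 0
        for contig, idx in nonzero:
            n = idx.size
            for j in np.flatnonzero(sig[offset : offset + n]):
                b = int(idx[j])
                calls.append(
                    PeakCall(
                        contig=contig,
                        start=b * bin_size,
                        end=min((b + 1) * bin_size, track.contig_lengths[contig]),
                        strand=strand,
                        count=int(per_contig[contig][b]),
                        p_value=float(pvals[offset + j]),
                        q_value=float(qvals[offset + j]) if correct else None,
                    )
                )
            offset += n
    calls.sort(key=lambda c: (c.contig, c.start, c.strand))
    if merge:
        calls = _merge_adjacent(calls, bin_size)
    return calls


def _merge_adjacent(calls: list[PeakCall], bin_size: int) -> list[PeakCall]:
    merged: list[PeakCall] = []
    by_key: dict[tuple[str, str], list[PeakCall]] = {}
    for c in calls:
        by_key.setdefault((c.contig, c.strand), []).append(c)
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.start)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start == cur.end:
                cur = PeakCall(
                    contig=contig,
                    start=cur.start,
                    end=nxt.end,
                    strand=strand,
                    count=cur.count + nxt.count,
                    p_value=min(cur.p_value, nxt.p_value),
                    q_value=(
                        min(cur.q_value, nxt.q_value)
                        if cur.q_value is not None and nxt.q_value is not None
                        else None
                    ),
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda c: (c.contig, c.start, c.strand))
    return merged


def sample_ztnb(
    n: int, mu: float, size: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n variates from the ZTNB by rejection of zeros."""
    p = size / (size + mu)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.negative_binomial(size, p, size=2 * (n - filled) + 16)
        draw = draw[draw >= 1]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out
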