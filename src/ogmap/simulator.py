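"""Monte-Carlo validation of the closed-form error probability.

Fragments of ``n`` bins are sampled bin-aligned at random offsets of the
binned genome, their occurrence counts are passed through the detection
channel, and an exhaustive maximum-likelihood decoder scores every valid
offset of every record in both orientations:

    i_hat = argmax_i sum_j ln p_{y|x}( y_j | x_{i+j} )

A trial counts as an error when the decoded (record, orientation, start)
differs from the truth by more than ``margin_bins`` (default 0: exact
position).  Error rates over repeated trials are reported with a Wilson
95% confidence interval.

The reverse orientation is realised by reversing each record's bin-count
vector: since pattern sets are closed under reverse complement, strand
reversal permutes bin counts up to a sub-bin boundary offset.

Decoding uses an FFT cross-correlation over the count-value indicators,
which is algebraically identical to the naive double loop: the score of
offset i decomposes as sum_b corr(ln p(y=b | x_.), 1[y_j = b]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve
from statsmodels.stats.proportion import proportion_confint

from .channel import ChannelModel
from .genome_io import BinnedGenome, GenomeSet, PatternSet, bin_genome
from .theory import TheoryResult, error_probability

__all__ = [
    "Fragment",
    "ErrorRateEstimate",
    "sample_fragment",
    "emit_labels",
    "ml_decode",
    "simulate_error_rate",
    "confidence_interval",
]

LIKELIHOOD_FLOOR = 1e-12
# scores closer than this are one mathematical tie (see _decode_batch)
SCORE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class Fragment:
    """A simulated fragment: true placement plus channel input/output counts."""

    record_id: str
    start_bin: int
    n: int
    orientation: Literal["forward", "reverse"]
    x_vec: np.ndarray
    y_vec: np.ndarray | None = None


@dataclass(frozen=True)
class ErrorRateEstimate:
    errors: int
    trials: int
    rate: float
    ci95: tuple[float, float]
    theory: TheoryResult | None = None


def sample_fragment(
    binned: BinnedGenome, n: int, rng: np.random.Generator
) -> Fragment:
    """Uniform fragment over all valid bin-aligned placements.

    The record is chosen with probability proportional to its number of
    valid start bins (bins - n + 1); the start bin is uniform among them.
    """
    valid = np.array([max(0, c.size - n + 1) for c in binned.counts], dtype=np.int64)
    total = valid.sum()
    if total == 0:
        raise ValueError(f"no record has >= {n} bins")
    flat = int(rng.integers(0, total))
    rec = int(np.searchsorted(np.cumsum(valid), flat, side="right"))
    start = flat - int(np.cumsum(valid)[rec] - valid[rec])
    x = binned.counts[rec][start : start + n].copy()
    return Fragment(
        record_id=binned.record_ids[rec],
        start_bin=start,
        n=n,
        orientation="forward",
        x_vec=x,
    )


def emit_labels(
    x_vec: np.ndarray, model: ChannelModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw each y_j independently from row x_j of the detection likelihood."""
    x = np.asarray(x_vec, dtype=np.int64)
    if x.size and (x.min() < 0 or x.max() > model.cap):
        raise ValueError(f"x values outside [0, {model.cap}]")
    cdf = np.cumsum(model.p_y_given_x, axis=1)
    u = rng.random(x.size)
    # per-element inverse-CDF draw from the row selected by x
    y = (u[:, None] > cdf[x]).sum(axis=1)
    return np.minimum(y, model.cap).astype(np.int64)


def _log_likelihood(model: ChannelModel, floor: float | None) -> np.ndarray:
    pyx = model.p_y_given_x
    if floor is not None:
        pyx = np.maximum(pyx, floor)
    if np.any(pyx <= 0):
        raise ValueError(
            "detection likelihood has zero cells; pass a floor to decode"
        )
    return np.log(pyx)


def _batch_scores(
    x_codes: np.ndarray, Y: np.ndarray, loglik: np.ndarray
) -> np.ndarray:
    """Scores of every offset for every fragment: (trials, bins - n + 1).

    score[t, i] = sum_j loglik[x_{i+j}, y_{t,j}], computed as a sum over
    count values b of the correlation of loglik[x_., b] with 1[y_{t,.}=b].
    """
    n = Y.shape[1]
    n_off = x_codes.size - n + 1
    if n_off < 1:
        return np.empty((Y.shape[0], 0))
    out = np.zeros((Y.shape[0], n_off))
    # The exact sliding-window matmul keeps equal-content windows bit-equal
    # (deterministic ties); FFT is reserved for very large problems where
    # exact ties are measure-zero and O(N n) per trial would dominate.
    use_fft = x_codes.size * n * Y.shape[0] > 4e9
    for b in range(loglik.shape[1]):
        a = loglik[x_codes, b]
        yb = (Y == b).astype(float)
        if not yb.any():
            continue
        if use_fft:
            # correlation via convolution with the reversed kernel
            out += fftconvolve(a[None, :], yb[:, ::-1], mode="valid", axes=1)
        else:
            windows = np.lib.stride_tricks.sliding_window_view(a, n)
            out += yb @ windows.T
    return out


def _decode_batch(
    Y: np.ndarray, binned: BinnedGenome, model: ChannelModel, floor: float | None
) -> list[tuple[str, int, str, float]]:
    """Exhaustive ML decode of a batch of label-count vectors.

    Ties are broken deterministically: first record in input order, forward
    before reverse, smallest start bin.  Two offsets are tied when their
    scores agree within SCORE_TIE_TOL; exact float equality would make
    mathematical ties (same likelihood terms summed in a different order)
    depend on rounding order.
    """
    loglik = _log_likelihood(model, floor)
    n = Y.shape[1]
    blocks: list[np.ndarray] = []
    keys: list[tuple[str, str]] = []
    for rec_id, x in zip(binned.record_ids, binned.counts):
        if x.size < n:
            continue
        blocks.append(_batch_scores(x, Y, loglik))
        keys.append((rec_id, "forward"))
        blocks.append(_batch_scores(x[::-1], Y, loglik))
        keys.append((rec_id, "reverse"))
    if not blocks:
        raise ValueError(f"no record has >= {n} bins")
    widths = [b.shape[1] for b in blocks]
    scores = np.concatenate(blocks, axis=1)
    quantised = np.rint(scores / SCORE_TIE_TOL).astype(np.int64)
    best = np.argmax(quantised, axis=1)  # first max wins: the tie-break order
    bounds = np.cumsum([0] + widths)
    results = []
    for t, flat in enumerate(best):
        blk = int(np.searchsorted(bounds, flat, side="right")) - 1
        rec_id, orient = keys[blk]
        results.append((rec_id, int(flat - bounds[blk]), orient, float(scores[t, flat])))
    return results


def ml_decode(
    y_vec: np.ndarray,
    binned: BinnedGenome,
    model: ChannelModel,
    floor: float | None = None,
) -> tuple[str, int, str, float]:
    """ML placement of one label-count vector over all offsets/orientations.

    Returns (record_id, start_bin, orientation, score); a reverse-orientation
    start bin is the offset in the reversed bin-count vector.  Scores use
    natural-log likelihoods; zero likelihood cells raise unless a ``floor``
    (e.g. 1e-12, for channels estimated from sparse data) is given.
    """
    Y = np.asarray(y_vec, dtype=np.int64)[None, :]
    return _decode_batch(Y, binned, model, floor)[0]


def confidence_interval(errors: int, trials: int) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial rate, clipped to [0, 1]."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= errors <= trials:
        raise ValueError("errors must be in [0, trials]")
    lo, hi = proportion_confint(errors, trials, alpha=0.05, method="wilson")
    # the Wilson bound is exactly 0 (1) at a 0% (100%) rate; undo rounding
    lo = 0.0 if errors == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if errors == trials else float(np.clip(hi, 0.0, 1.0))
    return (lo, hi)


def simulate_error_rate(
    genomes: GenomeSet | BinnedGenome,
    pattern: PatternSet | str | None,
    model: ChannelModel,
    fragment_length_bp: int,
    bin_size: int = 1000,
    trials: int = 512,
    margin_bins: int = 0,
    seed: int = 0,
    floor: float | None = None,
    with_theory: bool = True,
) -> ErrorRateEstimate:
    """Empirical mapping error rate of the ML decoder with a 95% CI.

    Each trial samples a forward fragment, emits label counts through the
    channel, and decodes; success requires the decoded record and
    orientation to match and |decoded start - true start| <= margin_bins.
    A single integer seed determines the full experiment; trial t uses the
    stream seeded by (seed, t).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if isinstance(genomes, BinnedGenome):
        binned = genomes
    else:
        if pattern is None:
            raise ValueError("pattern required when passing raw sequences")
        pset = PatternSet.from_string(pattern) if isinstance(pattern, str) else pattern
        binned = bin_genome(genomes, pset, bin_size=bin_size, cap=model.cap)
    n = fragment_length_bp // binned.bin_size
    if n < 1:
        raise ValueError("fragment shorter than one bin")
    frags = []
    Y = np.empty((trials, n), dtype=np.int64)
    for t in range(trials):
        rng = np.random.default_rng([seed, t])
        f = sample_fragment(binned, n, rng)
        Y[t] = emit_labels(f.x_vec, model, rng)
        frags.append(f)
    decoded = _decode_batch(Y, binned, model, floor)
    errors = 0
    for f, (rec, start, orient, _) in zip(frags, decoded):
        ok = (
            rec == f.record_id
            and orient == f.orientation
            and abs(start - f.start_bin) <= margin_bins
        )
        errors += not ok
    theory = (
        error_probability(model, binned, fragment_length_bp, binned.bin_size)
        if with_theory
        else None
    )
    return ErrorRateEstimate(
        errors=errors,
        trials=trials,
        rate=errors / trials,
        ci95=confidence_interval(errors, trials),
        theory=theory,
    )
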