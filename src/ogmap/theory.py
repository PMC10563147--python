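"""Closed-form mapping error probability via finite-blocklength analysis.

A DNA fragment of ``n`` bins is a codeword transmitted over the per-bin
detection channel; the candidate messages are all ``M = 2G/B`` position
offsets of the binned target genome (factor 2 for the unknown strand
orientation).  The normal approximation for a random code over a discrete
memoryless channel gives the maximum-likelihood mapping error probability

    epsilon = Phi( (ln M - n I - (1/2) ln n) / sqrt(n V) ),

where I and V are the mean and variance of the per-bin log-likelihood
ratio r(x, y) = ln[ p_xy(x, y) / (p_x(x) p_y(y)) ] under the joint
distribution — the channel's per-bin information content and dispersion.

All logarithms are natural; epsilon is invariant to the base as long as it
is used consistently in M, I, the (1/2) log n term and V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .channel import ChannelModel, marginal_py
from .genome_io import BinnedGenome, GenomeSet

__all__ = [
    "LogRatioTable",
    "TheoryResult",
    "log_ratio_table",
    "information_stats",
    "codebook_size",
    "error_probability",
    "error_probability_from_stats",
]


@dataclass(frozen=True)
class LogRatioTable:
    """Per-cell log-likelihood ratio r(x, y) and the joint p_xy."""

    r: np.ndarray
    joint: np.ndarray


@dataclass(frozen=True)
class TheoryResult:
    """One (genome, pattern, fragment-length) error-probability prediction.

    ``I`` [nats/bin], ``V`` [nats^2/bin], ``n`` bins per fragment, real
    codebook size ``M``, ``epsilon`` in [0, 1] and its log (``log_epsilon``,
    natural log, finite even when epsilon underflows).  ``degenerate`` is
    set when the channel carries no information (I = 0), where mapping is
    at chance and epsilon is reported as the limit 1.
    """

    I: float
    V: float
    n: int
    M: float
    epsilon: float
    log_epsilon: float
    degenerate: bool = False


def log_ratio_table(model: ChannelModel) -> LogRatioTable:
    """r(x,y) = ln[p_xy / (p_x p_y)]; cells with zero joint mass carry r = 0.

    Zero-probability cells contribute nothing to any moment of r, so the
    value stored there is a convention only.
    """
    joint = model.p_x[:, None] * model.p_y_given_x
    py = marginal_py(model)
    denom = model.p_x[:, None] * py[None, :]
    r = np.zeros_like(joint)
    nz = joint > 0
    r[nz] = np.log(joint[nz] / denom[nz])
    return LogRatioTable(r=r, joint=joint)


def information_stats(model: ChannelModel) -> tuple[float, float]:
    """Mutual information I = E[r] and dispersion V = Var[r] in nats."""
    t = log_ratio_table(model)
    I = float(np.sum(t.joint * t.r))
    V = float(np.sum(t.joint * (t.r - I) ** 2))
    # clamp tiny negative rounding residue on degenerate channels
    return max(I, 0.0), max(V, 0.0)


def codebook_size(
    genomes: GenomeSet | BinnedGenome,
    bin_size: int | None = None,
    n: int | None = None,
    exact_offsets: bool = False,
) -> float:
    """Number of candidate messages M = 2 * (whole genome bins).

    This is the 2G/B codebook up to partial-bin truncation.  With
    ``exact_offsets=True`` the exact count of valid fragment placements,
    ``2 * sum_k max(0, bins_k - n + 1)``, is returned instead (requires
    ``n``); the two differ by at most 2(n-1) per record and epsilon depends
    on M only logarithmically.
    """
    if isinstance(genomes, BinnedGenome):
        per_record = [c.size for c in genomes.counts]
    else:
        if bin_size is None:
            raise ValueError("bin_size required for a GenomeSet")
        per_record = [len(seq) // bin_size for _, seq in genomes.records]
    total = sum(per_record)
    if total < 1:
        raise ValueError("genome shorter than one bin")
    if exact_offsets:
        if n is None:
            raise ValueError("exact_offsets requires the fragment bin count n")
        return 2.0 * sum(max(0, b - n + 1) for b in per_record)
    return 2.0 * total


def error_probability_from_stats(
    I: float, V: float, n: int, M: float
) -> TheoryResult:
    """Evaluate the normal approximation from precomputed (I, V, n, M)."""
    if n < 1:
        raise ValueError("fragment must span at least one bin")
    if M < 2:
        raise ValueError("codebook has fewer than 2 messages")
    if I <= 1e-14:
        # numerically zero information per bin: decoding is at chance
        return TheoryResult(
            I=I, V=V, n=n, M=M, epsilon=1.0, log_epsilon=0.0, degenerate=True
        )
    num = np.log(M) - n * I - 0.5 * np.log(n)
    if V <= 0.0:
        eps = 1.0 if num > 0 else (0.5 if num == 0 else 0.0)
        log_eps = 0.0 if num > 0 else (np.log(0.5) if num == 0 else -np.inf)
        return TheoryResult(I=I, V=V, n=n, M=M, epsilon=eps, log_epsilon=log_eps)
    z = num / np.sqrt(n * V)
    return TheoryResult(
        I=I,
        V=V,
        n=n,
        M=M,
        epsilon=float(norm.cdf(z)),
        log_epsilon=float(norm.logcdf(z)),
    )


def error_probability(
    model: ChannelModel,
    genomes: GenomeSet | BinnedGenome,
    fragment_length_bp: int,
    bin_size: int = 1000,
    exact_offsets: bool = False,
) -> TheoryResult:
    """Closed-form mapping error probability for fragments of L bp.

    ``n = floor(L / B)`` bins per fragment; I and V come from the channel
    model; M from the genome size (see :func:`codebook_size`).
    """
    if isinstance(genomes, BinnedGenome):
        bin_size = genomes.bin_size
    n = fragment_length_bp // bin_size
    if n < 1:
        raise ValueError("fragment shorter than one bin")
    I, V = information_stats(model)
    M = codebook_size(genomes, bin_size=bin_size, n=n, exact_offsets=exact_offsets)
    return error_probability_from_stats(I, V, n, M)
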