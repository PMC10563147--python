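"""Exhaustive labeling-pattern design for a target genome set.

For a fixed detection likelihood (a property of the labeling chemistry and
imaging system, assumed shared across candidate patterns), the mapping
error probability of a pattern depends on the genome only through the
pattern-density distribution p_x.  Scanning therefore re-estimates p_x per
pattern from the target genome, holds p_{y|x} fixed, and evaluates the
closed-form error probability for each candidate — all 4^k words of length
k, or IUPAC-coded enzyme recognition sequences expanded to concrete word
sets.  Every pattern is matched jointly with its reverse complement.

Error probability is U-shaped in pattern density: sparse patterns put too
few labels on a fragment to place it, dense ones saturate the capped
per-bin counts and push the channel into its noisiest rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channel import ChannelModel
from .genome_io import (
    GenomeSet,
    PatternSet,
    _encode,
    _kmer_codes,
    _pattern_codes,
    bin_counts,
    reverse_complement,
)
from .theory import codebook_size, error_probability_from_stats, information_stats
from . import simulator as _sim

__all__ = [
    "PatternScanRow",
    "PatternScanTable",
    "enumerate_patterns",
    "expand_iupac",
    "pattern_density",
    "scan_patterns",
    "write_scan_csv",
    "read_scan_csv",
]

# 15-letter IUPAC nucleotide alphabet
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PatternScanRow:
    pattern: str
    density: float  # union occurrences per bp
    epsilon_theory: float
    degenerate: bool = False
    epsilon_sim: float | None = None
    sim_ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class PatternScanTable:
    rows: tuple[PatternScanRow, ...]
    genome_label: str
    fragment_length_bp: int
    bin_size: int
    channel_id: str = "custom"

    def __post_init__(self):
        pats = [r.pattern for r in self.rows]
        if len(pats) != len(set(pats)):
            raise ValueError("duplicate pattern rows in scan table")

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "pattern": [r.pattern for r in self.rows],
            "density": [r.density for r in self.rows],
            "p_err": [r.epsilon_theory for r in self.rows],
        }
        if any(r.epsilon_sim is not None for r in self.rows):
            d["p_err_sim"] = [
                np.nan if r.epsilon_sim is None else r.epsilon_sim for r in self.rows
            ]
            d["sim_ci_lo"] = [
                np.nan if r.sim_ci95 is None else r.sim_ci95[0] for r in self.rows
            ]
            d["sim_ci_hi"] = [
                np.nan if r.sim_ci95 is None else r.sim_ci95[1] for r in self.rows
            ]
        return pd.DataFrame(d)


def enumerate_patterns(k: int) -> list[str]:
    """All 4^k words over {A,C,G,T} of length k, lexicographic."""
    if not 1 <= k <= 12:
        raise ValueError("k must be in [1, 12]")
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def expand_iupac(code: str) -> PatternSet:
    """Concrete pattern set of an IUPAC-coded recognition sequence.

    All letter-by-letter expansions, unioned with their reverse complements.
    """
    code = code.upper()
    try:
        choices = [IUPAC[c] for c in code]
    except KeyError as e:
        raise ValueError(f"illegal IUPAC character {e.args[0]!r} in {code!r}") from None
    expansions = {"".join(p) for p in itertools.product(*choices)}
    closed = expansions | {reverse_complement(p) for p in expansions}
    return PatternSet(label=code, patterns=frozenset(closed))


def pattern_density(genomes: GenomeSet, patterns: PatternSet) -> float:
    """Union occurrence count across records divided by total length G."""
    g = genomes.total_length
    if g == 0:
        raise ValueError("empty genome")
    from .genome_io import find_occurrences

    total = sum(
        find_occurrences(seq, patterns).size for _, seq in genomes.records
    )
    return total / g


def _scan_one(
    kcode_cache: list[tuple[np.ndarray, np.ndarray, int]],
    pset: PatternSet,
    model: ChannelModel,
    bin_size: int,
) -> tuple[float, np.ndarray, int]:
    """Density, capped-count histogram and whole-bin count for one pattern."""
    targets = _pattern_codes(pset.patterns)
    hist = np.zeros(model.cap + 1, dtype=np.int64)
    occ = 0
    glen = 0
    for kcodes, ok, seq_len in kcode_cache:
        glen += seq_len
        hit = ok & np.isin(kcodes, targets)
        pos = np.flatnonzero(hit)
        occ += pos.size
        hist += np.bincount(
            bin_counts(pos, seq_len, bin_size, model.cap), minlength=model.cap + 1
        )
    return occ / glen, hist, int(hist.sum())


def scan_patterns(
    genomes: GenomeSet,
    model: ChannelModel,
    fragment_length_bp: int,
    bin_size: int,
    patterns: Sequence[str],
    simulate_subset: Sequence[str] | int | None = None,
    trials: int = 512,
    seed: int = 0,
    genome_label: str = "genome",
) -> PatternScanTable:
    """Rank candidate labeling patterns by predicted mapping error.

    For each pattern (IUPAC codes allowed) the genome is binned, p_x is
    re-estimated, and the closed-form error probability is evaluated with
    the shared detection likelihood.  Patterns absent from the genome (or
    any channel with I = 0) are degenerate: mapping is at chance and the
    error probability is reported as 1 with a flag.  Rows are sorted by
    theoretical error probability ascending.

    ``simulate_subset`` optionally runs the Monte-Carlo decoder for a list
    of patterns (or a seeded random subset of the given size).
    """
    if not patterns:
        raise ValueError("no patterns to scan")
    n = fragment_length_bp // bin_size
    if n < 1:
        raise ValueError("fragment shorter than one bin")
    psets = [expand_iupac(p) for p in patterns]
    # k-mer codes per record are shared across patterns of the same length
    cache_by_k: dict[int, list[tuple[np.ndarray, np.ndarray, int]]] = {}
    enc = [(_encode(seq), len(seq)) for _, seq in genomes.records]
    M = codebook_size(genomes, bin_size=bin_size)

    if isinstance(simulate_subset, int):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(patterns), size=min(simulate_subset, len(patterns)), replace=False)
        sim_labels = {psets[i].label for i in idx}
    elif simulate_subset is not None:
        sim_labels = {p.upper() for p in simulate_subset}
    else:
        sim_labels = set()

    rows = []
    for pset in psets:
        k = pset.k
        if k not in cache_by_k:
            cache_by_k[k] = [
                (*_kmer_codes(codes, k), seq_len) for codes, seq_len in enc
            ]
        density, hist, nbins = _scan_one(cache_by_k[k], pset, model, bin_size)
        if nbins == 0:
            raise ValueError("genome shorter than one bin")
        px = hist / nbins
        pat_model = model.with_px(px)
        I, V = information_stats(pat_model)
        res = error_probability_from_stats(I, V, n, M)
        eps_sim = ci = None
        if pset.label in sim_labels and not res.degenerate:
            est = _sim.simulate_error_rate(
                genomes,
                pset,
                pat_model,
                fragment_length_bp,
                bin_size=bin_size,
                trials=trials,
                seed=seed,
                with_theory=False,
            )
            eps_sim, ci = est.rate, est.ci95
        rows.append(
            PatternScanRow(
                pattern=pset.label,
                density=density,
                epsilon_theory=res.epsilon,
                degenerate=res.degenerate,
                epsilon_sim=eps_sim,
                sim_ci95=ci,
            )
        )
    rows.sort(key=lambda r: (r.epsilon_theory, r.pattern))
    return PatternScanTable(
        rows=tuple(rows),
        genome_label=genome_label,
        fragment_length_bp=fragment_length_bp,
        bin_size=bin_size,
    )


def write_scan_csv(table: PatternScanTable, path: str | Path) -> None:
    """CSV with header ``pattern,density,p_err`` (+ sim columns if present).

    Floats are written at full repr precision so a re-read round-trips
    bit-exactly.
    """
    if not table.rows:
        raise ValueError("empty scan table")
    # shortest round-trip repr so a re-read returns bit-identical floats
    table.to_dataframe().to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def read_scan_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
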