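"""Genome sequences, labeling-pattern matching and binning.

Optical genome mapping (OGM) images DNA fragments carrying fluorescent
labels at occurrences of a short recognition sequence (the *labeling
pattern*, typically 6 bp).  The model in this package works on a binned
representation of the genome: each record is cut into non-overlapping bins
of ``B`` bp (default 1 kb) and the number of pattern occurrences in each
bin, capped at a small maximum (default 2), is the per-bin channel input
symbol ``x``.

Because the strand orientation of an imaged fragment is unknown, a pattern
is always matched jointly with its reverse complement: a :class:`PatternSet`
is closed under reverse complement and occurrence positions are the union
over all members.

Coordinates are 0-based; an occurrence belongs to the bin containing its
start coordinate.  Trailing partial bins are dropped so all bins have equal
size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSet",
    "PatternSet",
    "BinnedGenome",
    "read_fasta",
    "generate_random_genome",
    "reverse_complement",
    "find_occurrences",
    "bin_counts",
    "bin_genome",
    "write_bed",
]

DEFAULT_BIN_SIZE = 1000
DEFAULT_CAP = 2

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# A=0, C=1, G=2, T=3, N=4 byte-code lookup for vectorised matching
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSet:
    """Named DNA sequences over {A,C,G,T,N}; ``total_length`` is G in bp."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for rec_id, seq in self.records:
            bad = set(seq) - _ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c not in _ALPHABET)
                raise ValueError(
                    f"record {rec_id!r}: illegal character {seq[pos]!r} at position {pos}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PatternSet:
    """A labeling pattern: a reverse-complement-closed set of equal-length words.

    ``label`` is the user-facing name (possibly IUPAC-coded); ``patterns``
    are the concrete {A,C,G,T} words matched in the genome.
    """

    label: str
    patterns: frozenset[str]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("empty pattern set")
        lengths = {len(p) for p in self.patterns}
        if len(lengths) != 1:
            raise ValueError(f"patterns have unequal lengths: {sorted(lengths)}")
        for p in self.patterns:
            if set(p) - set("ACGT"):
                raise ValueError(f"pattern {p!r} has characters outside ACGT")
            if reverse_complement(p) not in self.patterns:
                raise ValueError(
                    f"pattern set not closed under reverse complement: {p!r}"
                )

    @classmethod
    def from_string(cls, pattern: str) -> "PatternSet":
        """Build the set {pattern, reverse_complement(pattern)}."""
        p = pattern.upper()
        return cls(label=p, patterns=frozenset({p, reverse_complement(p)}))

    @property
    def k(self) -> int:
        return len(next(iter(self.patterns)))

    @property
    def is_palindromic(self) -> bool:
        return len(self.patterns) == 1 and all(
            p == reverse_complement(p) for p in self.patterns
        )


@dataclass(frozen=True)
class BinnedGenome:
    """Per-record vectors of capped pattern-occurrence counts.

    ``counts[i][j]`` is min(cap, occurrences starting in bin ``j`` of record
    ``i``); vector length is ``floor(record_length / bin_size)``.
    """

    record_ids: tuple[str, ...]
    counts: tuple[np.ndarray, ...]
    bin_size: int
    cap: int

    def __post_init__(self):
        for c in self.counts:
            if c.size and (c.min() < 0 or c.max() > self.cap):
                raise ValueError("bin counts outside [0, cap]")

    @property
    def n_bins(self) -> int:
        return int(sum(c.size for c in self.counts))

    def all_counts(self) -> np.ndarray:
        if not self.counts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.counts)


def read_fasta(path: str | Path) -> GenomeSet:
    """Read a (multi-record) FASTA file; lower-case is normalised to upper."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSet(records=tuple(records))


def generate_random_genome(
    length_bp: int, seed: int, record_id: str = "random"
) -> GenomeSet:
    """Single record of i.i.d. uniform letters from {A,C,G,T}.

    Deterministic in (length_bp, seed).  Lengths up to 1e8 bp are supported;
    the sequence is materialised as one Python string (~1 byte/bp).
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length_bp, dtype=np.uint8)
    seq = _DECODE[codes].tobytes().decode("ascii")
    return GenomeSet(records=((record_id, seq),))


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"illegal character {seq[pos]!r} at position {pos}")
    return arr


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all k-windows and a validity mask (False where any N)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        c = codes[i : i + n]
        ok &= c < 4
        out = out * 4 + (c & 3)
    return out, ok


def _pattern_codes(patterns: Iterable[str]) -> np.ndarray:
    vals = []
    for p in patterns:
        v = 0
        for ch in p:
            v = v * 4 + int(_CODE[ord(ch)])
        vals.append(v)
    return np.unique(np.asarray(vals, dtype=np.int64))


def find_occurrences(seq: str, patterns: PatternSet) -> np.ndarray:
    """0-based start positions of every exact match to any pattern-set member.

    Overlapping matches are all reported; windows containing N never match.
    Sorted ascending, duplicates removed (a palindromic member and its
    reverse complement are the same word, hence the same position).
    """
    codes = _encode(seq)
    kcodes, ok = _kmer_codes(codes, patterns.k)
    targets = _pattern_codes(patterns.patterns)
    hit = ok & np.isin(kcodes, targets)
    return np.flatnonzero(hit).astype(np.int64)


def bin_counts(
    positions: Sequence[int] | np.ndarray,
    seq_length_bp: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    cap: int = DEFAULT_CAP,
) -> np.ndarray:
    """Capped per-bin occurrence counts from sorted start positions.

    Entry ``j`` is ``min(cap, #{p : floor(p / bin_size) == j})``; positions in
    the dropped trailing partial bin are discarded.
    """
    if bin_size < 1 or cap < 1:
        raise ValueError("bin_size and cap must be >= 1")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size:
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted ascending")
        if pos[0] < 0 or pos[-1] >= seq_length_bp:
            raise ValueError("positions out of range [0, seq_length)")
    n_bins = seq_length_bp // bin_size
    kept = pos[pos < n_bins * bin_size]
    counts = np.bincount(kept // bin_size, minlength=n_bins)
    return np.minimum(counts, cap).astype(np.int64)


def bin_genome(
    genomes: GenomeSet,
    patterns: PatternSet,
    bin_size: int = DEFAULT_BIN_SIZE,
    cap: int = DEFAULT_CAP,
) -> BinnedGenome:
    """Locate pattern occurrences in every record and bin the counts."""
    ids, vecs = [], []
    for rec_id, seq in genomes.records:
        pos = find_occurrences(seq, patterns)
        ids.append(rec_id)
        vecs.append(bin_counts(pos, len(seq), bin_size, cap))
    return BinnedGenome(
        record_ids=tuple(ids), counts=tuple(vecs), bin_size=bin_size, cap=cap
    )


def write_bed(
    path: str | Path, record_id: str, positions: np.ndarray, k: int
) -> None:
    """Dump occurrence positions as BED3 (0-based, half-open) for debugging."""
    with open(path, "w") as fh:
        for p in positions:
            fh.write(f"{record_id}\t{int(p)}\t{int(p) + k}\n")
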