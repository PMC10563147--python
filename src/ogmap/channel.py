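"""The per-bin discrete memoryless channel of label detection.

The OGM measurement of one bin is modelled as a noisy channel taking the
number of pattern occurrences in a genome bin, ``x``, to the number of
labels detected in the corresponding image bin, ``y`` (both capped, default
at 2).  The channel has two free parameters:

* ``p_x`` — the pattern-density distribution: the histogram of capped
  per-bin occurrence counts over the target genome;
* ``p_y_given_x`` — the label-detection likelihood: a row-stochastic
  matrix absorbing labeling efficiency, off-target labeling and imaging
  noise, estimated from aligned (x, y) bin pairs of real measurements.

:func:`default_table1` ships the published estimates for the CTTAAG
(DLE-1) pattern on the human genome at 1-kb bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genome_io import BinnedGenome

__all__ = [
    "ChannelModel",
    "default_table1",
    "estimate_px",
    "estimate_pyx",
    "marginal_py",
    "read_xy_pairs",
]

_TOL = 1e-6


@dataclass(frozen=True)
class ChannelModel:
    """Pattern-density distribution p_x and detection likelihood p_{y|x}.

    Rows of ``p_y_given_x`` are indexed by x in {0..cap}, columns by y in
    {0..cap}.  ``p_x`` sums to 1 and every row of ``p_y_given_x`` sums to 1
    (within 1e-6).
    """

    cap: int
    p_x: np.ndarray
    p_y_given_x: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.p_x, dtype=float)
        pyx = np.asarray(self.p_y_given_x, dtype=float)
        object.__setattr__(self, "p_x", px)
        object.__setattr__(self, "p_y_given_x", pyx)
        m = self.cap + 1
        if px.shape != (m,) or pyx.shape != (m, m):
            raise ValueError(f"expected shapes ({m},) and ({m},{m})")
        if np.any(px < 0) or np.any(pyx < 0):
            raise ValueError("negative probabilities")
        if abs(px.sum() - 1.0) > _TOL:
            raise ValueError(f"p_x sums to {px.sum()}, not 1")
        rows = pyx.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _TOL):
            raise ValueError(f"p_y_given_x row sums {rows} not all 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cap": int(self.cap),
            "p_x": [float(v) for v in self.p_x],
            "p_y_given_x": [[float(v) for v in row] for row in self.p_y_given_x],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelModel":
        return cls(
            cap=int(d["cap"]),
            p_x=np.asarray(d["p_x"], dtype=float),
            p_y_given_x=np.asarray(d["p_y_given_x"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        """Write as YAML (or JSON if the suffix is .json); exact round-trip."""
        path = Path(path)
        d = self.to_dict()
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(d, fh, indent=1)
            else:
                yaml.safe_dump(d, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ChannelModel":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)

    def with_px(self, p_x: np.ndarray) -> "ChannelModel":
        """Same detection likelihood, different pattern-density distribution."""
        return ChannelModel(cap=self.cap, p_x=p_x, p_y_given_x=self.p_y_given_x)


# Published channel estimates: CTTAAG (DLE-1) on human hg38, B = 1 kb,
# counts capped at 2; likelihood from 445 aligned fragments (180 Mb).
_TABLE1_PX = (0.81555, 0.16278, 0.02168)
_TABLE1_PYX = (
    (0.95961, 0.03847, 0.00192),
    (0.18716, 0.67492, 0.13792),
    (0.13109, 0.35978, 0.50913),
)


def default_table1() -> ChannelModel:
    """The published human-genome CTTAAG channel (cap 2, 1-kb bins)."""
    px = np.asarray(_TABLE1_PX)
    pyx = np.asarray(_TABLE1_PYX)
    # printed values round to 5 decimals; renormalise the ~1e-5 residue
    return ChannelModel(cap=2, p_x=px / px.sum(), p_y_given_x=pyx / pyx.sum(axis=1, keepdims=True))


def estimate_px(binned: BinnedGenome) -> np.ndarray:
    """Empirical frequency of each capped count over all bins of all records."""
    counts = binned.all_counts()
    if counts.size == 0:
        raise ValueError("BinnedGenome has no bins")
    hist = np.bincount(counts, minlength=binned.cap + 1)
    return hist / hist.sum()


def estimate_pyx(
    pairs: Sequence[tuple[int, int]] | np.ndarray,
    cap: int = 2,
    strict: bool = True,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Row-normalised 2D histogram of aligned (x, y) bin pairs.

    Both coordinates must already be capped.  Rows of x values with no
    observations are an error in strict mode; otherwise they are returned
    as NaN with a warning — never silently imputed.  ``pseudocount`` is
    added to every cell before normalisation (default 0: raw histogram).
    """
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("no (x, y) pairs")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    if arr.min() < 0 or arr.max() > cap:
        raise ValueError(f"pair values outside [0, {cap}]")
    m = cap + 1
    hist = np.zeros((m, m), dtype=float)
    np.add.at(hist, (arr[:, 0], arr[:, 1]), 1.0)
    hist += pseudocount
    row_sums = hist.sum(axis=1)
    missing = np.flatnonzero(row_sums == 0)
    if missing.size:
        if strict:
            raise ValueError(
                f"no observations for x values {missing.tolist()}; "
                "pass strict=False or a pseudocount"
            )
        warnings.warn(
            f"likelihood rows for x values {missing.tolist()} are unobserved "
            "and returned as NaN",
            stacklevel=2,
        )
    out = np.full((m, m), np.nan)
    obs = row_sums > 0
    out[obs] = hist[obs] / row_sums[obs, None]
    return out


def marginal_py(model: ChannelModel) -> np.ndarray:
    """p_y(y) = sum_x p_x(x) p_{y|x}(y|x)."""
    return model.p_x @ model.p_y_given_x


def read_xy_pairs(path: str | Path) -> np.ndarray:
    """Read aligned bin pairs from a TSV with header line ``x<TAB>y``."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if [h.strip() for h in header] != ["x", "y"]:
            raise ValueError(f"expected header 'x\\ty', got {header}")
        rows = [line.split() for line in fh if line.strip()]
    return np.asarray([[int(a), int(b)] for a, b in rows], dtype=np.int64)
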