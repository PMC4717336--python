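"""Pairwise Jukes-Cantor distance matrices and min-max normalization.

The JC correction maps an observed mismatch proportion ``p`` to the
expected number of substitutions per site, ``d = -(3/4) ln(1 - 4p/3)``.
Min-max normalization linearly rescales the off-diagonal distances of a
matrix onto a target interval (default [0.00, 0.03]) so that datasets with
different realized ranges can be compared on a common scale; the mapping
is strictly monotone, so the ordering of distances is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError, SaturationError
from .seqsim import Alignment

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "jc_correct",
    "pairwise_matrix",
    "minmax_normalize",
    "write_csv",
    "read_csv",
    "write_phylip",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal.

    ``scale_tag`` is ``"jc_raw"`` for plain JC distances or
    ``"normalized"`` after min-max rescaling, in which case ``norm_params``
    records ``(source_min, source_max, new_min, new_max)``.
    """

    values: np.ndarray
    labels: list[str]
    scale_tag: str = "jc_raw"
    norm_params: tuple[float, float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InvalidArgumentError("diagonal must be zero")
        if np.any(v < -1e-15):
            raise InvalidArgumentError("distances must be nonnegative")
        self.values = v
        if len(self.labels) != v.shape[0]:
            raise InvalidArgumentError("one label per row required")
        if self.scale_tag not in ("jc_raw", "normalized"):
            raise InvalidArgumentError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """The n(n-1)/2 unordered off-diagonal values (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=np.int64)
        return self.values[np.ix_(idx, idx)]


def p_distance(a: str, b: str) -> float:
    """Proportion of sites at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise InvalidArgumentError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise InvalidArgumentError("empty sequences")
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return float(np.mean(arr_a != arr_b))


def jc_correct(p) -> np.ndarray | float:
    """Jukes-Cantor distance correction, ``d = -(3/4) ln(1 - 4p/3)``.

    Defined for ``0 <= p < 0.75``; monotone increasing and >= p.
    """
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr < 0) or np.any(p_arr >= 0.75):
        bad = p_arr[(p_arr < 0) | (p_arr >= 0.75)]
        raise SaturationError(
            f"mismatch proportion outside [0, 0.75): {np.atleast_1d(bad)[0]:.6g}"
        )
    d = -0.75 * np.log1p(-4.0 * p_arr / 3.0)
    return float(d) if np.isscalar(p) or p_arr.ndim == 0 else d


def pairwise_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs JC distance matrix for an alignment (n >= 2)."""
    if aln.n < 2:
        raise InvalidArgumentError("need at least 2 sequences")
    codes = aln.codes
    n, L = codes.shape
    p = np.zeros((n, n))
    for i in range(n - 1):
        p[i, i + 1 :] = np.count_nonzero(codes[i + 1 :] != codes[i], axis=1) / L
    p = p + p.T
    sat = np.argwhere(np.triu(p, k=1) >= 0.75)
    if sat.size:
        i, j = sat[0]
        raise SaturationError(
            f"pair ({aln.labels[i]}, {aln.labels[j]}) is JC-saturated (p={p[i, j]:.4f})"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(aln.labels), scale_tag="jc_raw")


def minmax_normalize(
    m: DistanceMatrix, new_min: float = 0.0, new_max: float = 0.03
) -> DistanceMatrix:
    """Min-max normalize the off-diagonal distances onto [new_min, new_max].

    Each off-diagonal ``d`` maps to
    ``(d - min)/(max - min) * (new_max - new_min) + new_min`` where min and
    max are taken over the off-diagonal entries only (the zero diagonal is
    excluded so the smallest *pairwise* distance defines the source
    minimum).  The diagonal stays zero.
    """
    if new_max <= new_min:
        raise InvalidArgumentError("new_max must exceed new_min")
    off = m.offdiag()
    lo, hi = float(off.min()), float(off.max())
    if hi <= lo:
        raise DegenerateInputError(
            "all pairwise distances are equal; min-max normalization is undefined"
        )
    scaled = (m.values - lo) / (hi - lo) * (new_max - new_min) + new_min
    np.fill_diagonal(scaled, 0.0)
    return DistanceMatrix(
        scaled,
        list(m.labels),
        scale_tag="normalized",
        norm_params=(lo, hi, float(new_min), float(new_max)),
    )


# -- interchange -----------------------------------------------------------


def write_csv(m: DistanceMatrix, path) -> None:
    """Square-matrix CSV with labels on the first row and column."""
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.to_csv(path, float_format="%.12g")


def read_csv(path, scale_tag: str = "jc_raw") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], scale_tag=scale_tag)


def write_phylip(m: DistanceMatrix, path) -> None:
    """PHYLIP square distance-matrix export."""
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label.ljust(10) + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
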