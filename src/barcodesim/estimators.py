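"""The four polymorphism estimators.

* nucleotide diversity (pi): mean of all pairwise distances in a sample;
* maximum pairwise distance;
* haplotype count: number of distinct sequences;
* mismatch distribution: histogram of pairwise distances plus a Gaussian
  kernel density estimate (Silverman's rule-of-thumb bandwidth), with a
  report of empty-bin runs ("gaps") and a simple modality count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .distances import DistanceMatrix
from .errors import InvalidArgumentError
from .seqsim import Alignment

__all__ = [
    "MismatchSummary",
    "DiversitySummary",
    "nucleotide_diversity",
    "max_pairwise",
    "count_haplotypes",
    "mismatch_histogram",
    "gap_report",
    "count_modes",
]

DEFAULT_BIN_WIDTH = 0.001
DEFAULT_RANGE = (0.0, 0.03)
KDE_GRID_POINTS = 512


@dataclass
class MismatchSummary:
    """Histogram + kernel density estimate of a set of pairwise distances."""

    bin_edges: np.ndarray
    counts: np.ndarray
    kde_grid: np.ndarray
    kde_density: np.ndarray
    n_values: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per histogram bin and per KDE grid point."""
        nbins = len(self.counts)
        npts = len(self.kde_grid)
        rows = max(nbins, npts)

        def pad(a, fill=np.nan):
            out = np.full(rows, fill, dtype=float)
            out[: len(a)] = a
            return out

        return pd.DataFrame(
            {
                "bin_left": pad(self.bin_edges[:-1]),
                "bin_right": pad(self.bin_edges[1:]),
                "count": pad(self.counts),
                "grid": pad(self.kde_grid),
                "density": pad(self.kde_density),
            }
        )


@dataclass
class DiversitySummary:
    """Full-dataset nucleotide diversity (beta) and pairwise-distance variance."""

    beta: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise InvalidArgumentError("variance cannot be negative")

    @classmethod
    def from_matrix(cls, m: DistanceMatrix) -> "DiversitySummary":
        off = m.offdiag()
        return cls(beta=float(off.mean()), sigma2=float(off.var()))


def _check_subset(m: DistanceMatrix, subset, min_size: int = 2) -> np.ndarray:
    idx = np.asarray(list(subset), dtype=np.int64)
    if idx.size < min_size:
        raise InvalidArgumentError(f"subset must have at least {min_size} members")
    if len(np.unique(idx)) != idx.size:
        raise InvalidArgumentError("subset indices must be distinct")
    if idx.min() < 0 or idx.max() >= m.n:
        raise InvalidArgumentError("subset index out of range")
    return idx


def nucleotide_diversity(m: DistanceMatrix, subset=None) -> float:
    """Mean of the k = s(s-1)/2 pairwise distances among subset members.

    With ``subset=None`` the full matrix is used, giving the full-dataset
    diversity beta.
    """
    if subset is None:
        subset = range(m.n)
    idx = _check_subset(m, subset)
    sub = m.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def max_pairwise(m: DistanceMatrix, subset=None) -> float:
    """Maximum pairwise distance among subset members."""
    if subset is None:
        subset = range(m.n)
    idx = _check_subset(m, subset)
    sub = m.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].max())


def count_haplotypes(aln: Alignment, subset=None) -> int:
    """Number of distinct sequences among subset members (exact identity)."""
    if subset is None:
        subset = range(aln.n)
    idx = np.asarray(list(subset), dtype=np.int64)
    if idx.size < 1:
        raise InvalidArgumentError("subset must be nonempty")
    rows = aln.codes[idx]
    return int(np.unique(rows, axis=0).shape[0])


def mismatch_histogram(
    values,
    bin_width: float = DEFAULT_BIN_WIDTH,
    value_range: tuple[float, float] = DEFAULT_RANGE,
) -> MismatchSummary:
    """Histogram + Gaussian KDE of pairwise distances.

    Bins are half-open ``[edge, edge + width)`` over ``value_range`` with
    the last bin closed (numpy's convention).  The KDE uses Silverman's
    rule-of-thumb bandwidth on a 512-point grid extended past the data
    range so the density integrates to ~1; for degenerate inputs (a single
    value, or zero spread) the KDE is a narrow Gaussian bump at that value.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InvalidArgumentError("empty value list")
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    lo, hi = value_range
    nbins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)

    spread = vals.std()
    if vals.size > 1 and spread > 0:
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        bw = np.sqrt(kde.covariance[0, 0])
        grid = np.linspace(vals.min() - 4 * bw, vals.max() + 4 * bw, KDE_GRID_POINTS)
        density = kde(grid)
    else:
        # all values identical: represent the point mass as a narrow bump
        center = float(vals[0])
        bw = bin_width / 4.0
        grid = np.linspace(center - 6 * bw, center + 6 * bw, KDE_GRID_POINTS)
        density = stats.norm.pdf(grid, loc=center, scale=bw)

    return MismatchSummary(
        bin_edges=edges,
        counts=counts,
        kde_grid=grid,
        kde_density=density,
        n_values=int(vals.size),
    )


def gap_report(
    values,
    bin_width: float = DEFAULT_BIN_WIDTH,
    value_range: tuple[float, float] = DEFAULT_RANGE,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive empty interior bins, as (start, end) edges.

    Interior means between the first and last occupied bin; leading and
    trailing empty bins are not gaps, they are simply outside the realized
    range of distances.  Exception: a single occupied bin reports its
    flanking empty runs (within ``value_range``) so a point mass is visibly
    isolated.
    """
    summ = mismatch_histogram(values, bin_width=bin_width, value_range=value_range)
    counts = summ.counts
    edges = summ.bin_edges
    occupied = np.flatnonzero(counts > 0)
    if occupied.size == 0:
        return []
    first, last = occupied[0], occupied[-1]
    if occupied.size == 1:
        runs = []
        if first > 0:
            runs.append((float(edges[0]), float(edges[first])))
        if last < len(counts) - 1:
            runs.append((float(edges[last + 1]), float(edges[-1])))
        return runs
    runs = []
    in_run = False
    start = 0
    for b in range(first + 1, last):
        if counts[b] == 0 and not in_run:
            in_run, start = True, b
        elif counts[b] > 0 and in_run:
            runs.append((float(edges[start]), float(edges[b])))
            in_run = False
    if in_run:
        runs.append((float(edges[start]), float(edges[last])))
    return runs


def count_modes(summ: MismatchSummary, rel_height: float = 0.01) -> int:
    """Number of local maxima of the KDE curve.

    Maxima below ``rel_height`` times the global peak are suppressed as
    numerical noise.
    """
    y = summ.kde_density
    peaks, _ = signal.find_peaks(y)
    threshold = rel_height * y.max()
    interior = [p for p in peaks if y[p] >= threshold]
    # endpoints can be maxima too when the density is truncated
    n = len(interior)
    if y[0] > y[1] and y[0] >= threshold:
        n += 1
    if y[-1] > y[-2] and y[-1] >= threshold:
        n += 1
    return n
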