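"""Subsampling engine and its summaries.

A :class:`SubsampleSchedule` names an estimator, a grid of sample sizes and
a replicate count; :func:`run_schedule` executes it on a dataset, drawing
uniform subsamples *without replacement* (specimens are not duplicated
within a sample).  Downstream summaries cover the study's analyses:

* band summaries — per size, the percentage of subsample diversities
  within ``beta ± 0.001`` of the full-dataset diversity;
* central-limit diagnostics — per-size mean/variance/skewness of subsample
  diversities, since the mean of k pairwise distances is expected to be
  approximately normal around beta for large k;
* five-number summaries for haplotype-count boxplots;
* a Michaelis-Menten saturation fit, F(x) = a*x / (1 + b*x), to the median
  haplotype count as a function of sample size (asymptote a/b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import derive_rng
from .distances import DistanceMatrix
from .errors import ConfigurationError, FitFailureError, InvalidArgumentError
from .estimators import count_haplotypes, max_pairwise, nucleotide_diversity
from .seqsim import Alignment

__all__ = [
    "ESTIMATOR_NAMES",
    "SubsampleSchedule",
    "ResampleResult",
    "BandSummary",
    "MMFit",
    "draw_subsample",
    "run_schedule",
    "enumerate_exhaustive",
    "band_summary",
    "clt_diagnostics",
    "quartile_summary",
    "fit_michaelis_menten",
    "mm_slope",
]

ESTIMATOR_NAMES = ("mismatch", "diversity", "haplotypes", "maxdist")

# fixed stream offsets so each estimator's schedule is independently
# reproducible from the same root seed
_ESTIMATOR_OFFSET = {name: i for i, name in enumerate(ESTIMATOR_NAMES)}


@dataclass
class SubsampleSchedule:
    """Subsample sizes x replicates for one estimator."""

    estimator: str
    sizes: tuple[int, ...]
    replicates: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATOR_NAMES:
            raise InvalidArgumentError(f"unknown estimator {self.estimator!r}")
        sizes = tuple(int(s) for s in self.sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise InvalidArgumentError("sizes must be strictly increasing")
        min_size = 1 if self.estimator == "haplotypes" else 2
        if sizes and sizes[0] < min_size:
            raise InvalidArgumentError(f"smallest size must be >= {min_size}")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        self.sizes = sizes

    def truncated(self, n: int) -> "SubsampleSchedule":
        """Drop sizes exceeding a dataset of ``n`` sequences."""
        kept = tuple(s for s in self.sizes if s <= n)
        if not kept:
            raise InvalidArgumentError(f"no schedule sizes fit a dataset of {n}")
        return SubsampleSchedule(self.estimator, kept, self.replicates, self.seed)


@dataclass
class ResampleResult:
    """Estimator values on the full (size x replicate) grid."""

    dataset_id: str
    estimator: str
    sizes: tuple[int, ...]
    replicates: int
    values: np.ndarray  # shape (len(sizes), replicates)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sizes), self.replicates):
            raise InvalidArgumentError("values grid must be sizes x replicates")

    def for_size(self, size: int) -> np.ndarray:
        return self.values[self.sizes.index(size)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: (dataset_id, estimator, size, replicate, value)."""
        sizes = np.repeat(self.sizes, self.replicates)
        reps = np.tile(np.arange(self.replicates), len(self.sizes))
        return pd.DataFrame(
            {
                "dataset_id": self.dataset_id,
                "estimator": self.estimator,
                "size": sizes,
                "replicate": reps,
                "value": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResampleResult":
        (dataset_id,) = df["dataset_id"].unique()
        (estimator,) = df["estimator"].unique()
        sizes = tuple(int(s) for s in sorted(df["size"].unique()))
        replicates = int(df.groupby("size").size().iloc[0])
        piv = df.sort_values(["size", "replicate"])
        values = piv["value"].to_numpy().reshape(len(sizes), replicates)
        return cls(str(dataset_id), str(estimator), sizes, replicates, values)


@dataclass
class BandSummary:
    """Per-size summary of subsample diversities around the full-dataset value."""

    size: int
    mean: float
    pct_in_band: float
    band_half_width: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_in_band <= 100.0:
            raise InvalidArgumentError("pct_in_band must be a percentage")


@dataclass
class MMFit:
    """Least-squares Michaelis-Menten fit F(x) = a*x / (1 + b*x)."""

    a: float
    b: float
    residual_variance: float
    n_points: int

    def predict(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = self.a * x / (1.0 + self.b * x)
        return float(out) if out.ndim == 0 else out

    @property
    def asymptote(self) -> float:
        return self.a / self.b


def draw_subsample(n_total: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random subset of ``size`` distinct indices from ``n_total``."""
    if size > n_total:
        raise InvalidArgumentError(f"size {size} exceeds dataset size {n_total}")
    if size < 1:
        raise InvalidArgumentError("size must be >= 1")
    return rng.choice(n_total, size=size, replace=False)


def _evaluator(estimator: str, aln: Alignment | None, m: DistanceMatrix | None):
    if estimator == "haplotypes":
        if aln is None:
            raise ConfigurationError("haplotype schedule requires an alignment")
        return lambda idx: count_haplotypes(aln, idx)
    if m is None:
        raise ConfigurationError(f"{estimator} schedule requires a distance matrix")
    if estimator == "diversity":
        return lambda idx: nucleotide_diversity(m, idx)
    if estimator == "maxdist":
        return lambda idx: max_pairwise(m, idx)
    if estimator == "mismatch":
        # mismatch keeps the raw subsample distances; summarised downstream
        raise ConfigurationError("use subsample_distance_sets for the mismatch estimator")
    raise ConfigurationError(f"unknown estimator {estimator!r}")


def run_schedule(
    sched: SubsampleSchedule,
    aln: Alignment | None = None,
    m: DistanceMatrix | None = None,
    dataset_id: str = "dataset",
) -> ResampleResult:
    """Execute a scalar-valued schedule (diversity, maxdist or haplotypes).

    Each (size, replicate) cell is an independent subsample; the stream for
    a given size is derived from ``(seed, estimator offset, size)`` so any
    size can be re-run in isolation.
    """
    n_total = aln.n if aln is not None else (m.n if m is not None else 0)
    if n_total == 0:
        raise ConfigurationError("need an alignment or a distance matrix")
    if aln is not None and m is not None and aln.n != m.n:
        raise ConfigurationError("alignment and matrix disagree on n")
    if sched.sizes and sched.sizes[-1] > n_total:
        raise InvalidArgumentError("schedule contains sizes larger than the dataset")

    evaluate = _evaluator(sched.estimator, aln, m)
    dtype = np.int64 if sched.estimator == "haplotypes" else np.float64
    values = np.empty((len(sched.sizes), sched.replicates), dtype=dtype)
    for si, size in enumerate(sched.sizes):
        rng = derive_rng(sched.seed, _ESTIMATOR_OFFSET[sched.estimator], size)
        for r in range(sched.replicates):
            idx = draw_subsample(n_total, size, rng)
            values[si, r] = evaluate(idx)
    return ResampleResult(dataset_id, sched.estimator, sched.sizes, sched.replicates, values)


def subsample_distance_sets(
    m: DistanceMatrix, sizes, replicates: int, seed: int, dataset_id: str = "dataset"
) -> dict[int, list[np.ndarray]]:
    """Subsample pairwise-distance pools for mismatch-distribution analysis.

    Returns, per size, ``replicates`` arrays of the s(s-1)/2 pairwise
    distances within an independent random subsample.  Distances come from
    the (already normalized) full-dataset matrix, so no re-normalization is
    applied to the subsamples.
    """
    out: dict[int, list[np.ndarray]] = {}
    for size in sizes:
        rng = derive_rng(seed, _ESTIMATOR_OFFSET["mismatch"], size)
        pools = []
        for _ in range(replicates):
            idx = draw_subsample(m.n, size, rng)
            sub = m.submatrix(idx)
            iu = np.triu_indices(len(idx), k=1)
            pools.append(sub[iu])
        out[size] = pools
    return out


def enumerate_exhaustive(
    estimator: str,
    size: int,
    aln: Alignment | None = None,
    m: DistanceMatrix | None = None,
) -> np.ndarray:
    """Estimator value for every subset of the given size (oracle-grade).

    Only feasible for small n; used to validate the Monte-Carlo engine.
    """
    n_total = aln.n if aln is not None else m.n
    evaluate = _evaluator(estimator, aln, m)
    return np.array([evaluate(list(c)) for c in combinations(range(n_total), size)])


def band_summary(
    r: ResampleResult, beta: float, half_width: float = 0.001
) -> list[BandSummary]:
    """Per size: mean value and percentage within the closed band beta ± h."""
    if r.estimator != "diversity":
        raise ConfigurationError("band summaries are defined for diversity results")
    out = []
    for si, size in enumerate(r.sizes):
        vals = r.values[si]
        inside = np.abs(vals - beta) <= half_width
        out.append(
            BandSummary(
                size=size,
                mean=float(vals.mean()),
                pct_in_band=float(100.0 * inside.mean()),
                band_half_width=half_width,
            )
        )
    return out


def clt_diagnostics(r: ResampleResult, beta: float) -> pd.DataFrame:
    """Per-size moments of subsample diversities: mean, variance, skewness.

    Constant replicate values get variance 0, skewness reported as 0 with
    ``degenerate=True``.
    """
    rows = []
    for si, size in enumerate(r.sizes):
        vals = np.asarray(r.values[si], dtype=float)
        var = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
        degenerate = var == 0.0
        skew = 0.0 if degenerate else float(stats.skew(vals))
        rows.append(
            {
                "size": size,
                "mean": float(vals.mean()),
                "variance": var,
                "skewness": skew,
                "bias": float(vals.mean() - beta),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def quartile_summary(r: ResampleResult) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per sample size.

    Quartiles use linear interpolation; the median is the midpoint of the
    two central order statistics for even replicate counts.
    """
    rows = []
    for si, size in enumerate(r.sizes):
        vals = np.asarray(r.values[si], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "size": size,
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def fit_michaelis_menten(sizes, medians, max_nfev: int = 10000) -> MMFit:
    """Least-squares fit of F(x) = a*x / (1 + b*x) to (size, median) points.

    Starting values come from ordinary least squares on the linearization
    ``1/F = (1/a)(1/x) + b/a``; the nonlinear fit then minimizes the
    untransformed residual sum of squares.  ``residual_variance`` is
    RSS / (n_points - 2), two parameters having been fitted.
    """
    x = np.asarray(list(sizes), dtype=float)
    y = np.asarray(list(medians), dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("sizes and medians must align")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 points to fit two constants")
    if np.any(x <= 0):
        raise InvalidArgumentError("sizes must be positive")
    if np.any(y <= 0):
        raise InvalidArgumentError("medians must be positive for the MM fit")

    # linearized start: 1/F = (1/a) * (1/x) + b/a
    slope, intercept = np.polyfit(1.0 / x, 1.0 / y, 1)
    if slope <= 0:
        a0 = float(y.max())  # fall back: near-horizontal data
        b0 = max(a0 / y.max() - 1.0, 1e-6)
    else:
        a0 = 1.0 / slope
        b0 = max(intercept * a0, 1e-9)

    def f(xv, a, b):
        return a * xv / (1.0 + b * xv)

    try:
        popt, _ = optimize.curve_fit(f, x, y, p0=[a0, b0], maxfev=max_nfev)
    except RuntimeError as exc:
        raise FitFailureError(
            f"Michaelis-Menten fit failed to converge (start a={a0:.4g}, b={b0:.4g}): {exc}"
        ) from exc
    a, b = map(float, popt)
    rss = float(np.sum((y - f(x, a, b)) ** 2))
    return MMFit(a=a, b=b, residual_variance=rss / (x.size - 2), n_points=int(x.size))


def mm_slope(fit: MMFit, x: float) -> float:
    """Analytic derivative of the fitted curve: a / (1 + b*x)^2."""
    return fit.a / (1.0 + fit.b * x) ** 2
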