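"""Sequence evolution on genealogies under the Jukes-Cantor model.

Two mutation machineries live here:

* ``evolve_jc`` — finite-sites JC evolution used to produce the study's
  1,500-bp alignments.  Branch lengths must first be rescaled to expected
  substitutions per site (``rescale_branches``); the case-by-case cap on
  within-dataset divergence is enforced by ``enforce_divergence_cap``.
* ``overlay_infinite_sites`` — Poisson mutations on coalescent-scale
  branches, each hitting a unique site.  Under the neutral constant-size
  model the expected pairwise difference count equals the population
  mutation parameter theta = 4*N*mu, which makes the overlay the natural
  validation channel for the genealogy simulator.

JC evolution is exact-by-construction: rather than simulating individual
substitution events, each site flips along a branch of length ``t`` with
the closed-form probability ``p_change(t) = (3/4)(1 - exp(-4t/3))`` to a
uniformly chosen different base.  For JC the two formulations have
identical finite-dimensional distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import derive_rng
from .errors import DegenerateInputError, InvalidArgumentError, SimulationFailureError
from .genealogy import Genealogy, tree_diameter

__all__ = [
    "Alignment",
    "MutationOverlay",
    "p_change",
    "rescale_branches",
    "evolve_jc",
    "enforce_divergence_cap",
    "overlay_infinite_sites",
    "write_fasta",
    "read_fasta",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SEQ_LENGTH = 1500
DEFAULT_DIVERGENCE_CAP = 0.03
DEFAULT_THETA = 3.0


@dataclass
class Alignment:
    """Gap-free nucleotide alignment over {A, C, G, T}.

    ``codes`` stores the sequences as an ``(n, L)`` uint8 matrix of indices
    into ``ACGT``; ``sequences`` renders them as strings on demand.
    ``provenance`` records how the alignment was produced (seed, scale
    factor, source genealogy id) for the run manifest.
    """

    codes: np.ndarray
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise InvalidArgumentError("codes must be a 2-D (n, L) matrix")
        if self.codes.size and self.codes.max() > 3:
            raise InvalidArgumentError("codes must be in 0..3 (ACGT)")
        if len(self.labels) != self.codes.shape[0]:
            raise InvalidArgumentError("one label per sequence required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("labels must be unique")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def sequences(self) -> list[str]:
        return [BASES[row].tobytes().decode("ascii") for row in self.codes]

    def subset(self, indices) -> "Alignment":
        idx = np.asarray(indices, dtype=np.int64)
        return Alignment(self.codes[idx], [self.labels[i] for i in idx], dict(self.provenance))

    @classmethod
    def from_strings(cls, sequences: list[str], labels: list[str] | None = None) -> "Alignment":
        if not sequences:
            raise InvalidArgumentError("empty alignment")
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise InvalidArgumentError("sequences must have equal length")
        lookup = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lookup[b] = i
        for i, b in enumerate(b"acgt"):
            lookup[b] = i
        codes = np.vstack([lookup[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in sequences])
        if codes.max() > 3:
            raise InvalidArgumentError("sequences restricted to ACGT")
        if labels is None:
            labels = [f"t{i + 1}" for i in range(len(sequences))]
        return cls(codes, list(labels))


@dataclass
class MutationOverlay:
    """Infinite-sites mutation summary on a coalescent-scale genealogy."""

    theta: float
    pairwise_differences: np.ndarray
    segregating_sites: int

    def __post_init__(self) -> None:
        m = np.asarray(self.pairwise_differences)
        if not np.array_equal(m, m.T) or np.any(np.diag(m) != 0):
            raise InvalidArgumentError("pairwise_differences must be symmetric with zero diagonal")
        if m.size and self.segregating_sites < m.max():
            raise InvalidArgumentError("segregating sites cannot be fewer than the largest pairwise difference")

    def mean_pairwise_differences(self) -> float:
        m = self.pairwise_differences
        n = m.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(m[iu].mean())


def p_change(t) -> np.ndarray | float:
    """JC probability that a site differs across a branch of length ``t``."""
    return 0.75 * (1.0 - np.exp(-4.0 * np.asarray(t, dtype=float) / 3.0))


def rescale_branches(g: Genealogy, target_diameter: float) -> Genealogy:
    """Uniformly rescale branch lengths to a target tip-to-tip diameter.

    After rescaling, branch lengths are interpreted as expected
    substitutions per site.  Ultrametricity is preserved because the
    rescaling is a single multiplicative factor on all node ages.
    """
    if target_diameter <= 0:
        raise InvalidArgumentError("target_diameter must be positive")
    d = tree_diameter(g)
    if d <= 0:
        raise DegenerateInputError("cannot rescale a zero-diameter tree")
    s = target_diameter / d
    return g.with_ages(g.ages * s)


def evolve_jc(g: Genealogy, L: int, seed: int) -> Alignment:
    """Evolve an ``L``-site alignment down ``g`` under Jukes-Cantor.

    The root sequence is i.i.d. uniform over ACGT (the JC stationary
    distribution); each site mutates independently along each branch with
    probability ``p_change(branch length)`` to one of the three other
    bases, uniformly.  Deterministic given ``seed``.
    """
    if L < 1:
        raise InvalidArgumentError("L must be >= 1")
    bl = g.branch_lengths
    if np.any(bl < -1e-15):
        raise InvalidArgumentError("negative branch length")
    bl = np.clip(bl, 0.0, None)

    rng = derive_rng(seed)
    seqs = np.empty((g.n_nodes, L), dtype=np.uint8)
    seqs[g.root] = rng.integers(0, 4, size=L, dtype=np.uint8)

    # preorder: parents before children; internal indices descend from root
    for v in range(g.root, g.n_tips - 1, -1):
        for c in g.children[v]:
            child_seq = seqs[v].copy()
            p = p_change(bl[c])
            if p > 0:
                hit = rng.random(L) < p
                k = int(hit.sum())
                if k:
                    # uniform among the 3 other bases: add 1..3 mod 4
                    child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
            seqs[c] = child_seq

    return Alignment(
        seqs[: g.n_tips].copy(),
        list(g.tip_labels),
        provenance={"seed": int(seed), "length": int(L)},
    )


def _max_jc_distance(aln: Alignment) -> float:
    # local import to avoid a cycle: distances depends on Alignment
    from .distances import pairwise_matrix

    return float(pairwise_matrix(aln).offdiag().max())


def enforce_divergence_cap(
    g: Genealogy,
    L: int = DEFAULT_SEQ_LENGTH,
    cap: float = DEFAULT_DIVERGENCE_CAP,
    seed: int = 0,
    max_iter: int = 20,
) -> tuple[Genealogy, Alignment]:
    """Rescale-and-evolve until the realized maximum JC distance is < ``cap``.

    Starts at a target diameter of ``0.85 * cap`` (so the expected maximum
    divergence already sits below the cap), evolves sequences, and shrinks
    the tree by a factor 0.9 and re-evolves with the same seed while the
    realized maximum pairwise JC distance is at or above the cap.  Returns
    the first accepted (tree, alignment) pair.
    """
    if cap <= 0:
        raise InvalidArgumentError("cap must be positive")
    scaled = rescale_branches(g, 0.85 * cap)
    for _ in range(max_iter):
        aln = evolve_jc(scaled, L, seed)
        realized = _max_jc_distance(aln)
        if realized < cap:
            aln.provenance.update(
                scale_diameter=tree_diameter(scaled),
                realized_max_jc=realized,
            )
            return scaled, aln
        scaled = scaled.with_ages(scaled.ages * 0.9)
    raise SimulationFailureError(
        f"maximum JC distance still >= {cap} after {max_iter} shrink iterations"
    )


def overlay_infinite_sites(g: Genealogy, theta: float, seed: int) -> MutationOverlay:
    """Drop Poisson infinite-sites mutations on a coalescent-scale tree.

    Each branch of length ``t`` (in units of 2N generations) receives
    ``Poisson(theta/2 * t)`` mutations, each at a unique site, so
    ``E[pairwise differences] = theta`` for two tips and
    ``E[segregating sites] = theta * sum_{i=1}^{n-1} 1/i``.
    """
    if theta < 0:
        raise InvalidArgumentError("theta must be nonnegative")
    rng = derive_rng(seed)
    bl = g.branch_lengths
    muts = rng.poisson(0.5 * theta * bl)
    muts[g.root] = 0  # no branch above the root

    n = g.n_tips
    # tips below each node, as a boolean incidence matrix
    below = np.zeros((g.n_nodes, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for v in range(n, g.n_nodes):
        a, b = g.children[v]
        below[v] = below[a] | below[b]

    # a branch contributes its mutations to pair (i, j) iff it separates them
    diffs = np.zeros((n, n), dtype=np.int64)
    for v in range(g.n_nodes - 1):  # root excluded
        if muts[v] == 0:
            continue
        inside = below[v]
        diffs[np.ix_(inside, ~inside)] += muts[v]
    diffs = diffs + diffs.T

    return MutationOverlay(
        theta=float(theta),
        pairwise_differences=diffs,
        segregating_sites=int(muts.sum()),
    )


# -- FASTA interchange -----------------------------------------------------


def write_fasta(aln: Alignment, path) -> None:
    """Write the alignment as FASTA, wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for seq, label in zip(aln.sequences, aln.labels)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidArgumentError(f"no sequences in {path}")
    return Alignment.from_strings([str(r.seq) for r in records], [r.id for r in records])
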