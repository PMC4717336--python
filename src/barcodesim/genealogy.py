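"""Constant-size Kingman coalescent genealogies and tree-shape statistics.

Trees are rooted, binary and ultrametric.  Node indices follow the
convention of array-based phylogenetics: tips are ``0 .. n-1``, internal
nodes ``n .. 2n-2`` in coalescence order, so the root is always ``2n-2``.
Branch lengths are stored implicitly as differences of node ages.

Time is measured in units of 2N generations: with ``j`` active lineages the
waiting time to the next coalescence is exponential with rate
``j(j-1)/2``, giving the textbook closed forms ``E[TMRCA] = 2(1 - 1/n)``
and mean pairwise coalescence time 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_rng
from .errors import InvalidArgumentError

__all__ = [
    "Genealogy",
    "SplitProfile",
    "simulate_genealogy",
    "tmrca",
    "tree_diameter",
    "colless_index",
    "aldous_split_profile",
    "balanced_reference_profile",
    "to_newick",
    "from_newick",
    "write_newick",
    "read_newick",
]


@dataclass
class Genealogy:
    """A rooted binary ultrametric genealogy.

    Parameters
    ----------
    n_tips
        Number of sampled lineages (tree leaves).
    children
        ``(2n-1, 2)`` integer array; row ``v`` holds the two children of
        internal node ``v`` and ``(-1, -1)`` for tips.
    ages
        ``(2n-1,)`` float array of node ages (distance above the tips).
        Tips have age 0 in a freshly simulated tree; rescaling preserves
        relative ages.
    tip_labels
        One unique label per tip, index-aligned.
    """

    n_tips: int
    children: np.ndarray
    ages: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.children = np.asarray(self.children, dtype=np.int64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        n = self.n_tips
        if n < 2:
            raise InvalidArgumentError("a genealogy needs at least 2 tips")
        if self.children.shape != (2 * n - 1, 2):
            raise InvalidArgumentError("children array has wrong shape")
        if self.ages.shape != (2 * n - 1,):
            raise InvalidArgumentError("ages array has wrong shape")
        if len(self.tip_labels) != n or len(set(self.tip_labels)) != n:
            raise InvalidArgumentError("tip labels must be unique, one per tip")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @property
    def parent(self) -> np.ndarray:
        """Parent index per node; the root maps to -1."""
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        internal = np.arange(self.n_tips, self.n_nodes)
        par[self.children[internal, 0]] = internal
        par[self.children[internal, 1]] = internal
        return par

    def branch_length(self, v: int) -> float:
        """Length of the branch above node ``v`` (0 for the root)."""
        p = self.parent[v]
        return 0.0 if p < 0 else float(self.ages[p] - self.ages[v])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch length above each non-root node (root entry is 0)."""
        par = self.parent
        bl = np.zeros(self.n_nodes)
        nonroot = par >= 0
        bl[nonroot] = self.ages[par[nonroot]] - self.ages[nonroot]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def clade_sizes(self) -> np.ndarray:
        """Number of tips descending from each node (tips count as 1)."""
        sizes = np.zeros(self.n_nodes, dtype=np.int64)
        sizes[: self.n_tips] = 1
        # children always have lower indices than their parent
        for v in range(self.n_tips, self.n_nodes):
            a, b = self.children[v]
            sizes[v] = sizes[a] + sizes[b]
        return sizes

    def with_ages(self, ages: np.ndarray) -> "Genealogy":
        return Genealogy(self.n_tips, self.children.copy(), np.asarray(ages, dtype=float), list(self.tip_labels))


@dataclass
class SplitProfile:
    """Larger-daughter clade sizes along a root-to-tip descent.

    ``entries`` is an ordered list of ``(node_rank, larger_daughter_size)``
    with ranks starting at 1 at the root.
    """

    entries: list[tuple[int, int]] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [s for _, s in self.entries]


def simulate_genealogy(n_tips: int, seed: int) -> Genealogy:
    """Simulate a Kingman coalescent genealogy for ``n_tips`` samples.

    With ``j`` active lineages the waiting time to the next merger is
    ``Exponential(j(j-1)/2)`` in units of 2N generations, and the merging
    pair is uniform over unordered pairs.  Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise InvalidArgumentError(f"n_tips must be >= 2, got {n_tips}")
    n = int(n_tips)
    rng = derive_rng(seed)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    ages = np.zeros(2 * n - 1)

    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(1.0 / (j * (j - 1) / 2.0))
        # two draws without replacement, uniform over unordered pairs
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        children[nxt] = (a, b)
        ages[nxt] = t
        active = [x for k, x in enumerate(active) if k not in (i1, i2)]
        active.append(nxt)
        nxt += 1
    labels = [f"t{i + 1}" for i in range(n)]
    return Genealogy(n, children, ages, labels)


def tmrca(g: Genealogy) -> float:
    """Root age: the time to the most recent common ancestor of all tips."""
    return float(g.ages[g.root] - g.ages[: g.n_tips].max())


def tree_diameter(g: Genealogy) -> float:
    """Maximum tip-to-tip path length.

    Computed exactly for any rooted binary tree; for an ultrametric tree it
    equals twice the root-to-tip height, and that identity is preserved by
    uniform rescaling.
    """
    n = g.n_tips
    # min tip age below each node: path length below v to its deepest tip
    # is age[v] - min_tip_age[v]
    min_tip_age = np.full(g.n_nodes, np.inf)
    min_tip_age[:n] = g.ages[:n]
    for v in range(n, g.n_nodes):
        a, b = g.children[v]
        min_tip_age[v] = min(min_tip_age[a], min_tip_age[b])
    best = 0.0
    for v in range(n, g.n_nodes):
        a, b = g.children[v]
        cand = 2.0 * g.ages[v] - min_tip_age[a] - min_tip_age[b]
        if cand > best:
            best = cand
    return float(best)


def colless_index(g: Genealogy, normalized: bool = False) -> float:
    """Colless imbalance: sum over internal nodes of |left - right| tip counts.

    The normalized form divides by the caterpillar maximum
    ``(n-1)(n-2)/2`` and lies in [0, 1].
    """
    n = g.n_tips
    if normalized and n < 3:
        raise InvalidArgumentError("normalized Colless needs n_tips >= 3")
    sizes = g.clade_sizes()
    internal = np.arange(n, g.n_nodes)
    left = sizes[g.children[internal, 0]]
    right = sizes[g.children[internal, 1]]
    raw = float(np.abs(left - right).sum())
    if not normalized:
        return raw
    return raw / ((n - 1) * (n - 2) / 2.0)


def aldous_split_profile(g: Genealogy, k: int) -> SplitProfile:
    """Split sizes for ``k`` internal nodes descending from the root.

    At each node the size of the larger daughter clade is recorded and the
    walk continues into that daughter (first child on ties).  If a tip is
    reached before ``k`` nodes have been visited the profile is truncated
    with a warning.
    """
    if k > g.n_tips - 1:
        raise InvalidArgumentError("k cannot exceed the number of internal nodes")
    sizes = g.clade_sizes()
    entries: list[tuple[int, int]] = []
    v = g.root
    rank = 1
    while rank <= k and not g.is_tip(v):
        a, b = g.children[v]
        if sizes[a] >= sizes[b]:
            big = a
        else:
            big = b
        entries.append((rank, int(sizes[big])))
        v = big
        rank += 1
    if len(entries) < k:
        warnings.warn(
            f"descent reached a tip after {len(entries)} nodes; "
            f"profile truncated (requested {k})",
            stacklevel=2,
        )
    return SplitProfile(entries)


def balanced_reference_profile(n_tips: int, k: int) -> SplitProfile:
    """Profile of a maximally balanced topology: iterated ceil-halving.

    Serves as the reference curve against which simulated profiles are
    compared.
    """
    entries = []
    size = n_tips
    for rank in range(1, k + 1):
        size = -(-size // 2)  # ceil(size / 2)
        entries.append((rank, size))
    return SplitProfile(entries)


# -- Newick interchange ----------------------------------------------------


def to_newick(g: Genealogy, precision: int = 10) -> str:
    """Serialize as a Newick string with branch lengths in current units."""
    bl = g.branch_lengths

    def render(v: int) -> str:
        if g.is_tip(v):
            return f"{g.tip_labels[v]}:{bl[v]:.{precision}g}"
        a, b = g.children[v]
        inner = f"({render(a)},{render(b)})"
        if v == g.root:
            return inner
        return f"{inner}:{bl[v]:.{precision}g}"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * g.n_tips + 100))
    try:
        return render(g.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def from_newick(newick: str) -> Genealogy:
    """Parse a Newick string into a :class:`Genealogy`.

    The tree must be strictly binary with branch lengths; node ages are
    reconstructed from root-to-node depths (deepest tip defines age 0).
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf for lf in tree.leaf_node_iter()]
    n = len(leaves)
    if n < 2:
        raise InvalidArgumentError("tree must have at least 2 tips")

    tip_index = {id(lf): i for i, lf in enumerate(leaves)}
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    depth = np.zeros(2 * n - 1)
    labels = [lf.taxon.label if lf.taxon else f"t{i + 1}" for i, lf in enumerate(leaves)]

    next_internal = n
    index_of: dict[int, int] = {}
    # postorder guarantees children are indexed before parents
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            index_of[id(node)] = tip_index[id(node)]
        else:
            if len(kids) != 2:
                raise InvalidArgumentError("tree must be strictly binary")
            v = next_internal
            next_internal += 1
            index_of[id(node)] = v
            children[v] = (index_of[id(kids[0])], index_of[id(kids[1])])

    for node in tree.preorder_node_iter():
        v = index_of[id(node)]
        if node.parent_node is None:
            depth[v] = 0.0
        else:
            el = node.edge.length or 0.0
            depth[v] = depth[index_of[id(node.parent_node)]] + el

    root_idx = index_of[id(tree.seed_node)]
    max_depth = depth.max()
    ages = max_depth - depth
    g = Genealogy(n, children, ages, labels)
    if root_idx != g.root:
        # postorder ends at the root so this cannot happen for binary trees
        raise InvalidArgumentError("root index mismatch after parsing")
    return g


def write_newick(g: Genealogy, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(g) + "\n")


def read_newick(path) -> Genealogy:
    with open(path) as fh:
        return from_newick(fh.read())
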