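import numpy as np
import pytest

from barcodesim import distances as dist
from barcodesim import genealogy as gen
from barcodesim import seqsim as seq


def make_balanced(n_tips: int, depth: float = 1.0) -> gen.Genealogy:
    """Fully balanced ultrametric tree for a power-of-two tip count."""
    assert n_tips & (n_tips - 1) == 0, "balanced helper needs a power of two"
    children = np.full((2 * n_tips - 1, 2), -1, dtype=np.int64)
    ages = np.zeros(2 * n_tips - 1)
    level = list(range(n_tips))
    nxt = n_tips
    age = 0.0
    step = depth / int(np.log2(n_tips))
    while len(level) > 1:
        age += step
        nxt_level = []
        for a, b in zip(level[::2], level[1::2]):
            children[nxt] = (a, b)
            ages[nxt] = age
            nxt_level.append(nxt)
            nxt += 1
        level = nxt_level
    return gen.Genealogy(n_tips, children, ages, [f"t{i+1}" for i in range(n_tips)])


def make_caterpillar(n_tips: int, step: float = 0.1) -> gen.Genealogy:
    """Maximally imbalanced ultrametric tree (each split peels one tip)."""
    children = np.full((2 * n_tips - 1, 2), -1, dtype=np.int64)
    ages = np.zeros(2 * n_tips - 1)
    spine = 0
    for k in range(1, n_tips):
        v = n_tips - 1 + k
        children[v] = (spine, k)
        ages[v] = k * step
        spine = v
    return gen.Genealogy(n_tips, children, ages, [f"t{i+1}" for i in range(n_tips)])


def make_three_tip() -> gen.Genealogy:
    """Fixed 3-tip tree: cherry (t1,t2) at age 0.2, root at age 0.5."""
    children = np.array([[-1, -1], [-1, -1], [-1, -1], [0, 1], [3, 2]], dtype=np.int64)
    ages = np.array([0.0, 0.0, 0.0, 0.2, 0.5])
    return gen.Genealogy(3, children, ages, ["t1", "t2", "t3"])


def two_tip_tree(tip_branch: float) -> gen.Genealogy:
    children = np.array([[-1, -1], [-1, -1], [0, 1]], dtype=np.int64)
    ages = np.array([0.0, 0.0, tip_branch])
    return gen.Genealogy(2, children, ages, ["t1", "t2"])


@pytest.fixture(scope="session")
def dataset500():
    """One full-protocol 500-sequence dataset (tree, alignment, matrices)."""
    g = gen.simulate_genealogy(500, seed=11)
    g_scaled, aln = seq.enforce_divergence_cap(g, seed=12)
    raw = dist.pairwise_matrix(aln)
    normalized = dist.minmax_normalize(raw, 0.0, 0.03)
    return {"tree": g, "tree_scaled": g_scaled, "aln": aln, "raw": raw, "norm": normalized}


@pytest.fixture(scope="session")
def dataset60():
    """A smaller dataset for resampling properties that need many replicates."""
    g = gen.simulate_genealogy(60, seed=21)
    g_scaled, aln = seq.enforce_divergence_cap(g, seed=22)
    raw = dist.pairwise_matrix(aln)
    normalized = dist.minmax_normalize(raw, 0.0, 0.03)
    return {"tree": g, "tree_scaled": g_scaled, "aln": aln, "raw": raw, "norm": normalized}
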