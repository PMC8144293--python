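"""Shared fixtures and independent naive oracle implementations.

The oracles re-derive every diversity measure with explicit loops over
edges and presence sets, sharing no code with the package's vectorized
kernel, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from coresweep.io import FeatureTable
from coresweep.tree import Phylogeny

FOUR_LEAF_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"


@pytest.fixture
def four_leaf_tree() -> Phylogeny:
    return Phylogeny.from_newick(FOUR_LEAF_NEWICK)


@pytest.fixture
def abcd() -> list[str]:
    return ["A", "B", "C", "D"]


def random_table(
    rng: np.random.Generator, n_samples: int, n_taxa: int, label: str = "s"
) -> FeatureTable:
    """Random sparse count table with every sample non-empty."""
    counts = rng.integers(0, 20, size=(n_samples, n_taxa))
    counts *= rng.random(size=counts.shape) < 0.6  # sparsify
    for i in range(n_samples):  # guarantee >= 2 reads (Morisita needs totals >= 2)
        while counts[i].sum() < 2:
            counts[i, rng.integers(n_taxa)] += rng.integers(1, 5)
    return FeatureTable(
        [f"{label}{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_taxa)],
        counts.astype(np.int64),
    )


# ------------------------------------------------------------------ #
# naive oracle route: explicit edge/leaf-set recursion, no numpy kernel
# ------------------------------------------------------------------ #
def _leafsets(tree: Phylogeny) -> dict[int, set[str]]:
    """Leaf-label set below every node, by recursion over children."""
    out: dict[int, set[str]] = {}

    def walk(v: int) -> set[str]:
        if tree.is_leaf[v]:
            out[v] = {tree.labels[v]}
        else:
            s: set[str] = set()
            for c in tree.children(v):
                s |= walk(c)
            out[v] = s
        return out[v]

    walk(tree.root)
    return out


def naive_edge_mass(
    counts: np.ndarray, taxon_ids: list[str], tree: Phylogeny
) -> dict[int, float]:
    total = float(np.sum(counts))
    rel = {t: c / total for t, c in zip(taxon_ids, counts)}
    return {
        v: sum(rel.get(lab, 0.0) for lab in leaves)
        for v, leaves in _leafsets(tree).items()
    }


def naive_faith(counts, taxon_ids, tree) -> float:
    mass = naive_edge_mass(counts, taxon_ids, tree)
    return sum(tree.length[v] for v, m in mass.items() if m > 0)


def naive_bwpd(counts, taxon_ids, tree, theta) -> float:
    mass = naive_edge_mass(counts, taxon_ids, tree)
    total = 0.0
    for v, m in mass.items():
        bal = 2.0 * min(m, 1.0 - m)
        if bal > 1e-12:  # degenerate edges (p_e in {0, 1}) never contribute
            total += tree.length[v] * bal**theta
    return total


def naive_shannon(counts) -> float:
    total = float(np.sum(counts))
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p)
    return h


def naive_jaccard(x, y) -> float:
    a = {j for j, v in enumerate(x) if v > 0}
    b = {j for j, v in enumerate(y) if v > 0}
    return 1.0 - len(a & b) / len(a | b)


def naive_morisita(x, y) -> float:
    X, Y = sum(x), sum(y)
    lam_x = sum(v * (v - 1) for v in x) / (X * (X - 1))
    lam_y = sum(v * (v - 1) for v in y) / (Y * (Y - 1))
    c = 2.0 * sum(a * b for a, b in zip(x, y)) / ((lam_x + lam_y) * X * Y)
    return max(0.0, 1.0 - c)


def naive_bray_curtis(x, y) -> float:
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def naive_unweighted_unifrac(x, y, taxon_ids, tree) -> float:
    mx = naive_edge_mass(x, taxon_ids, tree)
    my = naive_edge_mass(y, taxon_ids, tree)
    unique = sum(
        tree.length[v] for v in mx if (mx[v] > 0) != (my[v] > 0)
    )
    union = sum(tree.length[v] for v in mx if mx[v] > 0 or my[v] > 0)
    return unique / union


def naive_weighted_unifrac(x, y, taxon_ids, tree, normalized=True) -> float:
    mx = naive_edge_mass(x, taxon_ids, tree)
    my = naive_edge_mass(y, taxon_ids, tree)
    raw = sum(tree.length[v] * abs(mx[v] - my[v]) for v in mx)
    if not normalized:
        return raw
    return raw / sum(tree.length[v] * (mx[v] + my[v]) for v in mx)
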