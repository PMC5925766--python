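"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: silhouette by
plain loops over the definition, optimal leaf order by exhaustive flip
enumeration, single-linkage heights via Prim's minimum spanning tree.
"""

import numpy as np
import pytest
from hypothesis import settings

from interheat import DataMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def line_matrix():
    """Points {0, 1, 5} on a line: UPGMA merges at heights 1 then 4.5."""
    return DataMatrix(np.array([[0.0], [1.0], [5.0]]), ["p0", "p1", "p5"], ["v"])


@pytest.fixture
def four_point_matrix():
    """Points {0, 1, 10, 11}: two tight pairs far apart."""
    return DataMatrix(np.array([[0.0], [1.0], [10.0], [11.0]]),
                      ["a", "b", "c", "d"], ["v"])


def random_matrix(rng, n_rows, n_cols, missing_frac=0.0):
    values = rng.normal(size=(n_rows, n_cols))
    if missing_frac:
        mask = rng.random(values.shape) < missing_frac
        # keep at least 2 observed per column so scale() stays defined
        for j in range(n_cols):
            keep = rng.choice(n_rows, size=min(2, n_rows), replace=False)
            mask[keep, j] = False
        values[mask] = np.nan
    return DataMatrix(values, [f"r{i}" for i in range(n_rows)],
                      [f"c{j}" for j in range(n_cols)])


def brute_silhouette(d, labels):
    """Mean silhouette straight from the definition, loops only."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue  # singleton contributes 0
        a = sum(d[i, j] for j in own) / len(own)
        b = min(
            sum(d[i, j] for j in range(n) if labels[j] == c) /
            sum(1 for j in range(n) if labels[j] == c)
            for c in set(labels) if c != labels[i])
        total += 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return total / n


def enumerate_flip_orders(tree):
    """All leaf orders reachable by branch flips (2^(n-1) of them)."""
    n = tree.n_leaves
    children = tree.children()

    def orders(node):
        if node < n:
            return [[node]]
        a, b = children[node]
        out = []
        for oa in orders(a):
            for ob in orders(b):
                out.append(oa + ob)
                out.append(ob + oa)
        return out

    return orders(2 * n - 2)


def brute_olo_cost(tree, d):
    return min(sum(d[o[i], o[i + 1]] for i in range(len(o) - 1))
               for o in enumerate_flip_orders(tree))


def mst_edge_weights(d):
    """Prim's algorithm; returns sorted MST edge weights."""
    n = d.shape[0]
    in_tree = [0]
    out = set(range(1, n))
    weights = []
    while out:
        w, v = min((d[i, j], j) for i in in_tree for j in out)
        weights.append(w)
        in_tree.append(v)
        out.remove(v)
    return sorted(weights)


def span_contiguous(tree, order):
    """True iff every internal node's leaf set is contiguous in ``order``."""
    pos = {leaf: p for p, leaf in enumerate(order)}
    for leaves in tree.leaves_under().values():
        ps = sorted(pos[leaf] for leaf in leaves)
        if ps != list(range(ps[0], ps[0] + len(ps))):
            return False
    return True
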