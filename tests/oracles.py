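"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, full enumeration)
kept separate from the package code they check.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
from scipy import stats as sps


def parse_tree_edges(newick: str):
    """(length, frozenset-of-descendant-leaves) per edge, via dendropy."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    edges = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root has no branch
        leaves = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        edges.append((float(edge.length or 0.0), leaves))
    return edges


def unweighted_unifrac_bruteforce(a: dict, b: dict, newick: str) -> float:
    present_a = {t for t, v in a.items() if v > 0}
    present_b = {t for t, v in b.items() if v > 0}
    unique = observed = 0.0
    for length, leaves in parse_tree_edges(newick):
        in_a = bool(leaves & present_a)
        in_b = bool(leaves & present_b)
        if in_a or in_b:
            observed += length
            if in_a != in_b:
                unique += length
    return unique / observed


def weighted_unifrac_bruteforce(a: dict, b: dict, newick: str, normalized=False) -> float:
    ta = sum(a.values())
    tb = sum(b.values())
    raw = denom = 0.0
    for length, leaves in parse_tree_edges(newick):
        pa = sum(v for t, v in a.items() if t in leaves) / ta
        pb = sum(v for t, v in b.items() if t in leaves) / tb
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if normalized:
        return raw / denom if denom else 0.0
    return raw


def bh_stepup_bruteforce(p):
    """Textbook BH step-up: sort, adjust p_(i) * m / i, enforce monotone
    from the largest down, clip at 1, restore order."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adjusted[i] = min(val, 1.0)
        prev = val
    return adjusted


def wilcoxon_exact_bruteforce(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns
    on the observed |differences| (no ties assumed)."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = sps.rankdata([abs(x) for x in d])
    w_pos = sum(r for r, x in zip(ranks, d) if x > 0)
    w_neg = sum(r for r, x in zip(ranks, d) if x < 0)
    w_obs = min(w_pos, w_neg)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wn = sum(ranks) - wp
        if min(wp, wn) <= w_obs:
            count += 1
    return w_obs, count / 2**n


def hedges_g_formula(diffs):
    d = np.asarray(diffs, dtype=float)
    n = d.size
    cohen = d.mean() / d.std(ddof=1)
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return cohen * j


def trapezoid_by_hand(times, values):
    area = 0.0
    for i in range(len(times) - 1):
        area += 0.5 * (values[i] + values[i + 1]) * (times[i + 1] - times[i])
    return area


def random_tree_dict(rng: np.random.Generator, n_leaves: int):
    """Random rooted bifurcating newick over leaves L0..L{n-1} plus random
    abundance dicts for two samples (possibly sparse)."""
    names = [f"L{i}" for i in range(n_leaves)]

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        bl, br = rng.uniform(0.1, 1.0, 2)
        return f"({build(leaves[:k])}:{bl:.4f},{build(leaves[k:])}:{br:.4f})"

    order = [names[i] for i in rng.permutation(n_leaves)]
    newick = build(order) + ";"

    def sample():
        mask = rng.random(n_leaves) < 0.6
        if not mask.any():
            mask[rng.integers(n_leaves)] = True
        vals = rng.random(n_leaves) * mask
        return {n: float(v) for n, v in zip(names, vals)}

    return newick, sample(), sample()
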