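"""Independent brute-force oracles shared across test modules.

Each function re-derives a statistic by explicit enumeration, never through
the code paths under test.
"""

import itertools
import math

import numpy as np
import pandas as pd

from metacomm import community


def brute_force_wunifrac(newick, abund, normalized=True):
    """Weighted UniFrac by explicit per-branch tip-set enumeration."""
    tree = community.read_tree(newick)
    props = abund.div(abund.sum(axis=1), axis=0)
    branches = []  # (length, set of tip names below)
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length or 0.0, tips))
    depth = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depth[tip.name] = d
    ids = list(abund.index)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        u = sum(
            l * abs(
                sum(props.loc[a].get(t, 0.0) for t in tips)
                - sum(props.loc[b].get(t, 0.0) for t in tips)
            )
            for l, tips in branches
        )
        if normalized:
            denom = sum(
                depth[t] * (props.loc[a].get(t, 0.0) + props.loc[b].get(t, 0.0))
                for t in depth
            )
            u = u / denom if denom else 0.0
        out.loc[a, b] = out.loc[b, a] = u
    return out


def exhaustive_mrpp(d, labels):
    """Exact delta distribution over all distinct label assignments."""
    d = np.asarray(d, dtype=float)
    labels = list(labels)
    uniq = sorted(set(labels))
    deltas = []
    for perm in set(itertools.permutations(labels)):
        delta = 0.0
        for g in uniq:
            idx = [i for i, lab in enumerate(perm) if lab == g]
            pairs = list(itertools.combinations(idx, 2))
            mean_within = np.mean([d[i, j] for i, j in pairs])
            delta += len(idx) / len(labels) * mean_within
        deltas.append(delta)
    return np.array(deltas)


def brute_force_fisher(carriers, sizes):
    """Exact two-sided Fisher p by full table enumeration (rational comb)."""
    K = sum(carriers)
    N = sum(sizes)
    denom = math.comb(N, K)

    def prob(cells):
        num = 1
        for n, a in zip(sizes, cells):
            num *= math.comb(n, a)
        return num / denom

    p_obs = prob(carriers)
    total = 0.0
    ranges = [range(min(n, K) + 1) for n in sizes[:-1]]
    for partial in itertools.product(*ranges):
        last = K - sum(partial)
        if 0 <= last <= sizes[-1]:
            p = prob(list(partial) + [last])
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(total, 1.0)


def exhaustive_perm_p(x, n_inc, n_dec):
    """Permutation-test p over every disjoint group assignment."""
    n = len(x)
    c_inc = x[:n_inc].sum()
    c_dec = x[n_inc:n_inc + n_dec].sum()
    t_obs = abs(c_inc / n_inc - c_dec / n_dec)
    ts = []
    for inc in itertools.combinations(range(n), n_inc):
        rest = [i for i in range(n) if i not in inc]
        for dec in itertools.combinations(rest, n_dec):
            ts.append(abs(
                sum(x[list(inc)]) / n_inc - sum(x[list(dec)]) / n_dec))
    ts = np.array(ts)
    return (ts > t_obs + 1e-12).mean()


def rank_with_ties(v):
    """Average ranks computed by explicit tie-block scanning."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sv = np.asarray(v)[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks
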