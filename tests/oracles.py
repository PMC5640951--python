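"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive — step-by-step loops and exhaustive
enumeration — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb


def es_running_sum(ranked_genes, weights, member_genes, p=1.0):
    """Step-by-step weighted KS running sum; returns (ES, full running sum)."""
    members = set(member_genes)
    hit_w = [abs(w) ** p for g, w in zip(ranked_genes, weights) if g in members]
    W = sum(hit_w)
    n_miss = len(ranked_genes) - len(hit_w)
    run, sums = 0.0, []
    for g, w in zip(ranked_genes, weights):
        if g in members:
            run += (abs(w) ** p / W) if W > 0 else 1.0 / len(hit_w)
        else:
            run -= 1.0 / n_miss
        sums.append(run)
    max_pos, min_neg = max(sums), min(sums)
    # ties in |deviation| (up to float noise) resolve to the positive side
    es = max_pos if max_pos >= -min_neg - 1e-9 else min_neg
    return es, sums


def hypergeom_upper_tail(overlap, universe, set_size, n_de):
    """P(X >= overlap) by exhaustive summation of hypergeometric masses."""
    total = comb(universe, n_de)
    prob = 0.0
    for k in range(overlap, min(set_size, n_de) + 1):
        prob += comb(set_size, k) * comb(universe - set_size, n_de - k) / total
    return prob


def distinct_label_assignments(n1, n2):
    """Enumerate distinct two-cohort splits of n1+n2 samples by brute force.

    Complementary assignments count once when n1 == n2 (the two-group split
    is the same); for n1 != n2 every choice of the size-n1 group is distinct.
    """
    n = n1 + n2
    seen = set()
    for combo in itertools.combinations(range(n), n1):
        group = frozenset(combo)
        if n1 == n2:
            rest = frozenset(set(range(n)) - group)
            seen.add(frozenset({group, rest}))
        else:
            seen.add(group)
    return len(seen)


def expected_stub_discrimination(P, K):
    """Exact expected discrimination for a uniformly-random-K-subset stub.

    Enumerates all (A, A', a) triples of K-subsets of P pathways; by symmetry
    each sub-dataset ranking contributes independently, so the expectation is
    Pr[r(A, a) > r(A', a)] over uniform independent subsets.
    """
    subsets = list(itertools.combinations(range(P), K))
    win = total = 0
    for A in subsets:
        sA = set(A)
        for Ap in subsets:
            sAp = set(Ap)
            for a in subsets:
                sa = set(a)
                total += 1
                if len(sA & sa) > len(sAp & sa):
                    win += 1
    return win / total
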