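"""Independent brute-force oracles shared across test modules."""

import itertools


def brute_force_hypergeom_tail(k, q, m, N):
    """P(overlap >= k) by enumerating all C(N, q) draws."""
    marked = set(range(m))
    hits = total = 0
    for draw in itertools.combinations(range(N), q):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def exact_rank_sum_p(a, b):
    """Two-sided rank-sum p by full enumeration of rank assignments (no ties)."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    na = len(a)
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    us = [
        sum(c) - na * (na + 1) / 2
        for c in itertools.combinations(range(1, len(pooled) + 1), na)
    ]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_le, p_ge))
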