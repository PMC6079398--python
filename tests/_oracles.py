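"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/numpy machinery: the hypergeometric tail
is an explicit comb() sum and the percentile rank a quadratic counting
rule, so they share no code path with the functions they verify.
"""

from math import comb


def hypergeom_upper_tail(k: int, n_total: int, n_pos_total: int, n_sel: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_total, K=n_pos_total, n=n_sel)."""
    denom = comb(n_total, n_sel)
    total = 0
    for x in range(k, min(n_pos_total, n_sel) + 1):
        if n_sel - x <= n_total - n_pos_total:
            total += comb(n_pos_total, x) * comb(n_total - n_pos_total, n_sel - x)
    return total / denom


def counting_percentiles(values):
    """Tie-averaged percentile ranks by O(n^2) counting:
    (#{strictly below} + (#{equal} + 1) / 2) / n."""
    n = len(values)
    out = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append((below + (equal + 1) / 2) / n)
    return out


def induced_edges(candidates, edge_pairs):
    """Brute-force induced subgraph: double loop over all candidate pairs."""
    cand = {c.lower() for c in candidates}
    kept = set()
    for u, v in edge_pairs:
        if u.lower() in cand and v.lower() in cand and u.lower() != v.lower():
            kept.add(tuple(sorted((u.lower(), v.lower()))))
    return kept
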