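"""Independent oracles used by the test suite and the acceptance script.

These deliberately avoid the code paths they check: the chain oracle
enumerates every terminally-anchored collinear chain recursively instead of
running the dynamic programme, and the binomial oracle works in log space
with ``math.lgamma`` instead of scipy.
"""

import math
import random


def _gap_cost(k, params):
    if k < 1:
        return 0
    if params.gap_mode == "open_includes_first":
        return params.gap_open + (k - 1) * params.gap_extend
    return params.gap_open + k * params.gap_extend


def _fill(a, b, params):
    """Cheapest inter-anchor fill: m mismatch columns plus one gap run per
    genome (splitting a gap run is never cheaper under concave gap costs)."""
    return max(
        params.mismatch_score * m + _gap_cost(a - m, params) + _gap_cost(b - m, params)
        for m in range(min(a, b) + 1)
    )


def best_chain_score_bruteforce(rel, params):
    """Maximum score over all terminally-anchored collinear chains.

    *rel* maps (ref index, cmp index) -> "ortholog" | "homolog".  Chains
    have strictly increasing ref indices and strictly monotonic cmp indices
    (increasing = forward, decreasing = reversed).  Returns None when there
    are no anchors at all.
    """
    def sc(kind):
        return params.ortholog_score if kind == "ortholog" else params.homolog_score

    anchors = sorted(rel)
    best = None

    def extend(i0, j0, score, direction):
        nonlocal best
        if best is None or score > best:
            best = score
        for (i, j) in anchors:
            if i <= i0 or j == j0:
                continue
            d = 1 if j > j0 else -1
            if direction != 0 and d != direction:
                continue
            a, b = i - i0 - 1, abs(j - j0) - 1
            extend(i, j, score + _fill(a, b, params) + sc(rel[(i, j)]), d)

    for (i, j) in anchors:
        extend(i, j, sc(rel[(i, j)]), 0)
    return best


def random_instance(rng: random.Random, max_genes=8, density=0.18):
    """A random relation map for a small two-genome instance."""
    n = rng.randint(2, max_genes)
    m = rng.randint(2, max_genes)
    rel = {}
    for i in range(n):
        for j in range(m):
            if rng.random() < density:
                rel[(i, j)] = "ortholog" if rng.random() < 0.5 else "homolog"
    return n, m, rel


def binomial_point_logspace(k, n, p):
    """P(X = k) via lgamma in log space; underflow-free."""
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    logc = (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))
    return math.exp(logc + k * math.log(p) + (n - k) * math.log1p(-p))


def binomial_upper_tail_logspace(k, n, p):
    return sum(binomial_point_logspace(j, n, p) for j in range(k, n + 1))
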