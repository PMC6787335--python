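"""Independent oracles used by the test suite.

Each function re-derives a quantity by a route different from the package
implementation: tensor-product quadrature of the raw bivariate density,
Monte-Carlo integration, exhaustive subset counting, the closed-form 2x2
chi-square formula, and brute-force search over all set partitions.
"""
import itertools
import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm


def bvn_orthant_quadrature(margin_a, margin_b, rho, order=140, upper=9.0):
    """P(X > a, Y > b) by 2-D Gauss-Legendre quadrature of the density."""
    a, b = norm.isf(margin_a), norm.isf(margin_b)
    xs, wx = leggauss(order)
    x = 0.5 * (upper - a) * xs + 0.5 * (upper + a)
    wxs = 0.5 * (upper - a) * wx
    y = 0.5 * (upper - b) * xs + 0.5 * (upper + b)
    wys = 0.5 * (upper - b) * wx
    xx, yy = np.meshgrid(x, y, indexing="ij")
    det = 1.0 - rho * rho
    dens = np.exp(-(xx ** 2 - 2 * rho * xx * yy + yy ** 2) / (2 * det))
    dens /= 2 * math.pi * math.sqrt(det)
    return float(wxs @ dens @ wys)


def bvn_orthant_monte_carlo(margin_a, margin_b, rho, n, seed):
    """Monte-Carlo orthant probability; returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    a, b = norm.isf(margin_a), norm.isf(margin_b)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    hits = (z1 > a) & (z2 > b)
    p = hits.mean()
    return p, math.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# brute-force rule statistics by exhaustive subset counting
# ---------------------------------------------------------------------------

def brute_event_prob(indicators, weights, cols):
    """Weighted probability of having every condition in ``cols``."""
    has_all = np.ones(len(weights), dtype=bool)
    for c in cols:
        has_all &= indicators[:, c] == 1
    return float(weights[has_all].sum() / weights.sum())


def brute_rule(indicators, weights, ante_cols, cons_cols):
    """(pA, pB, support, confidence, lift) by direct counting."""
    pa = brute_event_prob(indicators, weights, ante_cols)
    pb = brute_event_prob(indicators, weights, cons_cols)
    joint = brute_event_prob(indicators, weights, list(ante_cols) + list(cons_cols))
    conf = joint / pa if pa > 0 else float("nan")
    lift = joint / (pa * pb) if pa * pb > 0 else float("nan")
    return pa, pb, joint, conf, lift


def brute_std_lift(pa, pb, joint, n, s=0.0, c=0.0):
    """Standardised lift with the attainable upper bound, from its algebra."""
    lift = joint / (pa * pb)
    lam = max(pa + pb - 1.0, 1.0 / n, s, c * pa) / (pa * pb)
    ups = 1.0 / max(pa, pb)
    return (lift - lam) / (ups - lam)


def chi2_two_by_two(a, b, c, d):
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------
# exhaustive community-detection oracle
# ---------------------------------------------------------------------------

def iter_set_partitions(items):
    """All partitions of a list of items (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def modularity_edge_sum(graph, membership, use_weights=True):
    """Q via the per-edge sum Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j) / 2m."""
    nodes = list(graph.nodes)
    w = {}
    deg = {v: 0.0 for v in nodes}
    for u, v, data in graph.edges(data=True):
        wt = data.get("weight", 1.0) if use_weights else 1.0
        w[(u, v)] = w[(v, u)] = wt
        deg[u] += wt
        deg[v] += wt
    two_m = sum(deg.values())
    if two_m == 0:
        return 0.0
    q = 0.0
    for u in nodes:
        for v in nodes:
            if membership[u] != membership[v]:
                continue
            a_uv = w.get((u, v), 0.0) if u != v else 0.0
            q += a_uv - deg[u] * deg[v] / two_m
    return q / two_m


def exhaustive_best_partition(graph, use_weights=True):
    """(best Q, best membership) by brute force over all partitions."""
    nodes = sorted(graph.nodes)
    best_q, best_m = -np.inf, None
    for part in iter_set_partitions(nodes):
        membership = {v: i for i, block in enumerate(part) for v in block}
        q = modularity_edge_sum(graph, membership, use_weights)
        if q > best_q:
            best_q, best_m = q, membership
    return best_q, best_m
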