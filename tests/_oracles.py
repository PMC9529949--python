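"""Independent reference implementations used only by the test suite.

Each oracle restates the defining computation directly (enumeration,
all-pairs scan, hand formula) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist


def overlap_hits_bruteforce(records, query):
    """All-pairs overlap scan: >=1 bp shared, half-open, same chromosome."""
    hits = [
        r
        for r in records
        if r.interval.chrom == query.chrom
        and r.interval.start < query.end
        and query.start < r.interval.end
    ]
    hits.sort(key=lambda r: (r.interval.start, getattr(r, "gene_id", None) or getattr(r, "enhancer_id", "")))
    return hits


def errg_pairs_bruteforce_numpy(enhancers_by_resource, genes, half_width, domain_length):
    """Vectorized all-pairs eRRG identification (no interval index).

    Returns (per_resource gene-id sets, final intersection,
    {(enhancer_id, resource, gene_id)} pair set).
    """
    chroms = sorted({g.interval.chrom for g in genes} | {
        e.interval.chrom for recs in enhancers_by_resource.values() for e in recs
    })
    code = {c: i for i, c in enumerate(chroms)}
    g_chrom = np.array([code[g.interval.chrom] for g in genes])
    g_start = np.array([g.interval.start for g in genes])
    g_end = np.array([g.interval.end for g in genes])
    gene_ids = np.array([g.gene_id for g in genes])

    per_resource, pairs = {}, set()
    for resource, recs in enhancers_by_resource.items():
        e_chrom = np.array([code[e.interval.chrom] for e in recs])
        mid = np.array([(e.interval.start + e.interval.end) // 2 for e in recs])
        r_start = np.maximum(0, mid - half_width)
        r_end = mid + half_width
        same = e_chrom[:, None] == g_chrom[None, :]
        region_ovl = same & (r_start[:, None] < g_end[None, :]) & (g_start[None, :] < r_end[:, None])
        keep = ~region_ovl.any(axis=1)
        half = domain_length // 2
        w_start = np.maximum(0, mid - half)
        w_end = mid + (domain_length - half)
        win_ovl = same & (w_start[:, None] < g_end[None, :]) & (g_start[None, :] < w_end[:, None])
        win_ovl &= keep[:, None]
        ei, gi = np.nonzero(win_ovl)
        per_resource[resource] = set(gene_ids[gi])
        for e_idx, g_idx in zip(ei, gi):
            pairs.add((recs[e_idx].enhancer_id, resource, gene_ids[g_idx]))
    final = set.intersection(*per_resource.values()) if per_resource else set()
    return per_resource, final, pairs


def wilcoxon_exact_p(x, y):
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Assumes no ties. Two-sided p = P(|W - E[W]| >= |W_obs - E[W]|) under
    the permutation null (the null distribution of W is symmetric, so this
    agrees with doubling the one-sided tail).
    """
    x, y = list(x), list(y)
    n1, n = len(x), len(x) + len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n, "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    mu = n1 * (n + 1) / 2
    total = hits = 0
    for combo in combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def fisher_exact_p(a, b, c, d):
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


def bh_stepup(pvalues):
    """BH step-up from its definition: q_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def logrank_by_hand(groups, times, events, label_a):
    """Log-rank chi-square accumulated per distinct event time."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    is_a = groups == label_a
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & is_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & is_a).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
    chi2 = (O - E) ** 2 / V
    return chi2, float(chi2_dist.sf(chi2, 1))


def km_by_hand(times, events):
    """Product-limit S(t) at each distinct event time (censoring after events)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out[t] = s
    return out
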