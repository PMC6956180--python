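"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive step-by-step algorithms (full running-sum
walks, exhaustive subset enumeration, closed-form combinatorics) and share
no code with the package internals.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_es(genes, stats, members, weight=1.0):
    """Enrichment score by walking every position of the ranked list.

    Computed in exact rational arithmetic so that magnitude ties — which
    occur whenever the walk's extremes are symmetric — are detected
    exactly; a tie resolves to the positive deviation (the package
    convention).
    """
    from fractions import Fraction

    members = set(members)
    hits = [g in members for g in genes]
    n = len(genes)
    n_hit = sum(hits)
    assert 0 < n_hit < n
    incs = [Fraction(float(abs(s)) ** weight) for s in stats]
    denom = sum(w for w, h in zip(incs, hits) if h)
    if denom == 0:
        return 0.0
    miss = Fraction(1, n - n_hit)
    cur = Fraction(0)
    best = Fraction(0)
    for w, h in zip(incs, hits):
        cur = cur + w / denom if h else cur - miss
        if abs(cur) > abs(best) or (abs(cur) == abs(best) and cur > best):
            best = cur
    return float(best)


def exhaustive_null_count(genes, stats, size, es_obs, weight=1.0):
    """Number of same-size subsets with a same-sign ES at least as extreme
    as ``es_obs``, by enumerating every subset."""
    b = 0
    for combo in itertools.combinations(genes, size):
        es = brute_force_es(genes, stats, set(combo), weight)
        if es_obs > 0 and es >= es_obs:
            b += 1
        elif es_obs < 0 and es <= es_obs:
            b += 1
    return b


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up, written directly from the definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def hypergeom_upper_tail(universe_size, n_markers, n_draws, overlap):
    """P(X >= overlap) by summing the hypergeometric pmf written as
    binomial coefficients."""
    total = comb(universe_size, n_draws)
    hi = min(n_markers, n_draws)
    acc = 0
    for j in range(overlap, hi + 1):
        acc += comb(n_markers, j) * comb(universe_size - n_markers, n_draws - j)
    return acc / total


def hypergeom_by_enumeration(list_genes, markers, universe):
    """P(a uniform random draw of |list_genes| genes overlaps the markers at
    least as much as observed), by enumerating every possible draw.

    Only feasible for small universes; used as the oracle on |universe| <= 12.
    """
    universe = sorted(universe)
    markers = set(markers) & set(universe)
    observed = len(set(list_genes) & markers)
    n_draws = len(list_genes)
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, n_draws):
        total += 1
        if len(set(combo) & markers) >= observed:
            hits += 1
    return hits / total


def match_by_enumeration(profiles, query_targets):
    """Reversal matching re-written as an explicit double loop."""
    out = []
    for prof in profiles:
        ok = True
        for pathway, want in query_targets.items():
            if prof.calls.get(pathway) != want:
                ok = False
        if ok:
            out.append(prof.signature_id)
    return out


def random_ranked(rng, n):
    """Distinct-stat ranked inputs (genes, stats sorted descending)."""
    stats = np.sort(rng.normal(0, 1, n))[::-1]
    genes = [f"g{i}" for i in range(n)]
    return genes, stats
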