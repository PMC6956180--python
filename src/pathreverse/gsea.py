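"""Pre-ranked gene set enrichment with a random-gene-set permutation null.

The enrichment score (ES) walks the ranked gene list: each in-set gene
("hit") moves the running sum up by ``|s_i|**weight`` normalised by the sum
of those increments, each out-of-set gene ("miss") moves it down by
``1/(N - n_hit)``.  The ES is the running sum's maximum-magnitude deviation
from zero, so a positive ES means the set is concentrated among
up-regulated genes and a negative ES among down-regulated ones.

Because the null distribution of the ES is not known analytically, p-values
come from random gene sets of the same size drawn uniformly without
replacement from the ranked universe: p is estimated from the number of
random sets with a same-sign ES at least as extreme as the observed one.
FDR control across pathways uses Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, EmptyInputError
from .types import GeneSetCollection, RankedSignature

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_score",
    "permutation_pvalue",
    "bh_adjust",
    "run_enrichment",
    "collapse_pathways",
    "EnrichmentTable",
]


@dataclass
class EnrichmentTable:
    """Per-pathway enrichment results for one ranked signature.

    ``records`` has one row per retained pathway with columns
    ``pathway, es, size, pvalue, padj, leading_edge`` (leading edge as a
    frozenset of symbols); ``params`` stores the run parameters
    (min_size, max_size, nperm, seed, weight).
    """

    dataset_id: str
    records: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _hit_positions(ranked: RankedSignature, members, idx=None) -> np.ndarray:
    if idx is None:
        idx = ranked.index
    pos = sorted(idx[g] for g in members if g in idx)
    return np.asarray(pos, dtype=np.int64)


def _es_batch(pos: np.ndarray, absr_w: np.ndarray, n_genes: int):
    """ES for each row of sorted hit-position matrix ``pos``.

    The running sum only attains candidate extrema adjacent to hits (it
    decreases linearly between them and ends at zero), so only the values
    just after and just before each hit are examined.  Returns
    ``(es, peak)`` where ``peak[i]`` is the hit index of the extremum in row
    i (for the leading edge).  Rows whose hit weights sum to zero get
    ES = 0 by convention (a set with no signal mass cannot be enriched).
    """
    pos = np.atleast_2d(pos)
    nperm, k = pos.shape
    miss_dec = 1.0 / (n_genes - k)
    w = absr_w[pos]  # (nperm, k)
    s = w.sum(axis=1, keepdims=True)
    ok = s[:, 0] > 0
    s_safe = np.where(s > 0, s, 1.0)
    cum = np.cumsum(w, axis=1) / s_safe
    misses = (pos - np.arange(k)) * miss_dec
    top = cum - misses  # value just after each hit
    bot = top - w / s_safe  # value just before each hit
    imax = np.argmax(top, axis=1)
    imin = np.argmin(bot, axis=1)
    rows = np.arange(nperm)
    maxtop = top[rows, imax]
    minbot = bot[rows, imin]
    # magnitude ties (common: the walk is piecewise rational) resolve to the
    # positive deviation; the tolerance absorbs float summation error
    tol = 1e-12 * np.maximum(np.abs(maxtop), np.abs(minbot))
    pos_wins = (maxtop + minbot) >= -tol
    es = np.where(pos_wins, maxtop, minbot)
    peak = np.where(pos_wins, imax, imin)
    es = np.where(ok, es, 0.0)
    return es, peak


def enrichment_score(
    ranked: RankedSignature, members, weight: float = 1.0
) -> tuple[float, frozenset]:
    """Weighted running-sum enrichment score and leading edge.

    Parameters
    ----------
    ranked : RankedSignature
        Genes sorted by statistic, descending.
    members : iterable of str
        The gene set; only members present in the ranking count.
    weight : float
        Exponent on ``|stat|`` for hit increments. 1 gives the weighted
        statistic of preranked GSEA; 0 the classic Kolmogorov-Smirnov form.

    Returns
    -------
    (es, leading_edge)
        ``es`` in [-1, 1]; the leading edge contains the in-set genes from
        the top of the list to the running-sum peak (es > 0) or from the
        trough to the bottom (es < 0).
    """
    n = len(ranked)
    pos = _hit_positions(ranked, members)
    k = len(pos)
    if k == 0:
        raise EmptyInputError("gene set does not intersect the ranked universe")
    if k == n:
        raise ConfigError(
            "gene set equals the whole ranked universe; miss increment undefined"
        )
    absr_w = np.abs(ranked.stats) ** weight
    es, peak = _es_batch(pos[None, :], absr_w, n)
    es, peak = float(es[0]), int(peak[0])
    if es == 0.0:
        return 0.0, frozenset()
    if es > 0:
        lead = pos[: peak + 1]
    else:
        lead = pos[peak:]
    genes = ranked.genes
    return es, frozenset(genes[i] for i in lead)


def _null_es(
    rng: np.random.Generator,
    absr_w: np.ndarray,
    n_genes: int,
    set_size: int,
    nperm: int,
) -> np.ndarray:
    """ES values for ``nperm`` random same-size gene sets."""
    pos = np.empty((nperm, set_size), dtype=np.int64)
    for i in range(nperm):
        pos[i] = rng.choice(n_genes, size=set_size, replace=False)
    pos.sort(axis=1)
    es, _ = _es_batch(pos, absr_w, n_genes)
    return es


def _perm_p(
    es_obs: float, null: np.ndarray, smoothed: bool, absolute: bool
) -> tuple[float, int]:
    nperm = len(null)
    if absolute:
        b = int(np.sum(np.abs(null) >= abs(es_obs)))
    elif es_obs > 0:
        b = int(np.sum(null >= es_obs))
    elif es_obs < 0:
        b = int(np.sum(null <= es_obs))
    else:  # degenerate zero score: nothing is more extreme than no signal
        return 1.0, nperm
    if smoothed:
        p = (b + 1) / (nperm + 1)
    else:
        p = max(b / nperm, 1.0 / nperm)
    return p, b


def permutation_pvalue(
    ranked: RankedSignature,
    members,
    nperm: int,
    seed,
    weight: float = 1.0,
    smoothed: bool = True,
    absolute: bool = False,
) -> tuple[float, float, int]:
    """Observed ES and its random-gene-set permutation p-value.

    Random sets of the intersected size are drawn uniformly without
    replacement from the ranked universe.  "Same or more extreme" is
    evaluated one-sided in the sign of the observed ES (opposite-sign null
    draws do not count); pass ``absolute=True`` to compare magnitudes
    instead.  The default estimator is the add-one-smoothed ratio
    ``(b + 1)/(nperm + 1)``, which never returns zero; ``smoothed=False``
    gives the plain ratio ``b/nperm`` floored at ``1/nperm``.

    Returns ``(es, pvalue, n_more_extreme)``.
    """
    if nperm < 1:
        raise ConfigError("nperm must be >= 1")
    es, _ = enrichment_score(ranked, members, weight=weight)
    k = len(_hit_positions(ranked, members))
    rng = np.random.default_rng(seed)
    absr_w = np.abs(ranked.stats) ** weight
    null = _null_es(rng, absr_w, len(ranked), k, nperm)
    p, b = _perm_p(es, null, smoothed, absolute)
    return es, p, b


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ConfigError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")


def _pathway_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-pathway stream: stable across platforms and across
    pathway orderings."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def run_enrichment(
    ranked: RankedSignature,
    collection: GeneSetCollection,
    nperm: int,
    seed: int,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
    smoothed: bool = True,
    absolute: bool = False,
) -> EnrichmentTable:
    """Enrichment of every size-eligible set in ``collection`` against
    ``ranked``, with BH-adjusted permutation p-values.

    Pathways are filtered by intersected size within [min_size, max_size];
    the BH family is exactly the retained pathways. Each pathway draws its
    null from an independent stream derived from (seed, pathway name), so
    results do not depend on collection order.
    """
    if len(collection) == 0:
        raise ConfigError("gene set collection is empty")
    if nperm < 1:
        raise ConfigError("nperm must be >= 1")
    n = len(ranked)
    absr_w = np.abs(ranked.stats) ** weight
    idx = ranked.index
    rows = []
    for gs in collection:
        pos = _hit_positions(ranked, gs.members, idx)
        k = len(pos)
        if k < min_size or k > max_size or k == n:
            continue
        es_arr, peak_arr = _es_batch(pos[None, :], absr_w, n)
        es, peak = float(es_arr[0]), int(peak_arr[0])
        rng = _pathway_rng(seed, gs.name)
        null = _null_es(rng, absr_w, n, k, nperm)
        p, b = _perm_p(es, null, smoothed, absolute)
        if es > 0:
            lead = frozenset(ranked.genes[i] for i in pos[: peak + 1])
        elif es < 0:
            lead = frozenset(ranked.genes[i] for i in pos[peak:])
        else:
            lead = frozenset()
        rows.append((gs.name, es, k, p, b, lead))
    params = dict(
        min_size=min_size, max_size=max_size, nperm=nperm, seed=seed, weight=weight
    )
    if not rows:
        logger.warning(
            "no pathway passed the size filter [%d, %d] for %s",
            min_size,
            max_size,
            ranked.signature_id,
        )
        records = pd.DataFrame(
            columns=["pathway", "es", "size", "pvalue", "padj", "leading_edge"]
        )
        return EnrichmentTable(ranked.signature_id, records, params)
    records = pd.DataFrame(
        rows, columns=["pathway", "es", "size", "pvalue", "n_more_extreme", "leading_edge"]
    )
    records["padj"] = bh_adjust(records["pvalue"].to_numpy())
    records = records[
        ["pathway", "es", "size", "pvalue", "padj", "n_more_extreme", "leading_edge"]
    ]
    return EnrichmentTable(ranked.signature_id, records, params)


def _restrict(ranked: RankedSignature, drop: set) -> RankedSignature:
    keep = [i for i, g in enumerate(ranked.genes) if g not in drop]
    return RankedSignature(
        ranked.signature_id,
        [ranked.genes[i] for i in keep],
        ranked.stats[keep],
        ranked.stat_kind,
    )


def collapse_pathways(
    table: EnrichmentTable,
    collection: GeneSetCollection,
    ranked: RankedSignature,
    dependence_p: float = 0.05,
    fdr: float = 0.05,
    nperm: int | None = None,
) -> tuple[set, dict]:
    """Greedy collapsing of redundant significant pathways.

    Significant pathways (padj <= ``fdr``) are processed in order of raw p
    (ties by name). The best remaining pathway is promoted to "main"; every
    remaining candidate is re-tested on the ranked list with the main
    pathway's genes removed from both universe and candidate set, and
    candidates whose conditional permutation p exceeds ``dependence_p`` are
    recorded as children of that main pathway.  A candidate left with fewer
    than two genes after removal is absorbed outright.

    Returns ``(main_names, parent_of)``.
    """
    if nperm is None:
        nperm = int(table.params.get("nperm", 1000))
    weight = float(table.params.get("weight", 1.0))
    seed = int(table.params.get("seed", 0))
    sig = table.records[table.records["padj"] <= fdr]
    order = sig.sort_values(["pvalue", "pathway"], kind="mergesort")["pathway"].tolist()
    main: set = set()
    parent_of: dict = {}
    remaining = list(order)
    while remaining:
        best = remaining.pop(0)
        main.add(best)
        if not remaining:
            break
        drop = set(collection[best].members)
        reduced = _restrict(ranked, drop)
        still = []
        for cand in remaining:
            members = set(collection[cand].members) - drop
            k = len([g for g in members if g in reduced.index])
            if k < 2:
                parent_of[cand] = best
                continue
            rng = _pathway_rng(seed ^ 0x5F3759DF, f"{best}|{cand}")
            es, _ = enrichment_score(reduced, members, weight=weight)
            absr_w = np.abs(reduced.stats) ** weight
            null = _null_es(rng, absr_w, len(reduced), k, nperm)
            p, _ = _perm_p(es, null, smoothed=True, absolute=False)
            if p > dependence_p:
                parent_of[cand] = best
            else:
                still.append(cand)
        remaining = still
    return main, parent_of
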