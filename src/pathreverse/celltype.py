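"""Directional cell-type marker enrichment.

Differentially expressed genes are split into up- and down-regulated lists
(strict nominal p < alpha, nonzero fold change) and each list is tested for
overlap with every cell-type marker list using the upper-tail
hypergeometric distribution, with Bonferroni correction across all
(list x direction) tests in the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .types import DOWN, UP, CellTypeMarkers

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionalGeneLists",
    "split_de_genes",
    "hypergeom_test",
    "run_celltype_enrichment",
    "best_per_celltype",
]


@dataclass(frozen=True)
class DirectionalGeneLists:
    """Up/down differentially expressed gene sets over a tested universe."""

    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ConfigError("up and down gene lists overlap")
        if not (self.up | self.down) <= self.universe:
            raise ConfigError("directional lists must be subsets of the universe")


def split_de_genes(table: pd.DataFrame, alpha: float = 0.05) -> DirectionalGeneLists:
    """Split a DE table into up/down lists at strict nominal p < ``alpha``.

    Direction comes from the fold-change sign; genes with exactly zero
    fold change are excluded from both lists.  The universe is every gene
    in the table.
    """
    sig = table["pvalue"] < alpha
    up = table.loc[sig & (table["log2fc"] > 0), "gene"]
    down = table.loc[sig & (table["log2fc"] < 0), "gene"]
    return DirectionalGeneLists(
        frozenset(up), frozenset(down), frozenset(table["gene"])
    )


def hypergeom_test(list_genes, markers, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test.

    P(X >= overlap) drawing ``|list_genes|`` genes from a universe of
    ``|universe|`` containing ``|markers & universe|`` marked genes.
    Markers outside the universe are ignored.
    """
    universe = set(universe)
    if not universe:
        raise ConfigError("empty universe")
    list_genes = set(list_genes)
    if not list_genes <= universe:
        raise ConfigError("gene list must be a subset of the universe")
    markers_in = set(markers) & universe
    if not markers_in:
        logger.warning("marker set does not intersect the universe")
        return 0, 1.0
    overlap = len(list_genes & markers_in)
    # sf(k-1) = P(X >= k)
    p = float(
        sps.hypergeom.sf(overlap - 1, len(universe), len(markers_in), len(list_genes))
    )
    return overlap, min(p, 1.0)


def run_celltype_enrichment(
    table: pd.DataFrame,
    marker_lists: list[CellTypeMarkers],
    alpha: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Directional marker enrichment for one dataset.

    One record per (marker list x direction); the Bonferroni multiplier is
    the total number of tests, 2 x number of marker lists.  ``significant``
    requires Bonferroni-corrected p < ``bonferroni_alpha`` (strict).
    """
    if not marker_lists:
        raise ConfigError("no marker lists supplied")
    lists = split_de_genes(table, alpha=alpha)
    n_tests = 2 * len(marker_lists)
    rows = []
    for m in marker_lists:
        markers_in = set(m.genes) & lists.universe
        for direction, genes in ((UP, lists.up), (DOWN, lists.down)):
            overlap, p = hypergeom_test(genes, m.genes, lists.universe)
            p_bonf = min(1.0, p * n_tests)
            rows.append(
                {
                    "cell_type": m.cell_type,
                    "source_label": m.source_label,
                    "direction": direction,
                    "overlap": overlap,
                    "list_size": len(genes),
                    "marker_size": len(markers_in),
                    "universe_size": len(lists.universe),
                    "pvalue": p,
                    "p_bonferroni": p_bonf,
                    "significant": p_bonf < bonferroni_alpha,
                }
            )
    return pd.DataFrame(rows)


def best_per_celltype(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type summary keeping the most significant record.

    When a cell type has several source lists (or is enriched in both
    directions) the smallest p-value wins, mirroring the convention of
    showing the most significant enrichment per cell type.
    """
    if records.empty:
        return records
    idx = records.groupby("cell_type")["pvalue"].idxmin()
    out = records.loc[np.sort(idx.to_numpy())].reset_index(drop=True)
    return out
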