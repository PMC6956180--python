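"""Orchestration of the two workflows.

Disease side: per-dataset pathway enrichment and cell-type enrichment,
then the cross-dataset pathway frequency table.  Drug side: quality and
repurposeability filtering, per-signature enrichment, direction profiles,
reversal matching, and compound roll-up.  Both write tab-separated outputs
plus a key-value manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import io as prio
from .celltype import best_per_celltype, run_celltype_enrichment
from .connectivity import (
    drug_pathway_frequency,
    filter_candidates,
    match_reversal,
    rollup_compounds,
    significant_directions,
    tabulate_across_datasets,
)
from .errors import ConfigError, EmptyInputError
from .gsea import EnrichmentTable, run_enrichment
from .types import GeneSetCollection, ReversalQuery, SignatureMetadata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_disease_side", "run_drug_side", "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for a full run.

    Defaults follow the published protocol: set-size bounds 15-500,
    10,000 permutations for disease datasets and 1000 for the (much
    larger) drug panels, FDR 0.05 for pathway calls, quality threshold
    0.15, ES weight 1, and conditional-dependence p 0.05 for collapsing.
    """

    min_size: int = 15
    max_size: int = 500
    nperm_disease: int = 10_000
    nperm_drug: int = 1000
    fdr: float = 0.05
    min_quality: float = 0.15
    weight: float = 1.0
    dependence_p: float = 0.05
    celltype_alpha: float = 0.05
    seed: int = 0
    require_repurposeable: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain ``key = value`` text config; unknown keys are
        rejected rather than ignored."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{ln}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ConfigError(f"{path}:{ln}: unknown config key {key!r}")
                if known[key] in ("int", int):
                    kwargs[key] = int(value)
                elif known[key] in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


def write_manifest(path, entries: dict) -> None:
    """Key-value run manifest (inputs, parameters, seeds)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")


def _write_enrichment(table: EnrichmentTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "# "
            + " ".join(f"{k}={v}" for k, v in sorted(table.params.items()))
            + "\n"
        )
        rec = table.records.copy()
        if "leading_edge" in rec.columns and len(rec):
            rec["leading_edge"] = rec["leading_edge"].map(
                lambda s: ",".join(sorted(s))
            )
        rec.insert(0, "dataset_id", table.dataset_id)
        rec.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_disease_side(
    config: RunConfig,
    de_tables: dict[str, pd.DataFrame],
    collection: GeneSetCollection,
    marker_lists=None,
    groups: dict[str, str] | None = None,
    outdir=None,
):
    """Disease workflow: enrichment per dataset, optional cell-type
    enrichment, and the cross-dataset pathway frequency table.

    ``de_tables`` maps dataset id -> DE table.  Returns
    ``(enrichment_tables, celltype_records, frequency_table)``;
    ``celltype_records`` maps dataset id -> records (empty dict when no
    marker lists are given).  With ``outdir`` every output is written as
    TSV together with a manifest.
    """
    if not de_tables:
        raise EmptyInputError("no differential-expression tables supplied")
    enrichment_tables: list[EnrichmentTable] = []
    celltype_records: dict[str, pd.DataFrame] = {}
    for dataset_id, table in de_tables.items():
        try:
            ranked = prio.rank_from_de(table, signature_id=dataset_id, stat_kind="t")
            et = run_enrichment(
                ranked,
                collection,
                nperm=config.nperm_disease,
                seed=config.seed,
                min_size=config.min_size,
                max_size=config.max_size,
                weight=config.weight,
            )
            enrichment_tables.append(et)
            n_sig = int((et.records["padj"] <= config.fdr).sum()) if len(et) else 0
            logger.info(
                "%s: %d genes ranked, %d pathways retained, %d significant",
                dataset_id,
                len(ranked),
                len(et),
                n_sig,
            )
            if marker_lists:
                celltype_records[dataset_id] = run_celltype_enrichment(
                    table, marker_lists, alpha=config.celltype_alpha
                )
        except Exception as exc:
            raise type(exc)(f"dataset {dataset_id!r}: {exc}") from exc
    freq = tabulate_across_datasets(enrichment_tables, fdr=config.fdr, groups=groups)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for et in enrichment_tables:
            _write_enrichment(et, outdir / f"enrichment_{et.dataset_id}.tsv")
        for dataset_id, rec in celltype_records.items():
            rec.to_csv(
                outdir / f"celltype_{dataset_id}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            best_per_celltype(rec).to_csv(
                outdir / f"celltype_{dataset_id}_best.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
        freq.to_csv(
            outdir / "pathway_frequency.tsv",
            sep="\t",
            index=False,
            lineterminator="\n",
        )
        write_manifest(
            outdir / "manifest.txt",
            {
                "workflow": "disease",
                "datasets": ",".join(de_tables),
                "n_gene_sets": len(collection),
                **{
                    k: getattr(config, k)
                    for k in (
                        "min_size",
                        "max_size",
                        "nperm_disease",
                        "fdr",
                        "weight",
                        "celltype_alpha",
                        "seed",
                    )
                },
            },
        )
    return enrichment_tables, celltype_records, freq


def run_drug_side(
    config: RunConfig,
    matrix: pd.DataFrame,
    metadata: list[SignatureMetadata],
    collection: GeneSetCollection,
    query: ReversalQuery,
    allowed_phases: set[str] | None = None,
    outdir=None,
):
    """Drug workflow: filter signatures, enrich, profile, match, roll up.

    Returns ``(summary, profiles, matching_ids)`` where ``summary`` is the
    compound-level candidate table after the optional clinical-phase
    filter.  An empty post-filter signature list yields an empty summary
    with a warning rather than an error.
    """
    for pathway in query.targets:
        if pathway not in collection:
            raise ConfigError(f"query pathway {pathway!r} not in the gene set collection")
    kept = prio.filter_by_quality(metadata, min_quality=config.min_quality)
    if config.require_repurposeable:
        kept = prio.filter_repurposeable(kept)
    if not kept:
        logger.warning("no signature passed the quality filter; empty result")
        empty = rollup_compounds([], metadata)
        return empty, [], []
    profiles = []
    for m in kept:
        ranked = prio.rank_from_matrix(matrix, m.signature_id, stat_kind="zscore")
        et = run_enrichment(
            ranked,
            collection,
            nperm=config.nperm_drug,
            seed=config.seed,
            min_size=config.min_size,
            max_size=config.max_size,
            weight=config.weight,
        )
        profiles.append(significant_directions(et, fdr=config.fdr))
    matching = match_reversal(profiles, query)
    logger.info(
        "drug side: %d/%d signatures matched the %d-pathway query",
        len(matching),
        len(profiles),
        len(query),
    )
    summary = rollup_compounds(matching, kept)
    summary = filter_candidates(summary, allowed_phases=allowed_phases)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(
            outdir / "candidates.tsv", sep="\t", index=False, lineterminator="\n"
        )
        drug_pathway_frequency(profiles, kept).to_csv(
            outdir / "drug_pathway_frequency.tsv",
            sep="\t",
            index=False,
            lineterminator="\n",
        )
        prio.write_reversal_query(query, outdir / "query.tsv")
        write_manifest(
            outdir / "manifest.txt",
            {
                "workflow": "drug",
                "n_signatures_input": len(metadata),
                "n_signatures_kept": len(kept),
                "n_matching": len(matching),
                "n_gene_sets": len(collection),
                **{
                    k: getattr(config, k)
                    for k in (
                        "min_size",
                        "max_size",
                        "nperm_drug",
                        "fdr",
                        "min_quality",
                        "weight",
                        "seed",
                    )
                },
            },
        )
    return summary, profiles, matching
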