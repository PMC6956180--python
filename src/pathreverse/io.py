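"""File formats and signature construction.

Everything is plain tab-separated UTF-8 text:

* differential-expression tables: columns ``gene, log2fc, stat, pvalue, padj``
* gene set collections: standard GMT (name TAB description TAB members...)
* signature matrices: genes x signatures, first column ``gene``
* signature metadata: one row per signature id
* cell-type marker lists: two or three columns (cell_type[, source], gene)

This module also owns the CMap amplitude statistic and the quality /
repurposeability filters applied to drug signatures before enrichment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, FormatError, SignatureLookupError
from .types import (
    CellTypeMarkers,
    GeneSet,
    GeneSetCollection,
    RankedSignature,
    ReversalQuery,
    SignatureMetadata,
)

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "stat", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# amplitude

def compute_amplitude(t: float, c: float) -> float:
    """CMap amplitude ``a = (t - c) / ((t + c) / 2)``.

    ``t`` and ``c`` are thresholded (non-negative) average-difference
    expression values for treatment and control.  a = 0 means no
    differential expression (including the degenerate t = c = 0 case,
    returned as 0 by convention), a > 0 increased expression upon
    treatment; the range for positive inputs is (-2, 2).  An amplitude of
    0.67 corresponds to a two-fold induction.
    """
    t = float(t)
    c = float(c)
    if t < 0 or c < 0:
        raise ConfigError(f"amplitude inputs must be non-negative, got t={t}, c={c}")
    if t == c:
        return 0.0
    return (t - c) / ((t + c) / 2.0)


def collapse_probes(
    table: pd.DataFrame, gene_col: str = "gene", stat_col: str = "stat"
) -> pd.DataFrame:
    """Collapse duplicate symbols (e.g. probe sets) keeping the row with the
    largest ``|stat|``; ties keep the first occurrence."""
    order = table.assign(_a=table[stat_col].abs(), _i=np.arange(len(table)))
    order = order.sort_values(["_a", "_i"], ascending=[False, True], kind="mergesort")
    out = order.drop_duplicates(subset=gene_col, keep="first")
    return out.sort_values("_i", kind="mergesort").drop(columns=["_a", "_i"])


# ---------------------------------------------------------------------------
# differential-expression tables

def read_de_table(path) -> pd.DataFrame:
    """Read a disease differential-expression table.

    Symbols are uppercased and stripped; rows with missing statistics are
    dropped (with a logged count); duplicate symbols keep the row with the
    largest ``|stat|``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[DE_COLUMNS].copy()
    df["gene"] = df["gene"].str.strip().str.upper()
    n_bad = int(df["stat"].isna().sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with missing stat", path, n_bad)
        df = df.dropna(subset=["stat"])
    if df.empty:
        raise EmptyInputError(f"{path}: no usable rows")
    before = len(df)
    df = collapse_probes(df)
    if len(df) < before:
        logger.info("%s: collapsed %d duplicate symbols", path, before - len(df))
    return df.reset_index(drop=True)


def write_de_table(df: pd.DataFrame, path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has no members")
            name, desc, *members = parts
            members = [m.strip().upper() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{ln}: GMT set {name!r} is empty")
            if name in seen:
                raise FormatError(f"{path}:{ln}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, desc, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# signature matrices + metadata

def read_signature_matrix(path) -> pd.DataFrame:
    """Genes x signatures matrix; first column ``gene``, symbols uppercased."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing 'gene' column")
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbols in matrix")
    return df.set_index("gene")


def write_signature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


_META_COLUMNS = [
    "signature_id",
    "compound",
    "cell_line",
    "dose",
    "time",
    "quality",
    "clinical_phase",
    "repurposeable",
]


def read_metadata(path) -> list[SignatureMetadata]:
    # keep_default_na=False so empty text fields round-trip as "" not NaN
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    out = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.signature_id in seen:
            raise FormatError(f"{path}: duplicate signature_id {row.signature_id!r}")
        seen.add(row.signature_id)
        quality = None if row.quality == "" else float(row.quality)
        out.append(
            SignatureMetadata(
                signature_id=row.signature_id,
                compound=row.compound,
                cell_line=row.cell_line,
                dose=row.dose,
                time=row.time,
                quality=quality,
                clinical_phase=row.clinical_phase or "unknown",
                repurposeable=row.repurposeable.strip().lower() in ("true", "1", "yes"),
            )
        )
    return out


def write_metadata(metadata: list[SignatureMetadata], path) -> None:
    df = pd.DataFrame(
        [
            {
                "signature_id": m.signature_id,
                "compound": m.compound,
                "cell_line": m.cell_line,
                "dose": m.dose,
                "time": m.time,
                "quality": m.quality,
                "clinical_phase": m.clinical_phase,
                "repurposeable": m.repurposeable,
            }
            for m in metadata
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# marker lists and queries

def read_markers(path) -> list[CellTypeMarkers]:
    """Marker lists as (cell_type, source_label, gene) or (cell_type, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["cell_type", "gene"]
        df["source_label"] = df["cell_type"]
    elif df.shape[1] == 3:
        df.columns = ["cell_type", "source_label", "gene"]
    else:
        raise FormatError(f"{path}: expected 2 or 3 tab-separated columns")
    df["gene"] = df["gene"].str.strip().str.upper()
    out = []
    for (ct, src), grp in df.groupby(["cell_type", "source_label"], sort=True):
        out.append(CellTypeMarkers(ct, src, frozenset(grp["gene"])))
    return out


def write_markers(markers: list[CellTypeMarkers], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in markers:
            for g in sorted(m.genes):
                fh.write(f"{m.cell_type}\t{m.source_label}\t{g}\n")


def read_reversal_query(path) -> ReversalQuery:
    """Two-column file: pathway TAB direction (UP/DOWN)."""
    targets = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'pathway<TAB>direction'")
            targets[parts[0]] = parts[1].strip().upper()
    return ReversalQuery(targets)


def write_reversal_query(query: ReversalQuery, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p, d in query.targets.items():
            fh.write(f"{p}\t{d}\n")


# ---------------------------------------------------------------------------
# ranked signatures

def _ranked_from_frame(
    sub: pd.DataFrame, signature_id: str, stat_kind: str
) -> RankedSignature:
    # stable sort: ties keep input row order, which is reproducible across
    # re-reads of the same file
    sub = sub.sort_values("stat", ascending=False, kind="mergesort")
    return RankedSignature(
        signature_id,
        sub["gene"].tolist(),
        sub["stat"].to_numpy(dtype=float),
        stat_kind,
    )


def rank_from_de(
    table: pd.DataFrame, signature_id: str = "de", stat_kind: str = "t"
) -> RankedSignature:
    """Ranked signature from a DE table: genes sorted by ``stat`` descending,
    ties broken by input row order (stable sort)."""
    if table.empty:
        raise EmptyInputError("cannot rank an empty DE table")
    return _ranked_from_frame(table[["gene", "stat"]], signature_id, stat_kind)


def rank_from_matrix(
    matrix: pd.DataFrame, signature_id: str, stat_kind: str = "zscore"
) -> RankedSignature:
    """Ranked signature from one column of a genes x signatures matrix.

    Genes with a missing value in that column are excluded (logged)."""
    if signature_id not in matrix.columns:
        raise SignatureLookupError(f"signature {signature_id!r} not in matrix")
    col = matrix[signature_id]
    n_bad = int(col.isna().sum())
    if n_bad:
        logger.warning("%s: excluded %d genes with missing values", signature_id, n_bad)
        col = col.dropna()
    if col.empty:
        raise EmptyInputError(f"signature {signature_id!r} has no usable values")
    sub = pd.DataFrame({"gene": col.index, "stat": col.to_numpy(dtype=float)})
    return _ranked_from_frame(sub, signature_id, stat_kind)


# ---------------------------------------------------------------------------
# signature-level filters

def filter_by_quality(
    metadata: list[SignatureMetadata], min_quality: float = 0.15
) -> list[SignatureMetadata]:
    """Keep signatures whose reproducibility score is present and
    >= ``min_quality`` (inclusive); records without a score are dropped."""
    no_score = sum(1 for m in metadata if m.quality is None)
    if no_score:
        logger.info("quality filter: dropped %d records without a score", no_score)
    kept = [m for m in metadata if m.quality is not None and m.quality >= min_quality]
    logger.info(
        "quality filter (>= %.3g): kept %d of %d signatures",
        min_quality,
        len(kept),
        len(metadata),
    )
    return kept


def filter_repurposeable(metadata: list[SignatureMetadata]) -> list[SignatureMetadata]:
    """Keep signatures of repurposeable compounds (marketed, in trials, or
    preclinical with good ADME, per Drug Repurposing Hub-style annotation)."""
    return [m for m in metadata if m.repurposeable]
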