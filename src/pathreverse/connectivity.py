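"""Cross-dataset tabulation and pathway-reversal matching.

Disease side: turn per-dataset enrichment tables into direction profiles
and tabulate how many datasets call each pathway up or down.  Drug side:
build a direction profile per signature, match profiles against a reversal
query (full conjunction over the queried pathways), roll signatures up to
compounds, and report per-compound pathway-call frequencies.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import ConfigError, SignatureLookupError
from .gsea import EnrichmentTable
from .types import DOWN, UP, DirectionProfile, ReversalQuery, SignatureMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "significant_directions",
    "tabulate_across_datasets",
    "match_reversal",
    "rollup_compounds",
    "drug_pathway_frequency",
    "filter_candidates",
]


def significant_directions(table: EnrichmentTable, fdr: float = 0.05) -> DirectionProfile:
    """Pathway direction calls at FDR <= ``fdr`` (inclusive).

    Direction is the sign of the enrichment score; a significant record
    with ES exactly zero is directionless and excluded with a warning.
    """
    calls: dict[str, str] = {}
    for row in table.records.itertuples(index=False):
        if row.padj > fdr:
            continue
        if row.es > 0:
            calls[row.pathway] = UP
        elif row.es < 0:
            calls[row.pathway] = DOWN
        else:
            logger.warning(
                "%s: pathway %s significant with ES = 0; no direction assigned",
                table.dataset_id,
                row.pathway,
            )
    return DirectionProfile(table.dataset_id, calls)


def tabulate_across_datasets(
    tables: list[EnrichmentTable],
    fdr: float = 0.05,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pathway counts of datasets calling it UP or DOWN.

    Each dataset contributes at most one direction per pathway.  With
    ``groups`` (dataset_id -> group label, e.g. brain region) the counts
    are additionally broken out per group; per-group counts sum to the
    global ones.
    """
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate dataset_id among enrichment tables")
    rows: dict[str, dict] = {}
    for t in tables:
        profile = significant_directions(t, fdr=fdr)
        group = groups.get(t.dataset_id) if groups else None
        for pathway, direction in profile.calls.items():
            rec = rows.setdefault(
                pathway,
                {
                    "pathway": pathway,
                    "n_up": 0,
                    "n_down": 0,
                    "datasets_up": [],
                    "datasets_down": [],
                    "_groups": {},
                },
            )
            key = "up" if direction == UP else "down"
            rec[f"n_{key}"] += 1
            rec[f"datasets_{key}"].append(t.dataset_id)
            if group is not None:
                gcounts = rec["_groups"].setdefault(group, {"up": 0, "down": 0})
                gcounts[key] += 1
    out = []
    for rec in rows.values():
        flat = {k: v for k, v in rec.items() if k != "_groups"}
        if groups:
            for g, counts in sorted(rec["_groups"].items()):
                flat[f"n_up[{g}]"] = counts["up"]
                flat[f"n_down[{g}]"] = counts["down"]
        out.append(flat)
    df = pd.DataFrame(out)
    if df.empty:
        return pd.DataFrame(
            columns=["pathway", "n_up", "n_down", "datasets_up", "datasets_down"]
        )
    return df.sort_values(
        ["n_up", "n_down", "pathway"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


def match_reversal(
    profiles: list[DirectionProfile], query: ReversalQuery
) -> list[str]:
    """Signature ids whose profile calls every queried pathway in exactly
    the desired direction (the full combination; a single miss disqualifies)."""
    return [p.signature_id for p in profiles if p.matches(query)]


def rollup_compounds(
    matching_ids: list[str], metadata: list[SignatureMetadata]
) -> pd.DataFrame:
    """Compound-level summary of signature matches.

    A compound qualifies when at least one of its signatures matches; the
    summary reports matching and total signature counts, the distinct cell
    lines among matching signatures, and the clinical phase, so stricter
    users can re-threshold on the match frequency.
    """
    by_id = {m.signature_id: m for m in metadata}
    unknown = [i for i in matching_ids if i not in by_id]
    if unknown:
        raise SignatureLookupError(f"unknown signature ids: {unknown[:5]}")
    matching = set(matching_ids)
    rows: dict[str, dict] = {}
    for m in metadata:
        rec = rows.setdefault(
            m.compound,
            {
                "compound": m.compound,
                "n_matching": 0,
                "n_signatures": 0,
                "cell_lines": set(),
                "clinical_phase": m.clinical_phase,
            },
        )
        rec["n_signatures"] += 1
        if m.signature_id in matching:
            rec["n_matching"] += 1
            rec["cell_lines"].add(m.cell_line)
    out = [r for r in rows.values() if r["n_matching"] > 0]
    for r in out:
        r["cell_lines"] = ",".join(sorted(r["cell_lines"]))
        r["match_frequency"] = r["n_matching"] / r["n_signatures"]
    df = pd.DataFrame(
        out,
        columns=[
            "compound",
            "n_matching",
            "n_signatures",
            "match_frequency",
            "cell_lines",
            "clinical_phase",
        ],
    )
    return df.sort_values(
        ["n_matching", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def drug_pathway_frequency(
    profiles: list[DirectionProfile], metadata: list[SignatureMetadata]
) -> pd.DataFrame:
    """How often each compound calls each pathway in each direction.

    One row per (compound, pathway, direction) with the count of that
    compound's signatures making the call and its total signature count;
    pathways a compound never calls have no row.
    """
    compound_of = {m.signature_id: m.compound for m in metadata}
    totals: dict[str, int] = {}
    for m in metadata:
        totals[m.compound] = totals.get(m.compound, 0) + 1
    counts: dict[tuple[str, str, str], int] = {}
    for p in profiles:
        compound = compound_of.get(p.signature_id)
        if compound is None:
            raise SignatureLookupError(f"signature {p.signature_id!r} not in metadata")
        for pathway, direction in p.calls.items():
            key = (compound, pathway, direction)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "compound": c,
            "pathway": pw,
            "direction": d,
            "n_calls": n,
            "n_signatures": totals[c],
            "frequency": n / totals[c],
        }
        for (c, pw, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["compound", "pathway", "direction", "n_calls", "n_signatures", "frequency"],
    )


def filter_candidates(
    summary: pd.DataFrame,
    allowed_phases: set[str] | None = None,
    require_flag: str | None = None,
    annotations: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Keep candidate compounds by clinical phase and optional annotation.

    ``allowed_phases`` keeps compounds whose clinical phase is in the set
    (None = no phase filter; empty set = nothing passes).  ``require_flag``
    names a user-supplied annotation (e.g. CNS penetrance) and
    ``annotations`` maps flag name -> set of compounds carrying it.
    """
    out = summary
    if allowed_phases is not None:
        out = out[out["clinical_phase"].isin(allowed_phases)]
    if require_flag is not None:
        flagged = (annotations or {}).get(require_flag, set())
        out = out[out["compound"].isin(flagged)]
    return out.reset_index(drop=True)
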