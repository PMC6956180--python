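"""Synthetic disease, drug, gene-set and cell-type data with planted truth.

The generator emulates the shape of the real inputs the pipeline consumes —
postmortem-brain differential-expression tables, L1000-style z-score
signature panels with metadata, KEGG-style gene set collections, and
cell-type marker lists — at desk scale, with known planted structure so
every downstream stage can be checked against ground truth:

* disease signatures draw a per-gene statistic from Normal(0, noise_sd)
  and shift every member of a planted pathway by +/- effect_size;
* drug panels plant "reverser" compounds whose signatures shift each
  queried pathway's members in the query's desired direction;
* marker lists include one designated cell type drawn mostly from genes
  with a positive planted shift.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so identical configs reproduce identical outputs bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, SizingError
from .gsea import bh_adjust
from .types import (
    DOWN,
    UP,
    CLINICAL_PHASES,
    CellTypeMarkers,
    GeneSet,
    GeneSetCollection,
    ReversalQuery,
    SignatureMetadata,
)

__all__ = [
    "SimulationConfig",
    "make_pathway_collection",
    "simulate_disease_signature",
    "simulate_drug_panel",
    "simulate_celltype_markers",
]

_CELL_LINES = ("A375", "HA1E", "MCF7", "PC3", "VCAP")
_DOSES = ("0.1 uM", "1 uM", "10 uM")
_TIMES = ("6 h", "24 h")
_PHASES = ("Launched", "Phase 3", "Phase 2", "Phase 1", "Preclinical")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    ``planted_disease`` maps pathway name -> (direction, effect_size): the
    mean shift, in statistic units, applied to every member gene of that
    pathway in disease signatures.  ``planted_reversers`` names the
    compounds whose signatures oppose the reversal query.  The default
    sizes mirror a single postmortem cohort analysed against a
    KEGG-sized collection: 5000 measured genes, 50 pathways of 20-100
    genes, unit-variance statistics.
    """

    n_genes: int = 5000
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (20, 100)
    overlap_fraction: float = 0.0
    planted_disease: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_compounds: int = 100
    signatures_per_compound: int = 3
    planted_reversers: frozenset[str] = frozenset()
    reverser_effect_size: float = 2.0
    noise_sd: float = 1.0
    quality_range: tuple[float, float] = (0.2, 0.95)
    n_celltypes: int = 5
    markers_per_type: int = 100
    marker_planted_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 1:
            raise ConfigError("n_genes and n_pathways must be positive")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid pathway_size_range {self.pathway_size_range}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigError("overlap_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.reverser_effect_size < 0:
            raise ConfigError("reverser_effect_size must be >= 0")
        for name, (direction, delta) in self.planted_disease.items():
            if direction not in (UP, DOWN):
                raise ConfigError(f"planted pathway {name!r}: bad direction")
            if delta < 0:
                raise ConfigError(f"planted pathway {name!r}: negative effect size")
        qlo, qhi = self.quality_range
        if not -1.0 <= qlo <= qhi <= 1.0:
            raise ConfigError("quality_range must be ordered and within [-1, 1]")
        object.__setattr__(self, "planted_reversers", frozenset(self.planted_reversers))
        object.__setattr__(
            self, "planted_disease", dict(self.planted_disease)
        )

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so each generator call is independently seeded."""
        tag = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, tag])
        )

    def gene_universe(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_genes + 1)]

    def compound_names(self) -> list[str]:
        return [f"CPD{i:04d}" for i in range(1, self.n_compounds + 1)]


def make_pathway_collection(config: SimulationConfig) -> GeneSetCollection:
    """Named gene sets over a synthetic symbol universe.

    With ``overlap_fraction`` f = 0 all sets are pairwise disjoint.  With
    f > 0 each set draws about a fraction f of its members from one shared
    pool sized to the largest shared draw, which makes the expected
    pairwise overlap approximately f of a set's size (an approximation,
    documented rather than exact).
    """
    rng = config.rng("pathways")
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    shared_counts = np.round(config.overlap_fraction * sizes).astype(int)
    private_counts = sizes - shared_counts
    pool_size = int(shared_counts.max()) if config.overlap_fraction > 0 else 0
    need = int(private_counts.sum()) + pool_size
    if need > config.n_genes:
        raise SizingError(
            f"need {need} distinct genes for {config.n_pathways} pathways "
            f"but the universe has only {config.n_genes}"
        )
    genes = np.array(config.gene_universe(), dtype=object)
    perm = rng.permutation(config.n_genes)
    pool = perm[:pool_size]
    cursor = pool_size
    sets = []
    for i in range(config.n_pathways):
        members = list(perm[cursor : cursor + private_counts[i]])
        cursor += int(private_counts[i])
        if shared_counts[i] > 0:
            members.extend(rng.choice(pool, size=shared_counts[i], replace=False))
        sets.append(
            GeneSet(
                f"PW{i + 1:03d}",
                "synthetic pathway",
                frozenset(genes[members]),
            )
        )
    return GeneSetCollection(sets)


def _planted_shifts(
    config: SimulationConfig, collection: GeneSetCollection, gene_pos: dict[str, int]
) -> np.ndarray:
    shift = np.zeros(config.n_genes)
    for name, (direction, delta) in config.planted_disease.items():
        if name not in collection:
            raise ConfigError(f"planted pathway {name!r} not in the collection")
        sign = 1.0 if direction == UP else -1.0
        for g in collection[name].members:
            shift[gene_pos[g]] += sign * delta
    return shift


def simulate_disease_signature(
    config: SimulationConfig,
    collection: GeneSetCollection,
    dataset_id: str = "synthetic",
) -> pd.DataFrame:
    """A disease differential-expression table with planted pathway shifts.

    Per-gene statistic = Normal(0, noise_sd) plus the planted shift for
    members of planted pathways; two-sided normal-tail p-values (on the
    statistic standardised by noise_sd, so null p-values are uniform);
    log2 fold change proportional to the statistic so signs agree; BH
    adjusted p-values included.  The extra ``planted_shift`` column records
    ground truth and is not part of the on-disk format.
    """
    rng = config.rng(f"disease:{dataset_id}")
    genes = config.gene_universe()
    gene_pos = {g: i for i, g in enumerate(genes)}
    shift = _planted_shifts(config, collection, gene_pos)
    stat = rng.normal(0.0, config.noise_sd, size=config.n_genes) + shift
    pvalue = 2.0 * sps.norm.sf(np.abs(stat) / config.noise_sd)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": 0.25 * stat,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "planted_shift": shift,
        }
    )


def simulate_drug_panel(
    config: SimulationConfig,
    collection: GeneSetCollection,
    query: ReversalQuery,
) -> tuple[pd.DataFrame, list[SignatureMetadata]]:
    """A z-score signature matrix plus metadata, with planted reversers.

    Every signature of a planted reverser compound shifts each queried
    pathway's member genes by ``reverser_effect_size`` in the query's
    desired direction; all other entries are Normal(0, noise_sd) noise.
    Metadata carries compound, cell line, dose, time, a quality
    (reproducibility) score drawn uniformly from ``quality_range``, and a
    clinical phase label.
    """
    for p in query.targets:
        if p not in collection:
            raise ConfigError(f"query pathway {p!r} not in the collection")
    compounds = config.compound_names()
    unknown = config.planted_reversers - set(compounds)
    if unknown:
        raise ConfigError(f"planted reversers not among compounds: {sorted(unknown)}")
    rng = config.rng("drugs")
    genes = config.gene_universe()
    gene_pos = {g: i for i, g in enumerate(genes)}
    query_shift = np.zeros(config.n_genes)
    for name, direction in query.targets.items():
        sign = 1.0 if direction == UP else -1.0
        for g in collection[name].members:
            query_shift[gene_pos[g]] += sign * config.reverser_effect_size

    n_sigs = config.n_compounds * config.signatures_per_compound
    matrix = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_sigs))
    metadata: list[SignatureMetadata] = []
    col = 0
    columns = []
    qlo, qhi = config.quality_range
    for ci, compound in enumerate(compounds):
        is_reverser = compound in config.planted_reversers
        for j in range(config.signatures_per_compound):
            if is_reverser:
                matrix[:, col] += query_shift
            sig_id = f"{compound}_S{j + 1}"
            columns.append(sig_id)
            metadata.append(
                SignatureMetadata(
                    signature_id=sig_id,
                    compound=compound,
                    cell_line=_CELL_LINES[(ci + j) % len(_CELL_LINES)],
                    dose=_DOSES[j % len(_DOSES)],
                    time=_TIMES[j % len(_TIMES)],
                    quality=float(rng.uniform(qlo, qhi)),
                    clinical_phase=_PHASES[ci % len(_PHASES)],
                    repurposeable=True,
                )
            )
            col += 1
    frame = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=columns)
    return frame, metadata


def simulate_celltype_markers(
    config: SimulationConfig, de_table: pd.DataFrame
) -> list[CellTypeMarkers]:
    """Marker gene lists for synthetic cell types.

    The first type (``CT01_PLANTED_UP``) draws ``marker_planted_fraction``
    of its markers from genes with a positive planted shift in
    ``de_table`` (falling back to fewer if the table has fewer such
    genes); the remaining types sample uniformly from the universe, so
    they carry no directional signal.
    """
    if "planted_shift" not in de_table.columns:
        raise ConfigError("de_table was not produced by simulate_disease_signature")
    if config.markers_per_type > config.n_genes:
        raise SizingError(
            f"markers_per_type {config.markers_per_type} exceeds the "
            f"universe of {config.n_genes} genes"
        )
    if config.n_celltypes == 0:
        return []
    rng = config.rng("markers")
    genes = de_table["gene"].to_numpy()
    up_genes = de_table.loc[de_table["planted_shift"] > 0, "gene"].to_numpy()
    out: list[CellTypeMarkers] = []
    for t in range(config.n_celltypes):
        if t == 0 and len(up_genes) > 0:
            n_up = min(
                int(round(config.marker_planted_fraction * config.markers_per_type)),
                len(up_genes),
            )
            chosen = set(rng.choice(up_genes, size=n_up, replace=False))
            rest_pool = np.array([g for g in genes if g not in chosen], dtype=object)
            n_rest = config.markers_per_type - n_up
            chosen |= set(rng.choice(rest_pool, size=n_rest, replace=False))
            name = "CT01_PLANTED_UP"
        else:
            chosen = set(rng.choice(genes, size=config.markers_per_type, replace=False))
            name = f"CT{t + 1:02d}"
        out.append(CellTypeMarkers(name, "synthetic", frozenset(chosen)))
    return out
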