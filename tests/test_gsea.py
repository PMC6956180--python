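"""Enrichment score, permutation p-values, BH, and pathway collapsing."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathreverse import (
    ConfigError,
    EmptyInputError,
    GeneSet,
    GeneSetCollection,
    RankedSignature,
    bh_adjust,
    collapse_pathways,
    enrichment_score,
    permutation_pvalue,
    run_enrichment,
)

from oracles import (
    bh_stepup,
    brute_force_es,
    exhaustive_null_count,
    random_ranked,
)


# ---------------------------------------------------------------------------
# enrichment score


def test_worked_example_extremes(six_gene_ranked):
    """A set holding the two most up-regulated genes attains ES = 1 with
    itself as the leading edge; the mirror set attains ES = -1."""
    es, lead = enrichment_score(six_gene_ranked, {"g1", "g2"})
    assert es == pytest.approx(1.0)
    assert lead == {"g1", "g2"}
    es, lead = enrichment_score(six_gene_ranked, {"g5", "g6"})
    assert es == pytest.approx(-1.0)
    assert lead == {"g5", "g6"}


def test_worked_example_running_sum_values(six_gene_ranked):
    """Intermediate case: hits at ranks 1 and 3 with increments 3/4 and 1/4,
    miss decrement 1/4; the walk peaks at 0.75 right after the first hit."""
    es, lead = enrichment_score(six_gene_ranked, {"g1", "g3"})
    assert es == pytest.approx(0.75)
    assert lead == {"g1"}


def test_es_matches_brute_force_on_random_universes():
    """Vectorised ES equals the naive full-walk evaluation for every proper
    non-empty subset of random small universes."""
    rng = np.random.default_rng(2024)
    for _ in range(20):
        n = int(rng.integers(3, 9))
        genes, stats = random_ranked(rng, n)
        ranked = RankedSignature("r", genes, stats)
        for size in range(1, n):
            for combo in itertools.combinations(genes, size):
                es, _ = enrichment_score(ranked, set(combo))
                assert es == pytest.approx(
                    brute_force_es(genes, stats, combo), abs=1e-12
                )


def test_es_antisymmetric_under_stat_negation():
    """Negating all statistics (reversing the ranking) negates the ES."""
    rng = np.random.default_rng(5)
    genes, stats = random_ranked(rng, 40)
    ranked = RankedSignature("f", genes, stats)
    flipped = RankedSignature("r", genes[::-1], -stats[::-1])
    for _ in range(25):
        members = set(rng.choice(genes, size=int(rng.integers(2, 20)), replace=False))
        es_f, _ = enrichment_score(ranked, members)
        es_r, _ = enrichment_score(flipped, members)
        assert es_r == pytest.approx(-es_f, abs=1e-12)


def test_es_weight_zero_is_rank_only():
    """With weight 0 the score ignores statistic magnitudes entirely."""
    genes = [f"g{i}" for i in range(10)]
    a = RankedSignature("a", genes, np.linspace(5, -5, 10))
    b = RankedSignature("b", genes, np.linspace(100, -0.5, 10))
    for members in ({"g0", "g1"}, {"g3", "g7", "g8"}):
        es_a, _ = enrichment_score(a, members, weight=0.0)
        es_b, _ = enrichment_score(b, members, weight=0.0)
        assert es_a == pytest.approx(es_b)


def test_es_zero_stats_returns_zero():
    """A set whose members all carry zero statistic has no signal mass."""
    ranked = RankedSignature("z", ["a", "b", "c", "d"], np.array([1.0, 0.0, 0.0, -1.0]))
    es, lead = enrichment_score(ranked, {"b", "c"})
    assert es == 0.0
    assert lead == frozenset()


def test_es_domain_errors(six_gene_ranked):
    with pytest.raises(EmptyInputError):
        enrichment_score(six_gene_ranked, {"absent"})
    with pytest.raises(ConfigError):
        enrichment_score(six_gene_ranked, set(six_gene_ranked.genes))


# ---------------------------------------------------------------------------
# permutation p-values


def test_exhaustive_null_on_six_genes(six_gene_ranked):
    """The sampled plain-ratio p agrees with complete enumeration of all
    C(6,2)=15 size-2 subsets."""
    genes = six_gene_ranked.genes
    stats = six_gene_ranked.stats
    es_obs, _ = enrichment_score(six_gene_ranked, {"g1", "g2"})
    b = exhaustive_null_count(genes, stats, 2, es_obs)
    assert b == 1
    assert b / 15 == pytest.approx(1 / 15)
    nperm = 10_000
    es, p, _ = permutation_pvalue(
        six_gene_ranked, {"g1", "g2"}, nperm=nperm, seed=9, smoothed=False
    )
    assert es == pytest.approx(es_obs)
    se = np.sqrt((1 / 15) * (14 / 15) / nperm)
    assert abs(p - 1 / 15) <= 3 * se


def test_permutation_deterministic(six_gene_ranked):
    out1 = permutation_pvalue(six_gene_ranked, {"g1", "g2"}, nperm=500, seed=3)
    out2 = permutation_pvalue(six_gene_ranked, {"g1", "g2"}, nperm=500, seed=3)
    assert out1 == out2


def test_permutation_requires_at_least_one_draw(six_gene_ranked):
    with pytest.raises(ConfigError):
        permutation_pvalue(six_gene_ranked, {"g1"}, nperm=0, seed=1)


def test_null_pvalues_calibrated():
    """On a signal-free signature, sign-directed p-values with the total-count
    denominator reject at about twice the nominal rate (each sign carries
    about half the null draws); the empirical CDF should track that."""
    rng = np.random.default_rng(77)
    genes, stats = random_ranked(rng, 200)
    ranked = RankedSignature("null", genes, stats)
    pvals = []
    for i in range(400):
        members = set(rng.choice(genes, size=10, replace=False))
        _, p, _ = permutation_pvalue(ranked, members, nperm=199, seed=1000 + i)
        pvals.append(p)
    pvals = np.array(pvals)
    for alpha in (0.05, 0.1, 0.2):
        frac = float(np.mean(pvals <= alpha))
        assert abs(frac - 2 * alpha) < 0.07, (alpha, frac)


def test_smoothed_estimator_never_zero(six_gene_ranked):
    _, p, b = permutation_pvalue(six_gene_ranked, {"g1", "g2"}, nperm=50, seed=2)
    assert p == pytest.approx((b + 1) / 51)
    assert p > 0


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_closed_forms():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_rejects_invalid():
    for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
        with pytest.raises(ConfigError):
            bh_adjust(bad)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=1e-9, max_value=1.0, allow_nan=False), min_size=1, max_size=30
    )
)
def test_bh_matches_definition_and_dominates(pvals):
    adj = bh_adjust(pvals)
    assert adj == pytest.approx(bh_stepup(pvals))
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    assert np.all(adj <= 1.0)
    # the FDR<=alpha set never grows when alpha shrinks
    for a_small, a_big in ((0.01, 0.05), (0.05, 0.1)):
        assert set(np.flatnonzero(adj <= a_small)) <= set(np.flatnonzero(adj <= a_big))


# ---------------------------------------------------------------------------
# run_enrichment


def _collection(sets):
    return GeneSetCollection(
        [GeneSet(name, "", frozenset(members)) for name, members in sets.items()]
    )


def test_size_filter_excludes_small_and_large():
    rng = np.random.default_rng(1)
    genes, stats = random_ranked(rng, 100)
    ranked = RankedSignature("s", genes, stats)
    coll = _collection(
        {
            "tiny": genes[:10],
            "ok": genes[20:40],
            "huge": genes[:95],
        }
    )
    table = run_enrichment(ranked, coll, nperm=50, seed=1, min_size=15, max_size=50)
    assert table.records["pathway"].tolist() == ["ok"]


def test_no_surviving_pathway_yields_empty_table_not_error(caplog):
    rng = np.random.default_rng(2)
    genes, stats = random_ranked(rng, 30)
    ranked = RankedSignature("s", genes, stats)
    coll = _collection({"small": genes[:5]})
    table = run_enrichment(ranked, coll, nperm=50, seed=1)
    assert len(table) == 0


def test_empty_collection_rejected(six_gene_ranked):
    with pytest.raises(ConfigError):
        run_enrichment(six_gene_ranked, GeneSetCollection([]), nperm=10, seed=0)


def test_results_independent_of_collection_order():
    """Per-pathway RNG streams are keyed by name, so shuffling the
    collection does not change any p-value."""
    rng = np.random.default_rng(3)
    genes, stats = random_ranked(rng, 200)
    ranked = RankedSignature("s", genes, stats)
    sets = {f"P{i}": list(rng.choice(genes, 20, replace=False)) for i in range(6)}
    fwd = run_enrichment(ranked, _collection(sets), nperm=100, seed=5)
    rev = run_enrichment(
        ranked, _collection(dict(reversed(list(sets.items())))), nperm=100, seed=5
    )
    a = fwd.records.sort_values("pathway").reset_index(drop=True)
    b = rev.records.sort_values("pathway").reset_index(drop=True)
    assert a[["pathway", "es", "pvalue", "padj"]].equals(
        b[["pathway", "es", "pvalue", "padj"]]
    )


def test_planted_pathway_dominates(small_config, small_collection):
    from pathreverse import rank_from_de, simulate_disease_signature

    de = simulate_disease_signature(small_config, small_collection)
    ranked = rank_from_de(de, "d")
    table = run_enrichment(ranked, small_collection, nperm=500, seed=4)
    rec = table.records.set_index("pathway")
    assert rec["es"].idxmax() == "PW001"
    assert rec.loc["PW001", "padj"] <= 0.05
    assert rec["es"].idxmin() == "PW002"
    assert rec.loc["PW002", "padj"] <= 0.05


# ---------------------------------------------------------------------------
# collapsing


def test_identical_pathways_collapse_to_one_main():
    rng = np.random.default_rng(8)
    genes, stats = random_ranked(rng, 300)
    stats = stats.copy()
    members = genes[:20]  # strongly up-regulated block
    ranked = RankedSignature("s", genes, stats)
    coll = _collection({"dup_a": members, "dup_b": members})
    table = run_enrichment(ranked, coll, nperm=200, seed=6)
    main, parent_of = collapse_pathways(table, coll, ranked, nperm=200)
    assert len(main) == 1
    (child,) = set(parent_of)
    assert parent_of[child] in main
    assert {child} | main == {"dup_a", "dup_b"}


def test_disjoint_independent_pathways_both_main():
    rng = np.random.default_rng(9)
    genes, stats = random_ranked(rng, 300)
    ranked = RankedSignature("s", genes, stats)
    coll = _collection({"top": genes[:20], "bottom": genes[-20:]})
    table = run_enrichment(ranked, coll, nperm=200, seed=7)
    main, parent_of = collapse_pathways(table, coll, ranked, nperm=200)
    assert main == {"top", "bottom"}
    assert parent_of == {}


def test_nested_subset_collapses_under_superset():
    """A pathway whose signal lives wholly inside a significant superset is
    absorbed once the superset's genes are conditioned away."""
    rng = np.random.default_rng(10)
    genes, stats = random_ranked(rng, 300)
    ranked = RankedSignature("s", genes, stats)
    superset = genes[:30]
    subset = genes[5:20]
    coll = _collection({"big": superset, "little": subset})
    table = run_enrichment(ranked, coll, nperm=300, seed=8)
    main, parent_of = collapse_pathways(table, coll, ranked, nperm=300)
    assert "big" in main
    assert parent_of.get("little") == "big"


# ---------------------------------------------------------------------------
# cross-check against the reference R implementation


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_es_matches_fgsea_reference():
    """The enrichment score agrees with fgsea::calcGseaStat on random cases."""
    rng = np.random.default_rng(123)
    cases = []
    for _ in range(5):
        genes, stats = random_ranked(rng, 60)
        members = sorted(rng.choice(60, size=15, replace=False).tolist())
        cases.append((stats, members))
    lines = ["suppressMessages(library(fgsea))"]
    for stats, members in cases:
        svec = ",".join(f"{s:.17g}" for s in stats)
        mvec = ",".join(str(m + 1) for m in members)
        lines.append(f"cat(sprintf('%.12f\\n', calcGseaStat(c({svec}), c({mvec}), gseaParam=1)))")
    proc = subprocess.run(
        ["Rscript", "-e", ";".join(lines)], capture_output=True, text=True, timeout=120
    )
    if proc.returncode != 0:
        pytest.skip(f"fgsea unavailable: {proc.stderr[-200:]}")
    refs = [float(x) for x in proc.stdout.split()]
    for (stats, members), ref in zip(cases, refs):
        genes = [f"g{i}" for i in range(len(stats))]
        ranked = RankedSignature("r", genes, stats)
        es, _ = enrichment_score(ranked, {genes[m] for m in members})
        assert es == pytest.approx(ref, abs=1e-9)
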