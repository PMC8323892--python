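"""Enrichment score arithmetic, permutation significance, overlap graph."""

import numpy as np
import pandas as pd
import pytest

from degpool import gsea
from degpool.datatypes import GeneSetCollection, ValidationError


def ranked_from(values: dict[str, float]) -> gsea.RankedList:
    return gsea.RankedList.from_series(pd.Series(values))


def test_prefix_set_scores_one():
    rk = ranked_from({f"g{i}": 10.0 - i for i in range(10)})
    es, profile, leading = gsea.enrichment_score(rk, {"g0", "g1", "g2"})
    assert es == pytest.approx(1.0)
    assert set(leading) == {"g0", "g1", "g2"}


def test_worked_running_sum_example():
    rk = ranked_from({"gene1": 3.0, "gene2": 2.0, "gene3": -1.0, "gene4": -4.0})
    es, profile, leading = gsea.enrichment_score(rk, {"gene1", "gene4"})
    assert es == pytest.approx(-4 / 7)
    assert profile == pytest.approx([3 / 7, 3 / 7 - 0.5, 3 / 7 - 1.0, 0.0])
    assert leading == ("gene4",)


def test_set_covering_universe_rejected():
    rk = ranked_from({"a": 2.0, "b": 1.0})
    with pytest.raises(ValidationError):
        gsea.enrichment_score(rk, {"a", "b"})


def test_es_bounded_and_reversal_negates():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(200)]
    metric = pd.Series(rng.normal(size=200), index=genes)
    rk_fwd = gsea.RankedList.from_series(metric)
    rk_rev = gsea.RankedList.from_series(-metric)
    for seed in range(10):
        s = set(np.random.default_rng(seed).choice(genes, 25, replace=False))
        es_f, _, _ = gsea.enrichment_score(rk_fwd, s)
        es_r, _, _ = gsea.enrichment_score(rk_rev, s)
        assert -1.0 <= es_f <= 1.0
        assert es_f == pytest.approx(-es_r, abs=1e-9)


def classical_ks_es(ranked: gsea.RankedList, gene_set) -> float:
    """Unweighted (p=0) running statistic, computed by a direct walk."""
    members = set(gene_set)
    k = sum(1 for g in ranked.gene_ids if g in members)
    n = len(ranked)
    running, best = 0.0, 0.0
    for g in ranked.gene_ids:
        running += 1.0 / k if g in members else -1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def test_weight_zero_reduces_to_classical_ks():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(80)]
    rk = gsea.RankedList.from_series(pd.Series(rng.normal(size=80), index=genes))
    for seed in range(8):
        s = set(np.random.default_rng(100 + seed).choice(genes, 12, replace=False))
        es, _, _ = gsea.enrichment_score(rk, s, weight_p=0.0)
        assert es == pytest.approx(classical_ks_es(rk, s), abs=1e-12)


def _random_collection(genes, n_sets, rng, size=20) -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            f"s{j}": frozenset(rng.choice(genes, size, replace=False))
            for j in range(n_sets)
        }
    )


def test_permutation_significance_is_seed_deterministic():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(300)]
    rk = gsea.RankedList.from_series(pd.Series(rng.normal(size=300), index=genes))
    sets = _random_collection(genes, 5, rng)
    a = gsea.permutation_significance(rk, sets, n_perm=200, seed=9)
    b = gsea.permutation_significance(rk, sets, n_perm=200, seed=9)
    for ra, rb in zip(a, b):
        assert (ra.es, ra.nes, ra.p_value, ra.fdr_q) == (rb.es, rb.nes, rb.p_value, rb.fdr_q)
    c = gsea.permutation_significance(rk, sets, n_perm=200, seed=10)
    assert any(ra.p_value != rc.p_value for ra, rc in zip(a, c))


def test_planted_top_decile_set_reaches_small_q():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(2000)]
    metric = pd.Series(rng.normal(size=2000), index=genes)
    rk = gsea.RankedList.from_series(metric)
    top = list(rk.gene_ids[:200])
    planted = frozenset(rng.choice(top, 30, replace=False))
    sets = GeneSetCollection(sets={"planted": planted, **_random_collection(genes, 10, rng).sets})
    res = {r.name: r for r in gsea.permutation_significance(rk, sets, n_perm=500, seed=4)}
    assert res["planted"].fdr_q < 0.05
    assert res["planted"].nes > 0


def test_fdr_monotone_in_abs_nes_within_sign_class():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(500)]
    rk = gsea.RankedList.from_series(pd.Series(rng.normal(size=500), index=genes))
    results = gsea.permutation_significance(
        rk, _random_collection(genes, 20, rng), n_perm=300, seed=6
    )
    for sign in (1, -1):
        group = sorted(
            (r for r in results if (r.nes >= 0) == (sign == 1)),
            key=lambda r: abs(r.nes), reverse=True,
        )
        qs = [r.fdr_q for r in group]
        assert qs == sorted(qs)


def test_significance_filter_boundaries():
    rk = ranked_from({"a": 3.0, "b": 0.5, "c": -0.2, "d": -3.0})
    res_hi = gsea.EnrichmentResult("hi", 1, 0.9, 2.0, 0.001, 0.049, leading_edge=("a",))
    res_edge = gsea.EnrichmentResult("edge", 1, 0.9, 2.0, 0.001, 0.05, leading_edge=("a",))
    res_flat = gsea.EnrichmentResult("flat", 1, 0.9, 2.0, 0.001, 0.01, leading_edge=("b",))
    kept = gsea.significant_sets([res_hi, res_edge, res_flat], rk)
    assert [r.name for r in kept] == ["hi"]  # q = 0.05 exactly and weak-LE both excluded
    assert gsea.significant_sets([], rk) == []


def test_overlap_similarity_and_graph_edges():
    assert gsea.combined_similarity(frozenset("abcd"), frozenset("abcdef")) == pytest.approx(
        0.5 * (4 / 6) + 0.5 * 1.0
    )
    # |A|=4, |B|=6, |A∩B|=3 -> jaccard 3/7, overlap 3/4 -> combined ~ 0.589
    a4 = frozenset({"p", "q", "r", "s"})
    b6 = frozenset({"q", "r", "s", "t", "u", "v"})
    assert gsea.combined_similarity(a4, b6) == pytest.approx(0.5 * 3 / 7 + 0.5 * 3 / 4)

    sets = GeneSetCollection(
        sets={"A": a4, "B": b6, "C": frozenset({"z1", "z2", "z3"})}
    )
    results = [
        gsea.EnrichmentResult("A", 4, 0.8, 1.9, 0.0, 0.0),
        gsea.EnrichmentResult("B", 6, 0.7, 1.7, 0.0, 0.0),
        gsea.EnrichmentResult("C", 3, -0.6, -1.5, 0.0, 0.0),
    ]
    graph = gsea.overlap_graph(results, sets, cutoff=0.375)
    assert graph.has_edge("A", "B")
    assert not graph.has_edge("A", "C") and not graph.has_edge("B", "C")
    assert graph.nodes["C"]["direction"] == "negative"
    with pytest.raises(ValidationError):
        gsea.overlap_graph([], sets)


def test_tie_breaking_is_lexicographic():
    rk = ranked_from({"b": 1.0, "a": 1.0, "c": 2.0})
    assert list(rk.gene_ids) == ["c", "a", "b"]
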