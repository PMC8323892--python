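"""Category count cells and the nonparametric tests, against brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degpool import categories, deg
from degpool.categories import CountCell
from degpool.datatypes import ValidationError

from conftest import make_annotation


def make_result(calls: dict[str, str], label="c1", group="G") -> deg.ContrastResult:
    table = pd.DataFrame(
        {
            "g1_mean": 1.0,
            "g2_mean": 1.0,
            "dfpkm": 2.0,
            "adj_log2fc": 1.5,
            "call": pd.Series(calls, dtype=object),
        }
    )
    return deg.ContrastResult(label=label, group=group, table=table)


ANNOTATION = make_annotation(
    {
        "g1": "odorant-binding protein",
        "g2": "odorant-binding protein",
        "g3": "cytochrome P450",
        "g4": "none",
        "g5": "none",
        "g6": "glutathione S-transferase",
        "g7": "serpin",
    }
)


def test_toy_recount_example():
    res = make_result(
        {
            "g1": deg.CALL_UP_G1, "g2": deg.CALL_UP_G1, "g3": deg.CALL_UP_G1,
            "g4": deg.CALL_UP_G1, "g5": deg.CALL_UP_G1,
            "g6": deg.CALL_NOT_DE, "g7": deg.CALL_NOT_DE,
        }
    )
    cells = categories.count_upregulated([res], ANNOTATION)
    by = {(c.functional_group, c.side): c.n_up for c in cells}
    assert by[("odorant-binding protein", "group1")] == 2
    assert by[("cytochrome P450", "group1")] == 1
    assert by[("cytochrome P450", "group2")] == 0
    # unannotated genes (g4, g5) never appear
    assert all(c.functional_group != "none" for c in cells)


def test_zero_deg_contrast_gives_zero_cells():
    res = make_result({g: deg.CALL_NOT_DE for g in ANNOTATION.gene_ids})
    cells = categories.count_upregulated([res], ANNOTATION)
    assert cells and all(c.n_up == 0 for c in cells)


def test_inevaluable_group_emits_no_cell():
    calls = {g: deg.CALL_NOT_DE for g in ANNOTATION.gene_ids}
    calls["g7"] = deg.CALL_NOT_EVALUABLE  # the only serpin
    res = make_result(calls)
    cells = categories.count_upregulated([res], ANNOTATION)
    assert all(c.functional_group != "serpin" for c in cells)


def test_aggregate_sums_dtx_groups_and_conserves_counts():
    cells = [
        CountCell("c1", "G", "group1", "head", "cytochrome P450", 3),
        CountCell("c1", "G", "group1", "head", "glutathione S-transferase", 2),
        CountCell("c1", "G", "group1", "head", "odorant-binding protein", 9),
        CountCell("c1", "G", "group2", "head", "cytochrome P450", 1),
    ]
    agg = categories.aggregate_category(cells, "DTX")
    by_side = {c.side: c.n_up for c in agg}
    assert by_side == {"group1": 5, "group2": 1}
    assert categories.aggregate_category([], "DTX") == []
    # conservation on a random fixture
    rng = np.random.default_rng(0)
    groups = list(categories.CATEGORY_GROUPS["DTX"])
    rand = [
        CountCell(f"c{i%4}", "G", side, "head", rng.choice(groups), int(rng.integers(0, 9)))
        for i in range(40)
        for side in ("group1", "group2")
    ]
    agg = categories.aggregate_category(rand, "DTX")
    assert sum(c.n_up for c in agg) == sum(c.n_up for c in rand)


# ------------------------------------------------------ wilcoxon signed rank


def enumeration_oracle(diffs: np.ndarray) -> float:
    """Two-sided exact p by literal enumeration of all 2^n sign vectors."""
    d = diffs[diffs != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-12)
    upper = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


def test_all_pairs_equal_gives_p_one():
    res = categories.wilcoxon_signed_rank([(2.0, 2.0), (5.0, 5.0)])
    assert res.p_value == 1.0
    assert "degenerate" in res.notes


def test_five_distinct_positive_differences_exact_p():
    pairs = [(float(i + 2), 1.0) for i in range(5)]
    res = categories.wilcoxon_signed_rank(pairs)
    assert res.p_value == pytest.approx(2 / 32)


@pytest.mark.parametrize("seed", range(12))
def test_exact_p_matches_sign_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 11))
    # integer-valued differences produce ties and zeros
    d = rng.integers(-4, 5, size=n).astype(float)
    if np.all(d == 0):
        d[0] = 1.0
    pairs = [(float(x), 0.0) for x in d]
    res = categories.wilcoxon_signed_rank(pairs)
    assert res.p_value == pytest.approx(enumeration_oracle(d), abs=1e-12)


def test_wilcoxon_antisymmetric_in_pair_order():
    rng = np.random.default_rng(3)
    pairs = [(float(a), float(b)) for a, b in rng.integers(0, 10, size=(8, 2))]
    fwd = categories.wilcoxon_signed_rank(pairs)
    rev = categories.wilcoxon_signed_rank([(b, a) for a, b in pairs])
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
    # W+ of one order is W- of the other: they sum to the total rank sum
    d = np.array([a - b for a, b in pairs], dtype=float)
    total = stats.rankdata(np.abs(d[d != 0])).sum()
    assert fwd.statistic + rev.statistic == pytest.approx(total)


def test_normal_approximation_branch_reasonable():
    rng = np.random.default_rng(5)
    pairs = [(float(x), 0.0) for x in rng.normal(0.8, 1.0, size=40)]
    res = categories.wilcoxon_signed_rank(pairs, exact_max_n=25)
    assert "normal approximation" in res.notes
    ref = stats.wilcoxon([a - b for a, b in pairs], correction=True, mode="approx")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


# ---------------------------------------------------------- kruskal-wallis --


def test_kruskal_wallis_hand_example():
    res = categories.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert res.p_value == pytest.approx(stats.chi2.sf(7.2, 2))


def test_kruskal_wallis_degenerate_cases():
    res = categories.kruskal_wallis([[3, 3], [3, 3, 3]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    with pytest.raises(ValidationError):
        categories.kruskal_wallis([[1, 2, 3]])


def test_null_rejection_rates_are_calibrated():
    """Both tests reject ~5% of the time on iid null count data."""
    rng = np.random.default_rng(9)
    n_rep = 400
    rej_w = rej_k = 0
    for _ in range(n_rep):
        a, b = rng.poisson(6, size=(2, 12))
        if categories.wilcoxon_signed_rank(list(zip(a.astype(float), b.astype(float)))).p_value < 0.05:
            rej_w += 1
        g = rng.poisson(6, size=(3, 8))
        if categories.kruskal_wallis([list(r) for r in g]).p_value < 0.05:
            rej_k += 1
    assert 0.01 <= rej_w / n_rep <= 0.09
    assert 0.01 <= rej_k / n_rep <= 0.09
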