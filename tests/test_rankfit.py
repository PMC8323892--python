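"""Rank regression: exact fits, Hodges-Lehmann oracle, dispersion geometry."""

import numpy as np
import pandas as pd
import pytest

from degpool import rankfit
from degpool.categories import CountCell
from degpool.datatypes import ValidationError


def test_wilcoxon_scores_sum_zero_and_unit_mean_square():
    for n in (10, 100, 1000):
        a = rankfit.wilcoxon_scores(n)
        assert abs(a.sum()) < 1e-9
        # exact second moment is (n-1)/(n+1), approaching 1 with n
        assert np.mean(a**2) == pytest.approx((n - 1) / (n + 1), abs=1e-9)
    assert np.mean(rankfit.wilcoxon_scores(1000) ** 2) == pytest.approx(1.0, rel=0.01)


def test_exact_linear_data_recovers_beta_with_zero_dispersion():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 2))
    beta = np.array([1.5, -2.0])
    y = x @ beta + 3.0
    fit = rankfit.rank_fit(x, y)
    assert fit.dispersion == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.coefficients, beta, atol=1e-6)


def hodges_lehmann_shift(a: np.ndarray, b: np.ndarray) -> float:
    """Median of all pairwise between-group differences (brute force)."""
    return float(np.median([x - y for x in a for y in b]))


@pytest.mark.parametrize("seed", range(10))
def test_binary_covariate_slope_is_hodges_lehmann(seed):
    rng = np.random.default_rng(seed)
    n1, n0 = 12, 15
    g = np.concatenate([np.ones(n1), np.zeros(n0)])
    y = rng.normal(size=n1 + n0) + 1.3 * g
    fit = rankfit.rank_fit(g[:, None], y)
    expect = hodges_lehmann_shift(y[g == 1], y[g == 0])
    assert fit.coefficients[0] == pytest.approx(expect, abs=1e-6)


def test_dispersion_minimum_along_random_directions():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(50, 3))
    y = x @ np.array([1.0, 0.5, -1.0]) + rng.standard_t(4, size=50)
    fit = rankfit.rank_fit(x, y)
    d0 = fit.dispersion
    for _ in range(25):
        direction = rng.normal(size=3)
        for t in (1e-3, 1e-2, 0.1, 1.0):
            d = rankfit.jaeckel_dispersion(y - x @ (fit.coefficients + t * direction))
            assert d >= d0 - 1e-7


def test_dispersion_is_location_invariant():
    rng = np.random.default_rng(2)
    e = rng.normal(size=30)
    assert rankfit.jaeckel_dispersion(e) == pytest.approx(
        rankfit.jaeckel_dispersion(e + 117.3), abs=1e-9
    )


def test_pairwise_difference_identity():
    """D(e) = sqrt(12)/(2(n+1)) * sum_{i<j} |e_i - e_j| (Wilcoxon scores)."""
    rng = np.random.default_rng(3)
    e = rng.normal(size=25)
    n = len(e)
    pairwise = sum(abs(a - b) for i, a in enumerate(e) for b in e[i + 1 :])
    assert rankfit.jaeckel_dispersion(e) == pytest.approx(
        np.sqrt(12) / (2 * (n + 1)) * pairwise, abs=1e-9
    )


def test_rank_deficient_design_errors_with_column_names():
    x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    with pytest.raises(ValidationError, match="rank deficient"):
        rankfit.rank_fit(x, np.arange(4.0))


def test_reduction_nonnegative_on_random_nested_pairs():
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        full = pd.DataFrame(x, columns=["a", "b", "c"])
        res = rankfit.drop_in_dispersion_test(full, full[["a"]], y)
        assert res.reduction >= 0.0


def test_identical_models_give_rd_zero_p_one():
    rng = np.random.default_rng(5)
    x = pd.DataFrame({"a": rng.normal(size=20)})
    res = rankfit.drop_in_dispersion_test(x, x, rng.normal(size=20))
    assert res.reduction == 0.0 and res.f_statistic == 0.0 and res.p_value == 1.0


def test_non_nested_models_rejected():
    rng = np.random.default_rng(6)
    full = pd.DataFrame({"a": rng.normal(size=20)})
    other = pd.DataFrame({"z": rng.normal(size=20)})
    with pytest.raises(ValidationError, match="nested"):
        rankfit.drop_in_dispersion_test(full, other, rng.normal(size=20))


def test_factor_coding_invariance():
    """Swapping which level is the reference leaves the test unchanged."""
    rng = np.random.default_rng(7)
    g = np.repeat([0, 1, 2], 12)
    t = np.tile([0, 1], 18)
    y = rng.normal(size=36) + 0.7 * (g == 2) * t
    code_a = pd.DataFrame({"g1": (g == 1) * 1.0, "g2": (g == 2) * 1.0, "t": t * 1.0})
    code_b = pd.DataFrame({"g0": (g == 0) * 1.0, "g2": (g == 2) * 1.0, "t": t * 1.0})
    inter_a = code_a[["g1", "g2"]].mul(code_a["t"], axis=0).rename(columns=lambda c: c + ":t")
    inter_b = code_b[["g0", "g2"]].mul(code_b["t"], axis=0).rename(columns=lambda c: c + ":t")
    res_a = rankfit.drop_in_dispersion_test(pd.concat([code_a, inter_a], axis=1), code_a, y)
    res_b = rankfit.drop_in_dispersion_test(pd.concat([code_b, inter_b], axis=1), code_b, y)
    assert res_a.p_value == pytest.approx(res_b.p_value, abs=5e-3)


def test_binary_predictor_agrees_with_rank_sum_test():
    """The drop test on one binary column tracks the Wilcoxon rank-sum p."""
    from scipy import stats

    rng = np.random.default_rng(8)
    diffs = []
    for _ in range(120):
        g = np.repeat([0.0, 1.0], 50)
        y = rng.normal(size=100) + 0.3 * g
        res = rankfit.drop_in_dispersion_test(
            pd.DataFrame({"g": g}), pd.DataFrame(index=range(100)), y
        )
        ref = stats.mannwhitneyu(y[g == 1], y[g == 0], alternative="two-sided")
        diffs.append(abs(res.p_value - ref.pvalue))
    assert np.mean(diffs) < 0.02
    assert np.quantile(diffs, 0.9) < 0.05


def make_cells(counts_by_key) -> list[CountCell]:
    return [
        CountCell(contrast=f"c{i}", contrast_group="G", side=side, tissue=tissue,
                  functional_group=fg, n_up=int(n))
        for i, ((side, tissue, fg), n) in enumerate(counts_by_key)
    ]


def test_interaction_tests_additive_cells_have_small_rd():
    """Pure additive, noise-free counts: every interaction RD ~ 0."""
    rows = []
    side_eff = {"group1": 0, "group2": 2}
    tissue_eff = {"head": 0, "abdomen": 3}
    fg_eff = {"cytochrome P450": 1, "glutathione S-transferase": 4}
    for side in side_eff:
        for tissue in tissue_eff:
            for fg in fg_eff:
                for rep in range(3):
                    rows.append(((side, tissue, fg), 10 + side_eff[side] + tissue_eff[tissue] + fg_eff[fg]))
    results = rankfit.interaction_tests(make_cells(rows))
    for res in results:
        if not res.notes.startswith("skipped"):
            assert res.reduction == pytest.approx(0.0, abs=1e-6)


def test_interaction_test_skips_single_level_factor():
    rows = [(("group1", "head", "serpin"), 3), (("group2", "head", "serpin"), 5)] * 6
    results = rankfit.interaction_tests(make_cells(rows))
    skipped = [r for r in results if "skipped" in r.notes]
    assert len(skipped) >= 2  # tissue and functional_group have one level


def test_planted_interaction_is_detected():
    """Counts inflated for one functional group on one side only."""
    rng = np.random.default_rng(10)
    detected = 0
    n_rep = 30
    for _ in range(n_rep):
        rows = []
        for side in ("group1", "group2"):
            for tissue in ("head", "abdomen"):
                for fg in ("cytochrome P450", "glutathione S-transferase"):
                    for rep in range(4):
                        base = 10 + rng.normal(0, 2)
                        if side == "group1" and fg == "cytochrome P450":
                            base += 12
                        rows.append(((side, tissue, fg), max(round(base), 0)))
        results = rankfit.interaction_tests(make_cells(rows))
        host_group = [r for r in results if "functional_group" in r.full_label and "host" in r.full_label]
        if host_group[0].p_value < 0.05:
            detected += 1
    assert detected / n_rep >= 0.8
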