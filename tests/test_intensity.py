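"""Five-bin weighted-median intensity against a brute-force oracle."""

import numpy as np
import pytest

from degpool import intensity
from degpool.datatypes import Contrast


def oracle(values, n_bins=5):
    """Independent bin-and-weighted-median implementation."""
    vals = sorted(values)
    if len(vals) <= 1:
        return None
    lo, hi = vals[0], vals[-1]
    if lo == hi:
        return lo
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in vals:
        b = min(int((v - lo) / width), n_bins - 1)
        counts[b] += 1
    mids = [lo + (b + 0.5) * width for b in range(n_bins)]
    pairs = [(m, c) for m, c in zip(mids, counts) if c]
    total = sum(c for _, c in pairs)
    cum = 0
    for m, c in pairs:
        cum += c
        if cum >= total / 2:  # lower midpoint on exact half
            return m
    raise AssertionError


def test_worked_example():
    cell = intensity.weighted_median_intensity([1.0, 1.5, 2.0, 2.5, 5.0])
    assert list(cell.bin_counts) == [2, 2, 0, 0, 1]
    assert cell.value == pytest.approx(2.2)
    assert cell.bin_edges[1] - cell.bin_edges[0] == pytest.approx(0.8)


def test_single_value_and_empty_are_excluded():
    assert intensity.weighted_median_intensity([2.5]).excluded
    empty = intensity.weighted_median_intensity([])
    assert empty.excluded and empty.n == 0


def test_zero_range_returns_common_value():
    cell = intensity.weighted_median_intensity([1.7] * 6)
    assert not cell.excluded
    assert cell.value == pytest.approx(1.7)


@pytest.mark.parametrize("seed", range(20))
def test_random_lists_match_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 40))
    vals = np.round(rng.uniform(0.5, 6.0, size=n), 2)  # rounding makes edge ties
    cell = intensity.weighted_median_intensity(list(vals))
    assert cell.value == pytest.approx(oracle(vals), abs=1e-12)
    assert int(cell.bin_counts.sum()) == n


def test_values_at_exact_bin_edges_are_all_binned():
    vals = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]  # every internal edge hit exactly
    cell = intensity.weighted_median_intensity(vals)
    assert int(cell.bin_counts.sum()) == len(vals)
    assert cell.value == pytest.approx(oracle(vals), abs=1e-12)


def test_within_bin_jitter_does_not_change_statistic():
    rng = np.random.default_rng(1)
    vals = np.array([1.0, 1.3, 2.6, 2.9, 4.2, 5.0])
    cell = intensity.weighted_median_intensity(list(vals))
    edges = cell.bin_edges
    jittered = vals.copy()
    # jitter interior values without crossing their bin boundaries or the range
    for i, v in enumerate(vals):
        b = min(np.searchsorted(edges, v, side="right") - 1, 4)
        lo = max(edges[b], vals.min())
        hi = min(edges[b + 1], vals.max())
        if v not in (vals.min(), vals.max()):
            jittered[i] = rng.uniform(lo + 1e-9, hi - 1e-9)
    cell2 = intensity.weighted_median_intensity(list(jittered))
    assert list(cell2.bin_counts) == list(cell.bin_counts)
    assert cell2.value == pytest.approx(cell.value, abs=1e-9)


def test_constant_shift_moves_statistic_by_same_amount():
    rng = np.random.default_rng(2)
    vals = rng.uniform(1, 4, size=15)
    c = 2.37
    v1 = intensity.weighted_median_intensity(list(vals)).value
    v2 = intensity.weighted_median_intensity(list(vals + c)).value
    assert v2 == pytest.approx(v1 + c, abs=1e-9)


def test_matrix_antisymmetry_under_group_swap():
    import pandas as pd

    from degpool import deg
    from conftest import make_annotation, make_fpkm

    rng = np.random.default_rng(3)
    n = 60
    genes = [f"g{i}" for i in range(n)]
    groups = {}
    for i, g in enumerate(genes):
        groups[g] = ["odorant-binding protein", "cytochrome P450", "serpin"][i % 3]
    ann = make_annotation(groups)
    vals = rng.gamma(2, 5, size=(n, 2))
    fm = make_fpkm(vals, gene_ids=genes)
    fwd = deg.call_degs(fm, Contrast("c", ("s1",), ("s2",)), group="G")
    rev = deg.call_degs(fm, Contrast("c", ("s2",), ("s1",)), group="G")
    cells_f = intensity.build_intensity_matrix([fwd], ann)
    cells_r = intensity.build_intensity_matrix([rev], ann)
    key = lambda c: (c.label, c.tissue, c.category)
    fmap = {(key(c), c.direction): c for c in cells_f}
    for c in cells_r:
        opposite = "negative" if c.direction == "positive" else "positive"
        mirror = fmap[(key(c), opposite)]
        assert c.n == mirror.n
        if not c.excluded:
            assert c.value == pytest.approx(mirror.value, abs=1e-9)


def test_direction_with_no_degs_is_excluded_cell():
    from degpool import deg
    from conftest import make_annotation, make_fpkm
    import pandas as pd

    ann = make_annotation({"g1": "serpin", "g2": "serpin", "g3": "serpin"})
    # three serpins strongly up in group1; balanced background keeps the
    # per-sample medians equal so the shift survives median scaling
    background = np.tile([[4.0], [5.0], [5.0], [5.0], [5.0], [6.0]], (1, 2))
    fm = make_fpkm(
        np.vstack([[[50.0, 2.0]], [[40.0, 2.0]], [[30.0, 2.0]], background]),
        gene_ids=["g1", "g2", "g3", "b1", "b2", "b3", "b4", "b5", "b6"],
    )
    res = deg.call_degs(fm, Contrast("c", ("s1",), ("s2",)), group="G")
    cells = intensity.build_intensity_matrix([res], ann)
    by_dir = {(c.category, c.direction): c for c in cells}
    assert not by_dir[("IM", "positive")].excluded
    assert by_dir[("IM", "negative")].excluded
    assert by_dir[("IM", "negative")].n == 0


def test_frame_encodes_direction_by_sign():
    cell_pos = intensity.weighted_median_intensity(
        [1, 2, 3], direction="positive", label="c", tissue="head", category="HD"
    )
    cell_neg = intensity.weighted_median_intensity(
        [1, 2, 3], direction="negative", label="c", tissue="head", category="HD"
    )
    frame = intensity.intensity_frame([cell_pos, cell_neg])
    assert frame.loc[0, "value"] > 0
    assert frame.loc[1, "value"] < 0
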