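"""Targeted-gene-category count tables and nonparametric tests.

Upregulated-DEG counts are tabulated per contrast x side x functional
gene group (host detection, detoxification and immune-defense families).
A functional group contributes a cell to a contrast only when at least
one of its genes is evaluable there (present in both groups); the
detoxification category is additionally analyzed as an aggregate by
summing over its six families.  Between-side differences are tested with
an exact Wilcoxon signed-rank test (pairing the two sides of each
comparison cell) and, across >= 3 conditions, the Kruskal-Wallis test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CATEGORY_GROUPS,
    GROUP_TO_CATEGORY,
    GeneAnnotation,
    StudyDesign,
    ValidationError,
)
from .deg import CALL_UP_G1, CALL_UP_G2, ContrastResult


@dataclass(frozen=True)
class CountCell:
    """Upregulated-gene count for one contrast x side x functional group."""

    contrast: str
    contrast_group: str | None
    side: str  # "group1" | "group2"
    tissue: str
    functional_group: str
    n_up: int


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    notes: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


_SIDE_CALL = {"group1": CALL_UP_G1, "group2": CALL_UP_G2}


def count_upregulated(
    results: list[ContrastResult],
    annotation: GeneAnnotation,
    design: StudyDesign | None = None,
) -> list[CountCell]:
    """Tabulate upregulated DEGs per contrast x side x functional group.

    Genes without a targeted-category annotation are ignored.  A cell is
    emitted only when the group's transcripts are evaluable in the
    contrast; both sides are emitted together (zero counts included) so
    the two sides of a comparison stay pairable.
    """
    ann = annotation.table
    targeted = ann[ann["category"] != "none"]
    cells: list[CountCell] = []
    for res in results:
        tissue = "mixed"
        if design is not None:
            tissue = design.tissue_of_contrast(design.contrast(res.label))
        tab = res.table
        present = tab.index.intersection(targeted.index)
        sub = tab.loc[present]
        groups_here = targeted.loc[present, "functional_group"]
        for fgroup in sorted(groups_here.unique()):
            members = groups_here.index[groups_here == fgroup]
            calls = sub.loc[members, "call"]
            if (calls == "not_evaluable").all():
                continue  # group not comparable in this contrast
            for side in ("group1", "group2"):
                n_up = int((calls == _SIDE_CALL[side]).sum())
                cells.append(
                    CountCell(
                        contrast=res.label,
                        contrast_group=res.group,
                        side=side,
                        tissue=tissue,
                        functional_group=fgroup,
                        n_up=n_up,
                    )
                )
    return cells


def cells_frame(cells: list[CountCell]) -> pd.DataFrame:
    cols = ["contrast", "contrast_group", "side", "tissue", "functional_group", "n_up"]
    if not cells:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(c) for c in cells])[cols]


def aggregate_category(cells: list[CountCell], category: str) -> list[CountCell]:
    """Sum counts over a category's functional groups per contrast x side."""
    if category not in CATEGORY_GROUPS:
        raise ValidationError(f"unknown category {category!r}")
    groups = set(CATEGORY_GROUPS[category])
    sums: dict[tuple, int] = {}
    meta: dict[tuple, CountCell] = {}
    for cell in cells:
        if cell.functional_group not in groups:
            continue
        key = (cell.contrast, cell.side)
        sums[key] = sums.get(key, 0) + cell.n_up
        meta.setdefault(key, cell)
    return [
        CountCell(
            contrast=key[0],
            contrast_group=meta[key].contrast_group,
            side=key[1],
            tissue=meta[key].tissue,
            functional_group=f"{category}_aggregate",
            n_up=total,
        )
        for key, total in sorted(sums.items())
    ]


def category_side_pairs(
    cells: list[CountCell], category: str, tissue: str | None = None
) -> list[tuple[float, float]]:
    """Pair the two sides of every (contrast x functional group) cell.

    The pairing unit matches one plotted point per side: a pairwise
    comparison x functional group (x tissue when ``tissue`` given).
    """
    groups = set(CATEGORY_GROUPS.get(category, ())) | {f"{category}_aggregate"}
    by_key: dict[tuple, dict[str, int]] = {}
    for cell in cells:
        if cell.functional_group not in groups:
            continue
        if tissue is not None and cell.tissue != tissue:
            continue
        by_key.setdefault((cell.contrast, cell.functional_group, cell.tissue), {})[
            cell.side
        ] = cell.n_up
    pairs = []
    for key in sorted(by_key):
        sides = by_key[key]
        if "group1" in sides and "group2" in sides:
            pairs.append((float(sides["group1"]), float(sides["group2"])))
    return pairs


def _signed_rank_exact_p(ranks2: np.ndarray, w2_plus: int) -> float:
    """Exact two-sided p for the signed-rank sum via subset-sum convolution.

    ``ranks2`` are doubled midranks (integers), ``w2_plus`` the doubled
    observed positive-rank sum.  All 2^n sign assignments are implicitly
    enumerated by the characteristic-function DP; two-sided p is twice
    the smaller tail (each tail including the observed value), capped
    at 1.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    lower = float(dist[: w2_plus + 1].sum())
    upper = float(dist[w2_plus:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]],
    exact_max_n: int = 25,
    zero_method: str = "wilcox",
) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test on (side1, side2) counts.

    Zero differences are dropped (``zero_method="wilcox"``, classical) or
    kept in the ranking (``"pratt"``).  Midranks handle ties.  The exact
    null distribution (which respects the tie pattern) is used when the
    effective n is at most ``exact_max_n``; otherwise the normal
    approximation with tie and continuity corrections.
    """
    if not pairs:
        raise ValidationError("need at least one pair")
    d = np.asarray([a - b for a, b in pairs], dtype=float)
    notes = []
    if zero_method == "wilcox":
        nz = d != 0
        if (~nz).any():
            notes.append(f"{int((~nz).sum())} zero difference(s) dropped")
        d = d[nz]
    elif zero_method != "pratt":
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    if len(d) == 0 or np.all(d == 0):
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0, "degenerate: all differences zero")

    ranks = stats.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
    w_plus = float(ranks[d > 0].sum())
    n = len(d)

    ranks2 = np.rint(2 * ranks).astype(int)
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks2, int(round(2 * w_plus)))
        notes.append("exact")
    else:
        mean = ranks.sum() / 2.0
        sd = np.sqrt(np.sum(ranks**2) / 4.0)  # midranks absorb tie correction
        if sd == 0:
            return TestResult("wilcoxon_signed_rank", w_plus, 1.0, n, "degenerate: zero variance")
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / sd
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
        notes.append("normal approximation with continuity correction")
    if (ranks2 % 2).any() or len(np.unique(ranks)) < n:
        notes.append("ties: midranks")
    return TestResult("wilcoxon_signed_rank", w_plus, p, n, "; ".join(notes))


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, n, "degenerate: all observations tied")
    h, p = stats.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p), n)


def category_of_functional_group(fgroup: str) -> str:
    if fgroup.endswith("_aggregate"):
        return fgroup.removesuffix("_aggregate")
    return GROUP_TO_CATEGORY.get(fgroup, "none")
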