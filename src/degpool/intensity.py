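"""Binned weighted-median expression-intensity statistic for heatmaps.

For every comparison (or comparison group) x tissue x targeted category
x direction, the |adjusted log2FC| values of the DEGs are split into
five equal-width bins over their own range; the cell's intensity is the
weighted median of the bin midpoints with weights equal to the genes per
bin.  Cells with at most one DEG are excluded (a single transcript gives
no distribution to summarize).  Direction is encoded by sign when the
matrix is assembled: positive = up in group 1, negative = up in group 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, StudyDesign, ValidationError
from .deg import CALL_UP_G1, CALL_UP_G2, ContrastResult

DIRECTIONS = ("positive", "negative")
_DIR_CALL = {"positive": CALL_UP_G1, "negative": CALL_UP_G2}


@dataclass
class IntensityCell:
    label: str  # contrast or comparison-group label
    tissue: str
    category: str
    direction: str
    n: int
    value_range: tuple[float, float] | None
    bin_edges: np.ndarray | None
    bin_counts: np.ndarray | None
    value: float | None
    excluded: bool

    def __post_init__(self) -> None:
        if self.excluded:
            return
        if self.bin_counts is not None and int(self.bin_counts.sum()) != self.n:
            raise ValidationError("bin counts must sum to n")
        lo, hi = self.value_range
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise ValidationError("weighted median outside the value range")


def weighted_median(points: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with the lower-point tie rule.

    Points are sorted; the weighted median is the first point at which
    the cumulative weight reaches half the total (ties at exactly half
    resolve to that lower point).
    """
    order = np.argsort(points)
    pts, w = points[order], weights[order]
    cum = np.cumsum(w)
    half = w.sum() / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    return float(pts[idx])


def weighted_median_intensity(
    values,
    n_bins: int = 5,
    convention: str = "midpoint",
    label: str = "",
    tissue: str = "",
    category: str = "",
    direction: str = "",
) -> IntensityCell:
    """Bin the values into ``n_bins`` equal-width bins and summarize.

    ``convention`` picks what the weighted median is taken over:
    ``"midpoint"`` (bin midpoints, default), ``"index"`` (1-based bin
    indices) or ``"within"`` (weighted median of the per-bin raw
    medians).  Cells with n <= 1 are excluded.
    """
    vals = np.asarray(list(values), dtype=float)
    meta = dict(label=label, tissue=tissue, category=category, direction=direction)
    if len(vals) <= 1:
        return IntensityCell(
            n=len(vals), value_range=None, bin_edges=None, bin_counts=None,
            value=None, excluded=True, **meta,
        )
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        # Zero range: one degenerate bin holding everything; the statistic
        # is the common value.
        edges = np.full(n_bins + 1, lo)
        counts = np.zeros(n_bins, dtype=int)
        counts[0] = len(vals)
        return IntensityCell(
            n=len(vals), value_range=(lo, hi), bin_edges=edges,
            bin_counts=counts, value=lo, excluded=False, **meta,
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    # Right-open bins except the last, which is closed so the maximum lands
    # in bin n_bins.
    bin_index = np.minimum(np.searchsorted(edges, vals, side="right") - 1, n_bins - 1)
    counts = np.bincount(bin_index, minlength=n_bins)
    occupied = counts > 0
    if convention == "midpoint":
        points = (edges[:-1] + edges[1:]) / 2.0
        value = weighted_median(points[occupied], counts[occupied].astype(float))
    elif convention == "index":
        points = np.arange(1, n_bins + 1, dtype=float)
        value = weighted_median(points[occupied], counts[occupied].astype(float))
    elif convention == "within":
        points = np.array([np.median(vals[bin_index == b]) for b in range(n_bins) if occupied[b]])
        value = weighted_median(points, counts[occupied].astype(float))
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    return IntensityCell(
        n=len(vals), value_range=(lo, hi), bin_edges=edges,
        bin_counts=counts, value=value, excluded=False, **meta,
    )


def build_intensity_matrix(
    results: list[ContrastResult],
    annotation: GeneAnnotation,
    design: StudyDesign | None = None,
    grouping: str = "contrast",
    n_bins: int = 5,
    convention: str = "midpoint",
) -> list[IntensityCell]:
    """Compute all comparison x tissue x category x direction cells.

    ``grouping="contrast"`` yields one row per pairwise contrast;
    ``"group"`` pools the DEGs of each comparison group (per tissue).
    """
    ann = annotation.table
    buckets: dict[tuple[str, str, str, str], list[float]] = {}
    for res in results:
        tissue = design.tissue_of_contrast(design.contrast(res.label)) if design else "mixed"
        row_label = res.label if grouping == "contrast" else (res.group or "ungrouped")
        tab = res.table
        for direction in DIRECTIONS:
            degs = tab[tab["call"] == _DIR_CALL[direction]]
            cats = ann.reindex(degs.index)["category"]
            for cat in ("HD", "DTX", "IM"):
                key = (row_label, tissue, cat, direction)
                vals = degs.loc[cats[cats == cat].index, "adj_log2fc"].abs()
                buckets.setdefault(key, []).extend(float(v) for v in vals)

    cells = []
    for (label, tissue, cat, direction) in sorted(buckets):
        cells.append(
            weighted_median_intensity(
                buckets[(label, tissue, cat, direction)],
                n_bins=n_bins, convention=convention,
                label=label, tissue=tissue, category=cat, direction=direction,
            )
        )
    return cells


def intensity_frame(cells: list[IntensityCell]) -> pd.DataFrame:
    """Serializable table; direction encoded by sign of the value."""
    rows = []
    for c in cells:
        signed = None
        if not c.excluded:
            signed = c.value if c.direction == "positive" else -c.value
        rows.append(
            {
                "label": c.label,
                "tissue": c.tissue,
                "category": c.category,
                "direction": c.direction,
                "n": c.n,
                "min": None if c.value_range is None else c.value_range[0],
                "max": None if c.value_range is None else c.value_range[1],
                "value": signed,
                "excluded": c.excluded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "tissue", "category", "direction", "n", "min", "max", "value", "excluded"],
    )
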