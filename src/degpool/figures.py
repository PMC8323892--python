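"""Figure rendering from pipeline output tables.

All figures are rebuilt from the written TSVs (not from in-memory
state), so they can be regenerated after the fact from a run directory:
violin/beeswarm plots of upregulated-gene counts per category,
composite intensity heatmaps (red = up in group 1, blue = up in group
2, gray = excluded), schematic 3-/4-way Venn diagrams, and the
enrichment overlap graph.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .categories import category_of_functional_group

logger = logging.getLogger(__name__)

_SAVE_KW = {"dpi": 120, "metadata": {"Date": None}}


def render_figures(run_dir, fmt: str = "png") -> list[Path]:
    """Render every figure whose source table exists; skip the rest."""
    run_dir = Path(run_dir)
    figdir = run_dir / "figures"
    figdir.mkdir(exist_ok=True)
    written = []
    jobs = [
        ("category_counts.tsv", _violin_counts, "category_counts"),
        ("intensity_cells.tsv", _intensity_heatmap, "intensity_heatmap"),
        ("venn_regions.tsv", _venn_figure, "venn"),
        ("enrichment_graph_edges.tsv", _graph_figure, "enrichment_graph"),
    ]
    for source, fn, name in jobs:
        path = run_dir / source
        if not path.exists():
            logger.warning("table %s missing; figure %s skipped", source, name)
            continue
        out = figdir / f"{name}.{fmt}"
        fig = fn(run_dir, path)
        fig.savefig(out, **_SAVE_KW)
        plt.close(fig)
        written.append(out)
    return written


def _violin_counts(run_dir: Path, path: Path):
    cells = pd.read_csv(path, sep="\t")
    cells = cells[~cells["functional_group"].str.endswith("_aggregate", na=False)]
    cells["category"] = cells["functional_group"].map(category_of_functional_group)
    tests = None
    tests_path = run_dir / "category_tests.tsv"
    if tests_path.exists():
        tests = pd.read_csv(tests_path, sep="\t")
    cats = ["HD", "DTX", "IM"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=False)
    rng = np.random.default_rng(0)
    for ax, cat in zip(axes, cats):
        sub = cells[cells["category"] == cat]
        data, labels = [], []
        for side in ("group1", "group2"):
            vals = sub.loc[sub["side"] == side, "n_up"].to_numpy(dtype=float)
            data.append(vals if len(vals) else np.array([0.0]))
            labels.append(side)
        parts = ax.violinplot(data, showmedians=True)
        for i, vals in enumerate(data, start=1):
            jitter = rng.uniform(-0.08, 0.08, size=len(vals))
            ax.plot(i + jitter, vals, "o", ms=3, alpha=0.6, color="k")
        ax.set_xticks([1, 2], labels)
        ax.set_title(cat)
        ax.set_ylabel("upregulated genes")
        if tests is not None:
            sig = tests[(tests["category"] == cat) & (tests["wilcoxon_p"] < 0.05)]
            if len(sig):
                ax.annotate("*", xy=(1.5, ax.get_ylim()[1] * 0.95), ha="center", fontsize=16)
    fig.tight_layout()
    return fig


def _intensity_heatmap(run_dir: Path, path: Path):
    cells = pd.read_csv(path, sep="\t")
    cols = [
        f"{cat}:{direction}"
        for cat in ("HD", "DTX", "IM")
        for direction in ("positive", "negative")
    ]
    rows = sorted(cells["label"].unique())
    mat = np.full((len(rows), len(cols)), np.nan)
    for _, cell in cells.iterrows():
        if bool(cell["excluded"]):
            continue
        i = rows.index(cell["label"])
        j = cols.index(f"{cell['category']}:{cell['direction']}")
        mat[i, j] = cell["value"]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.4 * len(rows))))
    vmax = np.nanmax(np.abs(mat)) if np.isfinite(mat).any() else 1.0
    if not np.isfinite(vmax) or vmax == 0:
        vmax = 1.0
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.8")  # gray: excluded / not computed
    im = ax.imshow(mat, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
    ax.set_yticks(range(len(rows)), rows, fontsize=7)
    fig.colorbar(im, ax=ax, label="signed weighted-median |log2FC|")
    fig.tight_layout()
    return fig


_VENN3_CENTERS = [(-0.4, 0.25), (0.4, 0.25), (0.0, -0.45)]
_VENN4_ELLIPSES = [
    (-0.35, 0.0, 45), (-0.12, 0.2, 45), (0.12, 0.2, 135), (0.35, 0.0, 135)
]


def _venn_figure(run_dir: Path, path: Path):
    regions = pd.read_csv(path, sep="\t")
    labels = sorted(
        {lab for region in regions["region"] for lab in region.split("&")}
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = plt.get_cmap("tab10")
    if len(labels) == 3:
        for (x, y), lab, c in zip(_VENN3_CENTERS, labels, range(3)):
            ax.add_patch(plt.Circle((x, y), 0.75, alpha=0.25, color=colors(c)))
            ax.annotate(lab, (x * 1.8, y * 1.8), ha="center", fontsize=9)
    else:
        from matplotlib.patches import Ellipse

        for (x, y, angle), lab, c in zip(_VENN4_ELLIPSES, labels, range(4)):
            ax.add_patch(
                Ellipse((x, y), 1.5, 0.8, angle=angle, alpha=0.25, color=colors(c))
            )
            ax.annotate(lab, (x * 2.2, 0.9 - 0.15 * c), ha="center", fontsize=8)
    # Region counts listed beside the schematic (layout is not proportional).
    text = "\n".join(
        f"{row['region']}: {row['count']}" for _, row in regions.iterrows() if row["count"]
    )
    ax.text(1.35, 0.5, text, transform=ax.transAxes, fontsize=7, va="center")
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    return fig


def _graph_figure(run_dir: Path, path: Path):
    import networkx as nx

    edges = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in edges.iterrows():
        graph.add_edge(row["set_a"], row["set_b"], similarity=row["similarity"])
    fig, ax = plt.subplots(figsize=(6, 5))
    if graph.number_of_nodes():
        pos = nx.spring_layout(graph, seed=0)
        nx.draw_networkx(graph, pos=pos, ax=ax, node_size=300, font_size=7)
    ax.axis("off")
    fig.tight_layout()
    return fig
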