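"""End-to-end orchestration: ingest -> QC -> normalize -> DEG -> statistics
-> intensity -> Venn -> enrichment, with a JSON run manifest.

Every stage writes its table under the configured output directory; the
manifest records the seed, every effective threshold and per-stage row
counts so a run is fully auditable.  With ``simulate=True`` the bundled
synthetic demo study is generated first and analyzed like real input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import categories, deg, gsea, intensity, io, normalize, qc, rankfit, simulate, venn
from .datatypes import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs: either simulate a demo study or point at files
    simulate: bool = True
    n_genes: int = 5000
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    contrasts_path: str | None = None
    # QC thresholds (defaults reproduce the printed rules)
    min_count_any: int = 2
    high_count: int = 10
    cpm_min: float = 1.0
    cpm_samples: int = 2
    share_threshold: float = 0.35
    min_high_count_genes: int = 1000
    low_count_mode: str = "all-samples"
    # normalization
    use_tmm: bool = True
    # DEG thresholds
    dfpkm_min: float = 1.0
    lfc_min: float = 1.0
    group_summary: str = "mean"
    include_flagged: bool = False
    # statistics
    exact_max_n: int = 25
    alpha: float = 0.05
    # intensity
    n_bins: int = 5
    median_convention: str = "midpoint"
    # enrichment
    n_perm: int = 500
    n_gene_sets: int = 30
    q_max: float = 0.05
    metric_floor: float = 1.0
    overlap_cutoff: float = 0.375
    # bookkeeping
    seed: int = 0
    outdir: str = "degpool_run"

    def __post_init__(self) -> None:
        for name in ("dfpkm_min", "lfc_min", "cpm_min", "share_threshold", "alpha", "q_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)


def _write_tsv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(frame)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    # ---- ingest -----------------------------------------------------------
    stage = "ingest"
    try:
        if config.simulate:
            sim_cfg = simulate.default_config(seed=config.seed, n_genes=config.n_genes)
            cm, design, truth = simulate.simulate_counts(sim_cfg)
            annotation = simulate.simulate_annotation(sim_cfg)
            gene_sets = simulate.simulate_gene_sets(
                annotation, n_sets=config.n_gene_sets, seed=config.seed
            )
            io.write_study(cm, design, annotation, gene_sets, truth, outdir / "inputs")
        else:
            cm, design, annotation, gene_sets = io.load_study(
                config.counts_path,
                config.metadata_path,
                config.annotation_path,
                config.gmt_path,
                config.contrasts_path,
            )
            truth = None
        manifest["stages"][stage] = {
            "n_genes": int(cm.n_genes),
            "n_samples": int(cm.n_samples),
            "n_contrasts": len(design.contrasts),
            "n_contrast_groups": len(design.contrast_groups),
        }

        # ---- QC -----------------------------------------------------------
        stage = "qc"
        sample_report = qc.flag_outlier_samples(
            cm,
            share_threshold=config.share_threshold,
            min_high_count_genes=config.min_high_count_genes,
            high_count=config.high_count,
        )
        filtered, gene_report = qc.filter_genes(
            cm,
            min_count_any=config.min_count_any,
            high_count=config.high_count,
            cpm_min=config.cpm_min,
            cpm_samples=config.cpm_samples,
            low_count_mode=config.low_count_mode,
        )
        _write_tsv(gene_report.to_frame(), outdir / "qc_gene_filters.tsv")
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(
                {"genes": gene_report.to_dict(), "samples": sample_report.to_dict()},
                fh, indent=2, sort_keys=True,
            )
        manifest["stages"][stage] = {
            "n_genes_retained": int(filtered.n_genes),
            "retention": {r.rule: r.n_after for r in gene_report.rules},
            "flagged_samples": sorted(sample_report.flagged_samples),
        }

        # ---- normalize ----------------------------------------------------
        stage = "normalize"
        factors = (
            normalize.tmm_factors(filtered) if config.use_tmm else normalize.NormFactors.unit(filtered)
        )
        fpkm = normalize.fpkm(filtered, factors)
        factors_frame = pd.DataFrame(
            {
                "sample_id": factors.factors.index,
                "tmm_factor": factors.factors.to_numpy(),
                "effective_library_size": factors.effective_library_sizes.to_numpy(),
            }
        )
        _write_tsv(factors_frame, outdir / "tmm_factors.tsv")
        manifest["stages"][stage] = {
            "reference_sample": factors.reference,
            "factor_range": [float(factors.factors.min()), float(factors.factors.max())],
        }

        # ---- DEG calling --------------------------------------------------
        stage = "deg"
        flagged = set(sample_report.flagged_samples)
        all_results: list[deg.ContrastResult] = []
        for group_name in design.contrast_groups:
            all_results.extend(
                deg.run_contrast_group(
                    design, fpkm, group_name,
                    dfpkm_min=config.dfpkm_min, lfc_min=config.lfc_min,
                    flagged_samples=flagged, include_flagged=config.include_flagged,
                    summary=config.group_summary,
                )
            )
        deg_frame = deg.contrast_result_frame(all_results)
        _write_tsv(deg_frame, outdir / "deg_calls.tsv")
        n_deg = int(deg_frame["call"].isin([deg.CALL_UP_G1, deg.CALL_UP_G2]).sum())
        manifest["stages"][stage] = {
            "n_contrasts_run": len(all_results),
            "n_deg_calls": n_deg,
            "rows": len(deg_frame),
        }

        # ---- category statistics -----------------------------------------
        stage = "category_stats"
        cells = categories.count_upregulated(all_results, annotation, design)
        cells_all = cells + categories.aggregate_category(cells, "DTX")
        _write_tsv(categories.cells_frame(cells_all), outdir / "category_counts.tsv")

        stat_rows = []
        group_of = {r.label: r.group for r in all_results}
        for group_name in design.contrast_groups:
            group_cells = [c for c in cells if group_of.get(c.contrast) == group_name]
            for cat in ("HD", "DTX", "IM"):
                pairs = categories.category_side_pairs(group_cells, cat)
                row = {"contrast_group": group_name, "category": cat, "n_pairs": len(pairs)}
                if pairs:
                    wres = categories.wilcoxon_signed_rank(pairs, exact_max_n=config.exact_max_n)
                    row.update(wilcoxon_stat=wres.statistic, wilcoxon_p=wres.p_value,
                               wilcoxon_notes=wres.notes)
                else:
                    row.update(wilcoxon_stat=np.nan, wilcoxon_p=np.nan, wilcoxon_notes="no pairs")
                cat_cells = [
                    c for c in group_cells
                    if categories.category_of_functional_group(c.functional_group) == cat
                ]
                for inter_res in _safe_interactions(cat_cells):
                    key = inter_res.full_label.removeprefix("main+")
                    row[f"p[{key}]"] = inter_res.p_value
                    if inter_res.notes:
                        row[f"notes[{key}]"] = inter_res.notes
                stat_rows.append(row)
        stats_frame = pd.DataFrame(stat_rows)
        _write_tsv(stats_frame, outdir / "category_tests.tsv")
        manifest["stages"][stage] = {
            "n_cells": len(cells_all),
            "n_tests": len(stats_frame),
        }

        # ---- intensity heatmap cells -------------------------------------
        stage = "intensity"
        int_cells = intensity.build_intensity_matrix(
            all_results, annotation, design, grouping="contrast",
            n_bins=config.n_bins, convention=config.median_convention,
        )
        _write_tsv(intensity.intensity_frame(int_cells), outdir / "intensity_cells.tsv")
        manifest["stages"][stage] = {
            "n_cells": len(int_cells),
            "n_excluded": sum(c.excluded for c in int_cells),
        }

        # ---- Venn partitions ---------------------------------------------
        stage = "venn"
        by_group: dict[str, list[deg.ContrastResult]] = {}
        for r in all_results:
            by_group.setdefault(r.group, []).append(r)
        pooled = {
            name: venn.group_deg_union(res_list, annotation)
            for name, res_list in by_group.items()
        }
        venn_info = {}
        if 3 <= len(pooled) <= 4:
            partition = venn.venn_partition(pooled)
            _write_tsv(partition.to_frame(), outdir / "venn_regions.tsv")
            venn_info = {
                "labels": list(partition.labels),
                "union_size": partition.union_size,
            }
        manifest["stages"][stage] = {
            "pooled_set_sizes": {k: len(v) for k, v in sorted(pooled.items())},
            **venn_info,
        }

        # ---- enrichment ---------------------------------------------------
        stage = "enrichment"
        enr_frames = []
        n_significant = 0
        rng = np.random.default_rng(config.seed)
        rep_contrasts = [labels[0] for labels in design.contrast_groups.values()]
        graph_written = False
        for r in all_results:
            if r.label not in rep_contrasts:
                continue
            ranked = gsea.RankedList.from_series(r.table["adj_log2fc"])
            results = gsea.permutation_significance(
                ranked, gene_sets, n_perm=config.n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            frame = gsea.results_frame(results)
            frame.insert(0, "contrast", r.label)
            enr_frames.append(frame)
            sig = gsea.significant_sets(
                results, ranked, q_max=config.q_max, metric_floor=config.metric_floor
            )
            n_significant += len(sig)
            if sig and not graph_written:
                graph = gsea.overlap_graph(sig, gene_sets, cutoff=config.overlap_cutoff)
                edges = nx_edge_frame(graph)
                _write_tsv(edges, outdir / "enrichment_graph_edges.tsv")
                import networkx as nx

                nx.write_graphml(graph, outdir / "enrichment_graph.graphml")
                graph_written = True
        if enr_frames:
            enr_all = pd.concat(enr_frames, ignore_index=True)
            _write_tsv(enr_all, outdir / "enrichment_results.tsv")
        manifest["stages"][stage] = {
            "n_contrasts_tested": len(enr_frames),
            "n_significant_sets": n_significant,
        }
    except ValidationError as err:
        raise ValidationError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _safe_interactions(cat_cells) -> list[rankfit.DropTestResult]:
    if not cat_cells:
        return []
    try:
        return rankfit.interaction_tests(cat_cells)
    except ValidationError as err:
        logger.warning("interaction tests skipped: %s", err)
        return []


def nx_edge_frame(graph) -> pd.DataFrame:
    rows = [
        {"set_a": a, "set_b": b, "similarity": data["similarity"]}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["set_a", "set_b", "similarity"])
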