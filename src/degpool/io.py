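"""Readers and writers for the pipeline's plain-text interchange formats.

Counts TSV dialect: header ``gene_id<TAB>length<TAB><sample ids...>``,
one row per gene.  Metadata and annotation are tidy TSVs keyed by
sample_id / gene_id.  Gene sets use the Broad GMT convention (set name,
description, then members, tab-separated).  Contrast definitions live in
a YAML/JSON config with ``contrasts`` and ``contrast_groups`` keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    Contrast,
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    StudyDesign,
    ValidationError,
    _as_int_counts,
)


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValidationError(f"{path}: counts TSV must have a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns="length")
    counts = pd.DataFrame(
        _as_int_counts(counts.to_numpy()), index=counts.index, columns=counts.columns
    )
    return CountMatrix(counts=counts, lengths=lengths.astype(int))


def write_counts(cm: CountMatrix, path) -> None:
    out = pd.concat([cm.lengths.rename("length"), cm.counts], axis=1)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return meta


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="gene_id", dtype=str)
    table["go_terms"] = table.get("go_terms", pd.Series("", index=table.index)).fillna("")
    return GeneAnnotation(table)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT lines need name, description, >=1 member"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_contrasts_config(path) -> tuple[list[Contrast], dict[str, list[str]]]:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    contrasts = [
        Contrast(
            label=entry["label"],
            group1=tuple(entry["group1"]),
            group2=tuple(entry["group2"]),
        )
        for entry in cfg.get("contrasts", [])
    ]
    groups = {name: list(members) for name, members in cfg.get("contrast_groups", {}).items()}
    return contrasts, groups


def write_contrasts_config(design: StudyDesign, path) -> None:
    cfg = {
        "contrasts": [
            {"label": c.label, "group1": list(c.group1), "group2": list(c.group2)}
            for c in design.contrasts
        ],
        "contrast_groups": design.contrast_groups,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_study(
    counts_path,
    metadata_path,
    annotation_path=None,
    gmt_path=None,
    contrasts_config=None,
) -> tuple[CountMatrix, StudyDesign, GeneAnnotation | None, GeneSetCollection | None]:
    """Load and cross-reference all study inputs.

    Every sample referenced by the metadata or a contrast must exist in
    the count matrix; every annotated gene and gene-set member must exist
    among the counted genes.  Violations raise :class:`ValidationError`
    naming the offending entity.
    """
    cm = read_counts(counts_path)
    meta = read_metadata(metadata_path)

    unknown_samples = set(meta.index) - set(cm.sample_ids)
    if unknown_samples:
        raise ValidationError(
            f"metadata references samples absent from counts: {sorted(unknown_samples)}"
        )
    missing_meta = set(cm.sample_ids) - set(meta.index)
    if missing_meta:
        raise ValidationError(
            f"samples without metadata: {sorted(missing_meta)}"
        )

    contrasts: list[Contrast] = []
    groups: dict[str, list[str]] = {}
    if contrasts_config is not None:
        contrasts, groups = read_contrasts_config(contrasts_config)
    design = StudyDesign(
        samples=meta.loc[list(cm.sample_ids)], contrasts=contrasts, contrast_groups=groups
    )

    annotation = None
    if annotation_path is not None:
        annotation = read_annotation(annotation_path)
        unknown_genes = set(annotation.gene_ids) - set(cm.gene_ids)
        if unknown_genes:
            raise ValidationError(
                "annotation references genes absent from counts: "
                f"{sorted(unknown_genes)[:5]}"
            )

    gene_sets = None
    if gmt_path is not None:
        gene_sets = read_gmt(gmt_path)
        universe = set(annotation.gene_ids) if annotation is not None else set(cm.gene_ids)
        for name, members in gene_sets:
            unknown = members - universe
            if unknown:
                raise ValidationError(
                    f"gene set {name!r} references unknown genes: {sorted(unknown)[:5]}"
                )
    return cm, design, annotation, gene_sets


def write_study(cm, design, annotation, gene_sets, truth, outdir) -> dict[str, Path]:
    """Write a full synthetic study as round-trippable text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "contrasts": outdir / "contrasts.yaml",
        "truth": outdir / "truth.tsv",
    }
    write_counts(cm, paths["counts"])
    write_metadata(design.samples, paths["metadata"])
    write_annotation(annotation, paths["annotation"])
    write_gmt(gene_sets, paths["gene_sets"])
    write_contrasts_config(design, paths["contrasts"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
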