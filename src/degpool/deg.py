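"""Two-criterion differential-expression calls on median-adjusted FPKM.

With single pooled samples per condition there is no within-group
dispersion to test against, so differential expression is a joint
threshold rule rather than a statistical test: a gene is called DE in a
pairwise contrast when the absolute difference of median-scaled group
mean FPKM exceeds ``dfpkm_min`` (strict) AND the adjusted log2 fold
change reaches ``lfc_min`` in magnitude.  "Adjusted" means each sample's
FPKM column is first rescaled so its median (over QC-retained genes)
equals the grand median of the per-sample medians within the contrast —
removing residual per-sample level shifts.  Genes with zero expression
in either group are not evaluable (no pseudocount is used) and carry the
call ``not_evaluable``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Contrast, StudyDesign, ValidationError
from .normalize import ExpressionMatrix

logger = logging.getLogger(__name__)

CALL_UP_G1 = "up_in_g1"
CALL_UP_G2 = "up_in_g2"
CALL_NOT_DE = "not_DE"
CALL_NOT_EVALUABLE = "not_evaluable"


@dataclass
class ContrastResult:
    """Per-gene fold-change table and calls for one pairwise contrast."""

    label: str
    group: str | None
    table: pd.DataFrame  # columns: g1_mean, g2_mean, dfpkm, adj_log2fc, call

    @property
    def deg_ids(self) -> pd.Index:
        return self.table.index[self.table["call"].isin([CALL_UP_G1, CALL_UP_G2])]

    def degs(self, direction: str | None = None) -> pd.DataFrame:
        t = self.table
        if direction is None:
            return t[t["call"].isin([CALL_UP_G1, CALL_UP_G2])]
        return t[t["call"] == direction]


def median_scaled_group_means(
    fpkm: ExpressionMatrix,
    group1: tuple[str, ...] | list[str],
    group2: tuple[str, ...] | list[str],
    summary: str = "mean",
) -> pd.DataFrame:
    """Median-scale each contrast sample's column, then summarize groups.

    Each sample's column is multiplied by (grand median of per-sample
    medians) / (its own median over retained genes); a sample whose
    median is zero is left unscaled with a warning.  Group summaries are
    the arithmetic mean (default) or median across the group's samples.
    """
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValidationError("groups must be non-empty")
    if set(group1) & set(group2):
        raise ValidationError("groups overlap")
    if len(group1) > 5 or len(group2) > 5:
        raise ValidationError("group sizes must be <= 5")
    missing = (set(group1) | set(group2)) - set(fpkm.values.columns)
    if missing:
        raise ValidationError(f"samples absent from expression matrix: {sorted(missing)}")

    cols = fpkm.values[group1 + group2]
    medians = cols.median(axis=0)
    target = float(medians.median())
    scales = pd.Series(1.0, index=cols.columns)
    nonzero = medians > 0
    if (~nonzero).any():
        logger.warning(
            "sample(s) %s have zero median FPKM; left unscaled",
            list(medians.index[~nonzero]),
        )
    scales[nonzero] = target / medians[nonzero]
    scaled = cols * scales

    if summary == "mean":
        g1 = scaled[group1].mean(axis=1)
        g2 = scaled[group2].mean(axis=1)
    elif summary == "median":
        g1 = scaled[group1].median(axis=1)
        g2 = scaled[group2].median(axis=1)
    else:
        raise ValidationError(f"unknown group summary {summary!r}")
    return pd.DataFrame({"g1_mean": g1, "g2_mean": g2})


def adjusted_log2fc(
    fpkm: ExpressionMatrix,
    group1,
    group2,
    summary: str = "mean",
) -> pd.Series:
    """Signed log2(group1/group2) of median-scaled group means.

    NaN where either group mean is zero (the gene is not evaluable in
    this contrast: it must be present in both groups to be compared).
    """
    means = median_scaled_group_means(fpkm, group1, group2, summary=summary)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(means["g1_mean"] / means["g2_mean"])
    lfc[(means["g1_mean"] == 0) | (means["g2_mean"] == 0)] = np.nan
    return lfc.rename("adj_log2fc")


def call_degs(
    fpkm: ExpressionMatrix,
    contrast: Contrast,
    dfpkm_min: float = 1.0,
    lfc_min: float = 1.0,
    group: str | None = None,
    summary: str = "mean",
) -> ContrastResult:
    """Apply the joint dFPKM / adjusted-log2FC rule to one contrast."""
    if fpkm.values.empty:
        raise ValidationError("empty gene universe")
    means = median_scaled_group_means(fpkm, contrast.group1, contrast.group2, summary=summary)
    dfpkm = (means["g1_mean"] - means["g2_mean"]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(means["g1_mean"] / means["g2_mean"])
    evaluable = (means["g1_mean"] > 0) & (means["g2_mean"] > 0)
    lfc = lfc.where(evaluable)

    call = pd.Series(CALL_NOT_DE, index=means.index, dtype=object)
    call[~evaluable] = CALL_NOT_EVALUABLE
    up1 = evaluable & (dfpkm > dfpkm_min) & (lfc >= lfc_min)
    up2 = evaluable & (dfpkm > dfpkm_min) & (lfc <= -lfc_min)
    call[up1] = CALL_UP_G1
    call[up2] = CALL_UP_G2

    table = pd.DataFrame(
        {
            "g1_mean": means["g1_mean"],
            "g2_mean": means["g2_mean"],
            "dfpkm": dfpkm,
            "adj_log2fc": lfc,
            "call": call,
        }
    )
    return ContrastResult(label=contrast.label, group=group, table=table)


def run_contrast_group(
    design: StudyDesign,
    fpkm: ExpressionMatrix,
    group_name: str,
    dfpkm_min: float = 1.0,
    lfc_min: float = 1.0,
    flagged_samples: set[str] | None = None,
    include_flagged: bool = False,
    summary: str = "mean",
) -> list[ContrastResult]:
    """Call DEGs for every contrast in one contrast group, in stable order.

    Contrasts containing a QC-flagged sample are skipped with a warning
    unless ``include_flagged`` is set.
    """
    flagged_samples = flagged_samples or set()
    results = []
    for contrast in design.group_contrasts(group_name):
        hit = set(contrast.samples) & flagged_samples
        if hit and not include_flagged:
            logger.warning(
                "contrast %s skipped: contains flagged sample(s) %s",
                contrast.label, sorted(hit),
            )
            continue
        results.append(
            call_degs(
                fpkm, contrast, dfpkm_min=dfpkm_min, lfc_min=lfc_min,
                group=group_name, summary=summary,
            )
        )
    return results


def contrast_result_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Long-format concatenation of per-contrast tables for serialization."""
    frames = []
    for r in results:
        frame = r.table.reset_index(names="gene_id")
        frame.insert(0, "contrast", r.label)
        frame.insert(1, "contrast_group", r.group)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["contrast", "contrast_group", "gene_id", "g1_mean", "g2_mean",
                     "dfpkm", "adj_log2fc", "call"]
        )
    return pd.concat(frames, ignore_index=True)
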