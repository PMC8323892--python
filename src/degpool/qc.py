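"""Gene- and sample-level quality filters.

Three gene filters are applied in declared order:

R1  drop genes whose maximum count across samples is < 2 (i.e. the gene
    never reaches 2 counts in any sample);
R2  keep genes with a count of >= 10 in at least one sample;
R3  the expression filter: keep genes with >= 1 count per million (CPM,
    computed with the current raw library sizes) in at least two samples.

Sample-level QC flags (never removes) samples whose 100 largest gene
counts exceed 35% of the library (PCR/bottleneck signature) or that have
very few genes with >= 10 counts.  Whether a flagged sample is excluded
from contrasts is a caller decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FilterRuleRecord:
    rule: str
    threshold: str
    n_before: int
    n_removed: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_before - self.n_removed != self.n_after:
            raise ValidationError(
                f"rule {self.rule}: before - removed != after "
                f"({self.n_before} - {self.n_removed} != {self.n_after})"
            )


@dataclass
class FilterReport:
    """Ordered record of every filter rule's effect plus sample flags."""

    rules: list[FilterRuleRecord] = field(default_factory=list)
    flagged_samples: dict[str, str] = field(default_factory=dict)
    top100_share: dict[str, float] = field(default_factory=dict)
    library_sizes_used: dict[str, int] = field(default_factory=dict)

    def add_rule(self, rule: str, threshold: str, n_before: int, n_after: int) -> None:
        self.rules.append(
            FilterRuleRecord(rule, threshold, n_before, n_before - n_after, n_after)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rules])

    def to_dict(self) -> dict:
        return {
            "rules": [vars(r) for r in self.rules],
            "flagged_samples": self.flagged_samples,
            "top100_share": self.top100_share,
            "library_sizes_used": self.library_sizes_used,
        }


def filter_genes(
    cm: CountMatrix,
    min_count_any: int = 2,
    high_count: int = 10,
    high_count_samples: int = 1,
    cpm_min: float = 1.0,
    cpm_samples: int = 2,
    low_count_mode: str = "all-samples",
) -> tuple[CountMatrix, FilterReport]:
    """Apply the three gene-level filters in order; return matrix + report.

    ``low_count_mode`` selects the reading of the "< 2 counts" rule:
    ``"all-samples"`` (default) drops a gene only when it is below the
    threshold in every sample; ``"any-sample"`` drops a gene when any
    single sample is below the threshold.
    """
    report = FilterReport()
    counts = cm.counts

    # R1: low-count removal.
    if low_count_mode == "all-samples":
        keep1 = counts.max(axis=1) >= min_count_any
    elif low_count_mode == "any-sample":
        keep1 = counts.min(axis=1) >= min_count_any
    else:
        raise ValidationError(f"unknown low_count_mode {low_count_mode!r}")
    report.add_rule(
        "R1_low_count",
        f"max count < {min_count_any} ({low_count_mode})",
        len(keep1),
        int(keep1.sum()),
    )
    counts = counts[keep1]

    # R2: require a high-count observation.
    keep2 = (counts >= high_count).sum(axis=1) >= high_count_samples
    report.add_rule(
        "R2_high_count",
        f">= {high_count} in >= {high_count_samples} sample(s)",
        len(keep2),
        int(keep2.sum()),
    )
    counts = counts[keep2]

    # R3: expression filter on CPM with current (raw) library sizes.
    lib = cm.counts.sum(axis=0)  # raw sizes, not sizes of the filtered matrix
    report.library_sizes_used = {s: int(v) for s, v in lib.items()}
    if (lib == 0).any():
        raise ValidationError("zero library size; cannot compute CPM")
    cpm = counts * 1e6 / lib
    keep3 = (cpm >= cpm_min).sum(axis=1) >= cpm_samples
    report.add_rule(
        "R3_expression",
        f"CPM >= {cpm_min} in >= {cpm_samples} samples",
        len(keep3),
        int(keep3.sum()),
    )
    counts = counts[keep3]

    if counts.empty:
        logger.warning("all genes removed by QC filters")
    filtered = CountMatrix(counts=counts, lengths=cm.lengths.loc[counts.index])
    return filtered, report


def flag_outlier_samples(
    cm: CountMatrix,
    share_threshold: float = 0.35,
    min_high_count_genes: int = 1000,
    high_count: int = 10,
) -> FilterReport:
    """Flag samples dominated by few genes or with few well-covered genes.

    A sample is flagged when the sum of its 100 largest gene counts
    exceeds ``share_threshold`` of its library size, or when fewer than
    ``min_high_count_genes`` genes reach ``high_count`` counts.  Flags
    are advisory: the matrix is not modified.
    """
    report = FilterReport()
    lib = cm.library_sizes
    n_before = cm.n_samples
    top100_possible = cm.n_genes >= 100
    if not top100_possible:
        logger.warning(
            "matrix has %d genes (< 100); top-100 share rule skipped", cm.n_genes
        )
    for sample in cm.sample_ids:
        col = cm.counts[sample].to_numpy()
        if lib[sample] > 0 and top100_possible:
            top = np.sort(col)[-100:]
            share = float(top.sum() / lib[sample])
            report.top100_share[sample] = share
            if share > share_threshold:
                report.flagged_samples[sample] = (
                    f"top-100 genes hold {share:.1%} of reads "
                    f"(> {share_threshold:.0%})"
                )
                continue
        n_high = int((col >= high_count).sum())
        if n_high < min_high_count_genes:
            report.flagged_samples[sample] = (
                f"only {n_high} genes with >= {high_count} counts "
                f"(< {min_high_count_genes})"
            )
    report.add_rule(
        "S1_outlier_flags",
        f"top-100 share > {share_threshold} or < {min_high_count_genes} high-count genes",
        n_before,
        n_before - len(report.flagged_samples),
    )
    return report
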