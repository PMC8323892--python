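"""Core in-memory containers for the pooled RNA-seq analysis pipeline.

The pipeline operates on four cross-referenced objects: a gene x sample
count matrix with per-gene effective lengths (:class:`CountMatrix`), the
study design describing samples and pairwise contrasts
(:class:`StudyDesign`), a per-gene functional annotation
(:class:`GeneAnnotation`), and a flat collection of gene sets
(:class:`GeneSetCollection`).  All tabular payloads are pandas objects so
that downstream modules can rely on label alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Functional gene groups making up each targeted category.  Host-detection
#: (HD) covers olfaction/gustation, detoxification (DTX) covers xenobiotic
#: metabolism, immune defense (IM) covers the immune cascade.
CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "HD": (
        "odorant-binding protein",
        "chemosensory protein",
        "gustatory protein",
    ),
    "DTX": (
        "cytochrome P450",
        "glutathione S-transferase",
        "glutathione peroxidase",
        "ABC transporter",
        "carboxylesterase",
        "UDP-glycosyltransferase",
    ),
    "IM": (
        "serine protease/proteinase",
        "serpin",
        "general immune",
    ),
}

#: Inverse map: functional gene group -> targeted category.
GROUP_TO_CATEGORY: dict[str, str] = {
    group: cat for cat, groups in CATEGORY_GROUPS.items() for group in groups
}

TISSUES = ("head", "abdomen", "immature")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-gene effective lengths (bp).

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, genes as rows, samples as columns.
    lengths
        Positive integer Series indexed like ``counts`` rows.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()]
            raise ValidationError(f"genes without length: {list(missing[:5])}")
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample column sums of raw counts."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.lengths.loc[gene_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lengths.equals(other.lengths)


@dataclass(frozen=True)
class Contrast:
    """One pairwise comparison: two disjoint groups of 1-5 samples each."""

    label: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.group1) <= 5 and 1 <= len(self.group2) <= 5):
            raise ValidationError(
                f"contrast {self.label!r}: group sizes must be in [1, 5]"
            )
        if set(self.group1) & set(self.group2):
            raise ValidationError(f"contrast {self.label!r}: groups overlap")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group1 + self.group2


@dataclass
class StudyDesign:
    """Sample metadata, pairwise contrasts, and named contrast groups.

    ``samples`` is indexed by sample id with columns species, tissue,
    host_plant, host_family, range, treatment.  Contrast groups collect
    2-15 pairwise contrasts that address one biological question (e.g.
    all Legume-vs-Other comparisons).
    """

    samples: pd.DataFrame
    contrasts: list[Contrast] = field(default_factory=list)
    contrast_groups: dict[str, list[str]] = field(default_factory=dict)

    REQUIRED_COLUMNS = (
        "species",
        "tissue",
        "host_plant",
        "host_family",
        "range",
        "treatment",
    )

    def __post_init__(self) -> None:
        missing_cols = set(self.REQUIRED_COLUMNS) - set(self.samples.columns)
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {sorted(missing_cols)}")
        if self.samples.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(
                f"unknown tissue codes {sorted(bad_tissue)}; expected {TISSUES}"
            )
        known = set(self.samples.index)
        for contrast in self.contrasts:
            unknown = set(contrast.samples) - known
            if unknown:
                raise ValidationError(
                    f"contrast {contrast.label!r} references unknown samples "
                    f"{sorted(unknown)}"
                )
        labels = {c.label for c in self.contrasts}
        for name, members in self.contrast_groups.items():
            unknown = set(members) - labels
            if unknown:
                raise ValidationError(
                    f"contrast group {name!r} references unknown contrasts "
                    f"{sorted(unknown)}"
                )
            if not (2 <= len(members) <= 15):
                raise ValidationError(
                    f"contrast group {name!r} must hold 2-15 contrasts, "
                    f"has {len(members)}"
                )

    def contrast(self, label: str) -> Contrast:
        for c in self.contrasts:
            if c.label == label:
                return c
        raise KeyError(label)

    def group_contrasts(self, group_name: str) -> list[Contrast]:
        return [self.contrast(lab) for lab in self.contrast_groups[group_name]]

    def tissue_of_contrast(self, contrast: Contrast) -> str:
        """Tissue shared by a contrast's samples ('mixed' if heterogeneous)."""
        tissues = set(self.samples.loc[list(contrast.samples), "tissue"])
        return tissues.pop() if len(tissues) == 1 else "mixed"


@dataclass
class GeneAnnotation:
    """Per-gene functional annotation.

    ``table`` is indexed by gene id with columns: protein_annotation
    (free text), functional_group (one of the 12 named groups or 'none'),
    category (HD/DTX/IM/none, a function of the group), go_terms
    (semicolon-joined ids, may be empty).
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("protein_annotation", "functional_group", "category")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if "go_terms" not in self.table.columns:
            self.table = self.table.assign(go_terms="")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene ids in annotation")
        expected = self.table["functional_group"].map(
            lambda g: GROUP_TO_CATEGORY.get(g, "none")
        )
        mismatch = self.table.index[expected != self.table["category"]]
        if len(mismatch):
            raise ValidationError(
                "category must be a function of functional_group; mismatch at "
                f"{list(mismatch[:5])}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_in_category(self, category: str) -> pd.Index:
        return self.table.index[self.table["category"] == category]

    def genes_in_group(self, group: str) -> pd.Index:
        return self.table.index[self.table["functional_group"] == group]

    def category_of(self, gene_id: str) -> str:
        return self.table.at[gene_id, "category"]


@dataclass
class GeneSetCollection:
    """Named, flat gene sets (GMT semantics: name, description, members)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _as_int_counts(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("counts must be finite")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded):
        raise ValidationError("counts must be integers")
    return rounded.astype(np.int64)
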