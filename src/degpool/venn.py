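"""DEG-identity pooling per comparison group and exact Venn partitions.

DEG identities (either direction) are pooled across the contrasts of a
comparison group, optionally restricted to one targeted category, and
3-4 such pooled sets are partitioned into their exact membership
regions.  When a comparison group spans two species (whose transcript
ids come from independent assemblies), identity matching can use the
protein-annotation string instead of the transcript id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .datatypes import GeneAnnotation, ValidationError
from .deg import ContrastResult


@dataclass
class VennPartition:
    """Exact disjoint regions of 3 or 4 labelled sets."""

    labels: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]

    def count(self, *labels: str) -> int:
        return len(self.regions.get(frozenset(labels), frozenset()))

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
            members = self.regions[subset]
            rows.append(
                {
                    "region": "&".join(sorted(subset)),
                    "count": len(members),
                    "members": ";".join(sorted(members)),
                }
            )
        return pd.DataFrame(rows, columns=["region", "count", "members"])


def group_deg_union(
    results: list[ContrastResult],
    annotation: GeneAnnotation,
    category: str | None = None,
    identity: str = "gene_id",
) -> frozenset[str]:
    """Union of DEG identities (either direction) over a group's contrasts.

    ``identity="protein"`` maps transcript ids to the annotation's
    protein string (for cross-assembly comparisons).
    """
    ann = annotation.table
    pooled: set[str] = set()
    for res in results:
        degs = res.deg_ids
        if category is not None:
            cats = ann.reindex(degs)["category"]
            degs = degs[(cats == category).fillna(False)]
        if identity == "gene_id":
            pooled.update(degs)
        elif identity == "protein":
            pooled.update(ann.reindex(degs)["protein_annotation"].dropna())
        else:
            raise ValidationError(f"unknown identity mode {identity!r}")
    return frozenset(pooled)


def venn_partition(sets: dict[str, frozenset[str] | set[str]]) -> VennPartition:
    """Partition the union of 3 or 4 labelled sets into exact regions.

    Every element of the union lands in exactly one region — the one
    named by its full membership pattern — so region counts sum to the
    union's cardinality (asserted).
    """
    if not 3 <= len(sets) <= 4:
        raise ValidationError(f"need 3 or 4 sets, got {len(sets)}")
    labels = tuple(sets)
    frozen = {k: frozenset(v) for k, v in sets.items()}
    universe = frozenset().union(*frozen.values())
    regions: dict[frozenset[str], set[str]] = {
        frozenset(combo): set()
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, r)
    }
    for element in universe:
        membership = frozenset(lab for lab in labels if element in frozen[lab])
        regions[membership].add(element)
    partition = VennPartition(
        labels=labels,
        regions={k: frozenset(v) for k, v in regions.items()},
    )
    total = partition.union_size
    if total != len(universe):
        raise AssertionError("venn regions do not partition the union")
    return partition
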