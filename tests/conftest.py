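import numpy as np
import pandas as pd
import pytest

from degpool.datatypes import Contrast, CountMatrix, GeneAnnotation
from degpool.normalize import ExpressionMatrix


def make_counts(array, gene_ids=None, sample_ids=None, lengths=None) -> CountMatrix:
    """Small CountMatrix from a 2-D list/array."""
    arr = np.asarray(array, dtype=np.int64)
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(1, n_genes + 1)]
    sample_ids = sample_ids or [f"s{j}" for j in range(1, n_samples + 1)]
    lengths = lengths if lengths is not None else [1000] * n_genes
    return CountMatrix(
        counts=pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        lengths=pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id")),
    )


def make_fpkm(array, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    arr = np.asarray(array, dtype=float)
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(1, n_genes + 1)]
    sample_ids = sample_ids or [f"s{j}" for j in range(1, n_samples + 1)]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        unit="FPKM",
    )


def make_annotation(groups: dict[str, str]) -> GeneAnnotation:
    """gene id -> functional group ('none' allowed)."""
    from degpool.datatypes import GROUP_TO_CATEGORY

    table = pd.DataFrame(
        {
            "protein_annotation": {g: grp for g, grp in groups.items()},
            "functional_group": pd.Series(groups),
            "category": {g: GROUP_TO_CATEGORY.get(grp, "none") for g, grp in groups.items()},
            "go_terms": "",
        }
    )
    table.index.name = "gene_id"
    return GeneAnnotation(table)


@pytest.fixture(scope="session")
def demo_study():
    """A small simulated study shared by read-only tests."""
    import degpool as dp

    cfg = dp.default_config(seed=11, n_genes=2500)
    cm, design, truth = dp.simulate_counts(cfg)
    annotation = dp.simulate_annotation(cfg)
    gene_sets = dp.simulate_gene_sets(annotation, n_sets=12, seed=11)
    return dict(
        config=cfg, counts=cm, design=design, truth=truth,
        annotation=annotation, gene_sets=gene_sets,
    )


@pytest.fixture()
def two_group_contrast():
    return Contrast(label="A_vs_B", group1=("s1", "s2"), group2=("s3", "s4"))
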