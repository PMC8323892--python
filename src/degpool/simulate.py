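"""Synthetic study generator.

Emulates the structure of a pooled-sample host-plant RNA-seq study: each
sample is one pooled RNA preparation per locality x tissue x host-plant
condition, counts follow a negative-binomial model with sample-specific
sequencing depths, and selected gene subsets carry planted multiplicative
(log2) expression effects in chosen conditions.  A ground-truth table of
every planted effect is returned for parameter-recovery testing.

The NB model uses the mean/dispersion parameterization
``var = mu + phi * mu**2`` (standard for RNA-seq counts).  Gene lengths
are drawn uniformly; baseline per-gene abundances are log-normal so the
simulated library has the long-tailed composition real transcriptomes
show.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CATEGORY_GROUPS,
    Contrast,
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    StudyDesign,
    ValidationError,
)


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative log2 effect on a gene subset in one condition.

    ``gene_selector`` picks genes either by targeted category ("HD",
    "DTX", "IM"), by functional group name, or by an explicit count of
    otherwise-unannotated genes via ``("random", n)``.  ``condition``
    matches metadata columns, e.g. ``{"host_plant": "legume"}``: samples
    matching every key get their expected counts scaled by
    ``2**log2_effect`` for the selected genes.
    """

    gene_selector: str | tuple[str, int]
    condition: tuple[tuple[str, str], ...]
    log2_effect: float

    @staticmethod
    def make(gene_selector, condition: dict[str, str], log2_effect: float):
        return PlantedEffect(
            gene_selector=gene_selector,
            condition=tuple(sorted(condition.items())),
            log2_effect=float(log2_effect),
        )


@dataclass
class GroupSpec:
    """One sample group: a host/tissue condition replicated over localities."""

    host_plant: str
    tissue: str
    n_samples: int
    host_family: str = "unknown"
    species: str = "sp1"
    range_: str = "introduced"
    treatment: str = "maintain"

    def __post_init__(self) -> None:
        if not 1 <= self.n_samples <= 5:
            raise ValidationError("group size must be in [1, 5]")


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    group_layout: list[GroupSpec] = field(default_factory=list)
    mean_log_expression: float = 3.0   # natural-log mean of expressed-gene abundance
    sd_log_expression: float = 1.0     # natural-log sd of baseline abundance
    # A de novo assembly carries a large background of low-abundance
    # fragments; this fraction of unannotated genes gets its log-mean
    # shifted down by low_expression_shift (natural log), putting them
    # below the CPM filter at typical depths.
    low_expression_fraction: float = 0.40
    low_expression_shift: float = 6.0
    dispersion: float = 0.1            # NB phi: var = mu + phi mu^2
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    category_fractions: tuple[float, float, float] = (0.02, 0.03, 0.02)  # HD, DTX, IM
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    gene_length_range: tuple[int, int] = (200, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not self.group_layout:
            raise ValidationError("group_layout must not be empty")
        fr = self.category_fractions
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ValidationError(
                "category fractions must be non-negative and sum to <= 1"
            )
        if not all(np.isfinite(e.log2_effect) for e in self.planted_effects):
            raise ValidationError("planted effect sizes must be finite")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("invalid library_size_range")

    @property
    def n_samples(self) -> int:
        return sum(g.n_samples for g in self.group_layout)


_DEMO_FAMILY = {"legume": "Fabaceae", "citrus": "Rutaceae", "aster": "Asteraceae"}


def default_config(seed: int = 0, n_genes: int = 5000) -> SimulationConfig:
    """The bundled demo layout: 20 pooled samples over three host plants.

    Head and abdomen pools for each host (maintained on the natal host),
    plus host-switched pools for the two crop hosts; targeted-category
    effects are planted per host, and a detoxification response to the
    host switch.
    """
    layout = []
    for host in ("legume", "citrus", "aster"):
        for tissue in ("head", "abdomen"):
            layout.append(
                GroupSpec(host, tissue, 2, host_family=_DEMO_FAMILY[host])
            )
    for host in ("legume", "citrus"):
        for tissue in ("head", "abdomen"):
            layout.append(
                GroupSpec(
                    host, tissue, 2, host_family=_DEMO_FAMILY[host],
                    treatment="switch",
                )
            )
    effects = [
        PlantedEffect.make("HD", {"host_plant": "legume"}, 3.0),
        PlantedEffect.make("DTX", {"host_plant": "citrus"}, 3.0),
        PlantedEffect.make("IM", {"host_plant": "aster"}, 2.0),
        PlantedEffect.make("IM", {"treatment": "switch"}, 1.5),
    ]
    return SimulationConfig(
        n_genes=n_genes, group_layout=layout, planted_effects=effects, seed=seed
    )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Assign each gene one functional group (or none) by category fractions.

    Genes are assigned to HD/DTX/IM with the configured probabilities;
    within a category the functional group is drawn uniformly from the
    category's named groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = _gene_ids(config.n_genes)
    fr_hd, fr_dtx, fr_im = config.category_fractions
    probs = [fr_hd, fr_dtx, fr_im, 1.0 - fr_hd - fr_dtx - fr_im]
    cats = rng.choice(["HD", "DTX", "IM", "none"], size=config.n_genes, p=probs)
    groups = np.empty(config.n_genes, dtype=object)
    for i, cat in enumerate(cats):
        if cat == "none":
            groups[i] = "none"
        else:
            groups[i] = rng.choice(CATEGORY_GROUPS[cat])
    table = pd.DataFrame(
        {
            "protein_annotation": [
                g if g != "none" else "uncharacterized protein" for g in groups
            ],
            "functional_group": groups,
            "category": cats,
            "go_terms": "",
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotation(table)


def _select_genes(
    selector,
    annotation: GeneAnnotation,
    rng: np.random.Generator,
    expressed: pd.Index | None = None,
) -> pd.Index:
    if isinstance(selector, tuple) and selector[0] == "random":
        pool = annotation.table.index[annotation.table["category"] == "none"]
        if expressed is not None:
            pool = pool.intersection(expressed)
        n = int(selector[1])
        if n > len(pool):
            raise ValidationError(f"cannot select {n} genes from {len(pool)} unannotated")
        return pd.Index(sorted(rng.choice(pool, size=n, replace=False)))
    if selector in CATEGORY_GROUPS:
        return annotation.genes_in_category(selector)
    genes = annotation.genes_in_group(selector)
    if len(genes) == 0:
        raise ValidationError(f"unknown gene selector {selector!r}")
    return genes


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, StudyDesign, pd.DataFrame]:
    """Draw the count matrix, study design and planted-effect truth table.

    Returns
    -------
    counts
        NB-distributed integer counts with sample-specific depths.
    design
        Metadata plus pairwise contrasts between every pair of groups
    truth
        One row per (planted effect x gene): gene_id, condition, the
        true log2 effect, and the gene's targeted category.
    """
    annotation = simulate_annotation(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_genes = config.n_genes
    genes = list(annotation.gene_ids)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )
    # Baseline relative abundance per gene (shared across samples): a main
    # expressed component plus a low-abundance background restricted to
    # unannotated genes (targeted-category genes are real, expressed genes).
    log_mean = np.full(n_genes, config.mean_log_expression)
    unannotated = (annotation.table["category"] == "none").to_numpy()
    background = unannotated & (rng.random(n_genes) < config.low_expression_fraction)
    log_mean[background] -= config.low_expression_shift
    base = np.exp(rng.normal(log_mean, config.sd_log_expression))
    expressed_index = annotation.table.index[~background]

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for gi, grp in enumerate(config.group_layout, start=1):
        for si in range(1, grp.n_samples + 1):
            sid = f"{grp.host_plant[:3]}_{grp.tissue[0]}{gi}s{si}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "species": grp.species,
                    "tissue": grp.tissue,
                    "host_plant": grp.host_plant,
                    "host_family": grp.host_family,
                    "range": grp.range_,
                    "treatment": grp.treatment,
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # Per-sample expected composition: baseline times planted fold changes.
    effect_matrix = np.ones((n_genes, len(sample_ids)))
    truth_rows: list[dict] = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    for effect in config.planted_effects:
        sel = _select_genes(effect.gene_selector, annotation, rng, expressed_index)
        cond = dict(effect.condition)
        mask = np.ones(len(sample_ids), dtype=bool)
        for key, value in cond.items():
            mask &= (meta[key] == value).to_numpy()
        idx = [gene_pos[g] for g in sel]
        effect_matrix[np.ix_(idx, mask)] *= 2.0 ** effect.log2_effect
        cond_str = ";".join(f"{k}={v}" for k, v in sorted(cond.items()))
        for g in sel:
            truth_rows.append(
                {
                    "gene_id": g,
                    "condition": cond_str,
                    "true_log2_effect": effect.log2_effect,
                    "true_category": annotation.category_of(g),
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "condition", "true_log2_effect", "true_category"]
    )

    depths = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=len(sample_ids),
    )
    composition = base[:, None] * effect_matrix
    frac = composition / composition.sum(axis=0, keepdims=True)
    mu = frac * depths[None, :]

    # NB via gamma-Poisson: var = mu + phi mu^2.
    phi = config.dispersion
    if phi > 0:
        shape = 1.0 / phi
        lam = rng.gamma(shape, mu * phi)
    else:
        lam = mu
    counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids
        ),
        lengths=pd.Series(lengths, index=pd.Index(genes, name="gene_id"), name="length"),
    )

    design = StudyDesign(
        samples=meta, contrasts=_default_contrasts(config, meta), contrast_groups={}
    )
    design.contrast_groups = _default_contrast_groups(design)
    return cm, design, truth


def _default_contrasts(config: SimulationConfig, meta: pd.DataFrame) -> list[Contrast]:
    """Pairwise host contrasts within tissue, plus treatment contrasts.

    Conditions are (host, tissue, treatment) cells.  Hosts are compared
    within tissue among same-treatment cells; treatments are compared
    within host x tissue.
    """
    cells: dict[tuple[str, str, str], list[str]] = {}
    for sid, row in meta.iterrows():
        key = (row["host_plant"], row["tissue"], row["treatment"])
        cells.setdefault(key, []).append(sid)
    contrasts = []
    keys = sorted(cells)
    for i, (h1, t1, tr1) in enumerate(keys):
        for h2, t2, tr2 in keys[i + 1 :]:
            if t1 != t2:
                continue
            if tr1 == tr2 and h1 != h2:
                label = f"{h1}_vs_{h2}_{t1}" + ("" if tr1 == "maintain" else f"_{tr1}")
            elif h1 == h2 and tr1 != tr2:
                label = f"{tr1}_vs_{tr2}_{h1}_{t1}"
            else:
                continue
            contrasts.append(
                Contrast(
                    label=label,
                    group1=tuple(cells[(h1, t1, tr1)]),
                    group2=tuple(cells[(h2, t2, tr2)]),
                )
            )
    return contrasts


def _default_contrast_groups(design: StudyDesign) -> dict[str, list[str]]:
    """Group the demo contrasts by the biological question they address."""
    groups: dict[str, list[str]] = {}
    for c in design.contrasts:
        label = c.label
        if "maintain_vs_switch" in label or "switch_vs_maintain" in label:
            key = "switch_vs_maintain"
        elif label.endswith("_switch"):
            key = "switched_hosts"
        elif "legume" in label:
            key = "legume_vs_other"
        else:
            key = "within_other"
        groups.setdefault(key, []).append(label)
    return {k: v for k, v in sorted(groups.items()) if 2 <= len(v) <= 15}


def simulate_gene_sets(
    annotation: GeneAnnotation,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> GeneSetCollection:
    """Sample random gene sets, guaranteeing one per targeted category.

    The first three sets (when ``n_sets >= 3`` and the category has
    enough members) are drawn from within HD, DTX and IM respectively so
    downstream enrichment has category-coherent sets to find.
    """
    if len(annotation.gene_ids) == 0:
        raise ValidationError("annotation is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    lo, hi = set_size_range
    universe = np.asarray(annotation.gene_ids)
    if hi > len(universe):
        raise ValidationError(
            f"set size {hi} exceeds gene universe of {len(universe)}"
        )
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    categories = ["HD", "DTX", "IM"]
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        pool = universe
        desc = "random gene set"
        if k < len(categories):
            members_in_cat = np.asarray(annotation.genes_in_category(categories[k]))
            if len(members_in_cat) >= lo:
                pool = members_in_cat
                size = min(size, len(pool))
                desc = f"genes in targeted category {categories[k]}"
        name = f"SET_{k + 1:03d}"
        sets[name] = frozenset(rng.choice(pool, size=size, replace=False))
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(config, seed=seed)
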