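"""Preranked gene-set enrichment: ES, NES, permutation FDR, overlap graph.

Genes are ranked by a signed metric (here the adjusted log2 fold change
of a contrast).  A gene set's enrichment score (ES) is the signed
extremum of a weighted Kolmogorov-Smirnov-like running sum: walking down
the ranking, set members ("hits") add their normalized |metric|^p
weight, non-members subtract 1/(N - N_h).  Significance comes from a
gene-label permutation null built per set size: the normalized score
NES = ES / mean(|null ES| of the same sign), the nominal p is the
same-sign null tail fraction, and the FDR q follows the positive /
negative pooling scheme of the GSEA method.  Significant sets are
assembled into an enrichment-map-style graph whose edges carry the
combined overlap similarity (mean of the Jaccard and overlap
coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, ValidationError


@dataclass
class RankedList:
    """Gene ids ordered by descending metric; ties break lexicographically."""

    gene_ids: np.ndarray
    metric: np.ndarray

    @staticmethod
    def from_series(metric: pd.Series) -> "RankedList":
        metric = metric.dropna()
        order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
        return RankedList(
            gene_ids=np.asarray(order, dtype=object),
            metric=metric.loc[order].to_numpy(dtype=float),
        )

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions_of(self, gene_set) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return np.sort([index[g] for g in gene_set if g in index])


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.nes != 0 and np.sign(self.nes) != np.sign(self.es):
            raise ValidationError("NES must carry the sign of ES")
        if not (np.isnan(self.fdr_q) or 0.0 <= self.fdr_q <= 1.0):
            raise ValidationError("FDR q outside [0, 1]")


def _es_from_positions(
    positions: np.ndarray, abs_metric: np.ndarray, n_total: int, weight_p: float
) -> tuple[float, int]:
    """ES and extremum rank position from sorted 0-based hit positions.

    The running profile only attains its extrema adjacent to hits, so
    the full N-length walk reduces to O(k) arithmetic on the hit
    positions.
    """
    k = len(positions)
    w = abs_metric[positions] ** weight_p
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    w = w / total
    miss = 1.0 / (n_total - k)
    j = np.arange(1, k + 1)
    cumw = np.cumsum(w)
    after_hit = cumw - (positions + 1 - j) * miss      # profile just after hit j
    before_hit = np.concatenate(([0.0], cumw[:-1])) - (positions - (j - 1)) * miss
    i_max = int(np.argmax(after_hit))
    i_min = int(np.argmin(before_hit))
    es_pos = float(after_hit[i_max])
    es_neg = float(before_hit[i_min])
    if abs(es_pos) >= abs(es_neg):
        return es_pos, int(positions[i_max])
    return es_neg, int(positions[i_min])


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, the full running profile, and the leading-edge genes.

    Leading edge: for a positive ES, the set members at or above the
    extremum; for a negative ES, the members at or below it.
    """
    n = len(ranked)
    positions = ranked.positions_of(gene_set)
    k = len(positions)
    if k == 0:
        raise ValidationError("gene set does not intersect the ranked universe")
    if k >= n:
        raise ValidationError("gene set covers the whole universe; ES undefined")

    es, extremum_pos = _es_from_positions(positions, np.abs(ranked.metric), n, weight_p)

    w = np.abs(ranked.metric[positions]) ** weight_p
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    profile = np.full(n, -1.0 / (n - k))
    profile[positions] = w / total
    profile = np.cumsum(profile)

    if es >= 0:
        lead_positions = positions[positions <= extremum_pos]
    else:
        lead_positions = positions[positions >= extremum_pos]
    leading = tuple(ranked.gene_ids[lead_positions])
    return es, profile, leading


def _null_es(
    ranked: RankedList, sizes: list[int], n_perm: int, weight_p: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Gene-label permutation null ES per set size (shared across sets)."""
    n = len(ranked)
    abs_metric = np.abs(ranked.metric)
    out: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        null = np.empty(n_perm)
        for b in range(n_perm):
            pos = np.sort(rng.choice(n, size=k, replace=False))
            null[b], _ = _es_from_positions(pos, abs_metric, n, weight_p)
        out[k] = null
    return out


def permutation_significance(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[EnrichmentResult]:
    """NES, nominal p and FDR q for every set via a gene-label null.

    The FDR pools normalized null and observed scores within each sign
    class:  q(S) = [fraction of null NES at least as extreme as NES(S)]
    / [fraction of observed NES at least as extreme], clipped to [0, 1]
    and made monotone in |NES| within the sign class.
    """
    if n_perm < 100:
        raise ValidationError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    universe = set(ranked.gene_ids.tolist())
    usable: list[tuple[str, list, int]] = []
    for name, members in sets:
        inter = sorted(members & universe)
        if 0 < len(inter) < len(ranked):
            usable.append((name, inter, len(inter)))
    null_by_size = _null_es(
        ranked, [k for _, _, k in usable], n_perm, weight_p, rng
    )

    # Per-size same-sign means normalize observed and null scores alike.
    norm_mean: dict[tuple[int, int], float] = {}
    for k, null in null_by_size.items():
        pos, neg = null[null >= 0], null[null < 0]
        norm_mean[(k, 1)] = float(np.mean(pos)) if len(pos) else np.nan
        norm_mean[(k, -1)] = float(np.mean(np.abs(neg))) if len(neg) else np.nan

    def normalize(es: float, k: int) -> float:
        sign = 1 if es >= 0 else -1
        denom = norm_mean[(k, sign)]
        if not np.isfinite(denom) or denom == 0:
            return 0.0
        return es / denom

    records = []
    null_nes_pool: list[float] = []
    for k, null in null_by_size.items():
        sizes_count = sum(1 for _, _, kk in usable if kk == k)
        if sizes_count == 0:
            continue
        null_nes_pool.extend(normalize(e, k) for e in null)
    null_nes_pool = np.asarray(null_nes_pool)

    for name, members, k in usable:
        es, _, leading = enrichment_score(ranked, members, weight_p)
        null = null_by_size[k]
        if es >= 0:
            same = null[null >= 0]
            p = float(np.mean(same >= es)) if len(same) else 1.0
        else:
            same = null[null < 0]
            p = float(np.mean(same <= es)) if len(same) else 1.0
        records.append(
            dict(name=name, size=k, es=es, nes=normalize(es, k), p=p, leading=leading)
        )

    obs_nes = np.asarray([r["nes"] for r in records])
    results = []
    qs = np.empty(len(records))
    for i, rec in enumerate(records):
        nes = rec["nes"]
        if nes >= 0:
            null_frac_denom = max(int(np.sum(null_nes_pool >= 0)), 1)
            null_frac = np.sum(null_nes_pool >= nes) / null_frac_denom
            obs_denom = max(int(np.sum(obs_nes >= 0)), 1)
            obs_frac = np.sum(obs_nes >= nes) / obs_denom
        else:
            null_frac_denom = max(int(np.sum(null_nes_pool < 0)), 1)
            null_frac = np.sum(null_nes_pool <= nes) / null_frac_denom
            obs_denom = max(int(np.sum(obs_nes < 0)), 1)
            obs_frac = np.sum(obs_nes <= nes) / obs_denom
        qs[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0

    # Monotone in |NES| within each sign class: a more extreme set never
    # carries a larger q than a less extreme one (cummin from the weak end,
    # as in Benjamini-Hochberg).
    for sign in (1, -1):
        idx = [i for i, r in enumerate(records) if (r["nes"] >= 0) == (sign == 1)]
        idx.sort(key=lambda i: abs(records[i]["nes"]))  # ascending extremeness
        best = np.inf
        for i in idx:
            best = min(best, qs[i])
            qs[i] = best

    for rec, q in zip(records, qs):
        results.append(
            EnrichmentResult(
                name=rec["name"], size=rec["size"], es=rec["es"], nes=rec["nes"],
                p_value=rec["p"], fdr_q=float(q), leading_edge=rec["leading"],
            )
        )
    return results


def significant_sets(
    results: list[EnrichmentResult],
    ranked: RankedList,
    q_max: float = 0.05,
    metric_floor: float = 1.0,
    floor_mode: str = "leading_edge",
) -> list[EnrichmentResult]:
    """Keep sets with FDR q strictly below ``q_max`` whose signal clears
    the fold-change floor.

    ``floor_mode="leading_edge"`` (default) requires at least one
    leading-edge gene with |metric| > ``metric_floor``;
    ``"set_mean"`` requires the mean |metric| over the whole set to
    exceed the floor.
    """
    metric_of = dict(zip(ranked.gene_ids.tolist(), np.abs(ranked.metric)))
    kept = []
    for res in results:
        if not res.fdr_q < q_max:
            continue
        if floor_mode == "leading_edge":
            ok = any(metric_of.get(g, 0.0) > metric_floor for g in res.leading_edge)
        elif floor_mode == "set_mean":
            vals = [metric_of[g] for g in res.leading_edge if g in metric_of]
            ok = bool(vals) and float(np.mean(vals)) > metric_floor
        else:
            raise ValidationError(f"unknown floor_mode {floor_mode!r}")
        if ok:
            kept.append(res)
    return kept


def combined_similarity(a: frozenset, b: frozenset) -> float:
    """Mean of the Jaccard and overlap coefficients (EnrichmentMap style)."""
    inter = len(a & b)
    if inter == 0:
        return 0.0
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return 0.5 * jaccard + 0.5 * overlap


def overlap_graph(
    significant: list[EnrichmentResult],
    sets: GeneSetCollection,
    cutoff: float = 0.375,
    coefficient: str = "combined",
    node_attributes: dict[str, dict] | None = None,
) -> nx.Graph:
    """Similarity graph over significant sets (edge when >= cutoff)."""
    if not significant:
        raise ValidationError("need at least one significant set")
    graph = nx.Graph()
    for res in significant:
        attrs = dict(
            size=res.size, es=res.es, nes=res.nes, fdr_q=res.fdr_q,
            direction="positive" if res.nes >= 0 else "negative",
        )
        if node_attributes and res.name in node_attributes:
            attrs.update(node_attributes[res.name])
        graph.add_node(res.name, **attrs)
    for i, a in enumerate(significant):
        for b in significant[i + 1 :]:
            if coefficient == "combined":
                sim = combined_similarity(sets[a.name], sets[b.name])
            elif coefficient == "jaccard":
                inter = len(sets[a.name] & sets[b.name])
                sim = inter / len(sets[a.name] | sets[b.name]) if inter else 0.0
            elif coefficient == "overlap":
                inter = len(sets[a.name] & sets[b.name])
                sim = inter / min(len(sets[a.name]), len(sets[b.name])) if inter else 0.0
            else:
                raise ValidationError(f"unknown coefficient {coefficient!r}")
            if sim >= cutoff:
                graph.add_edge(a.name, b.name, similarity=float(sim))
    return graph


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
                "p_value": r.p_value, "fdr_q": r.fdr_q,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ],
        columns=["set", "size", "es", "nes", "p_value", "fdr_q", "leading_edge"],
    )
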