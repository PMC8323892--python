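"""Between-sample normalization: TMM scale factors, CPM and FPKM.

TMM (trimmed mean of M-values) estimates a per-sample scale factor that
corrects for RNA-composition differences: genes are compared with a
reference sample on the (M, A) = (log-ratio, log-abundance) plane, both
axes are doubly trimmed (30% of M, 5% of A by default), and the factor is
2 to the precision-weighted mean of the surviving M values, with weights
from the delta-method binomial variance of M.  Factors are rescaled so
their geometric mean is one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormFactors:
    """Per-sample TMM scale factors and the derived effective library sizes."""

    factors: pd.Series
    reference: str
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("TMM factors must be positive and finite")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"geometric mean of factors is {gm}, expected 1")

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    @staticmethod
    def unit(cm: CountMatrix) -> "NormFactors":
        """All-ones factors (raw library sizes)."""
        ones = pd.Series(1.0, index=cm.sample_ids)
        return NormFactors(ones, reference=str(cm.sample_ids[0]), library_sizes=cm.library_sizes.astype(float))


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a unit tag (CPM or FPKM)."""

    values: pd.DataFrame
    unit: str
    factors: NormFactors | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "FPKM"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")


def _tmm_one_sample(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Single-sample TMM factor against the reference (unscaled)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return np.nan
    obs = obs[pos].astype(float)
    ref = ref[pos].astype(float)
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # Delta-method binomial variance of M; weights are its inverse.
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return np.nan
    w = 1.0 / var[keep]
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def choose_reference(cm: CountMatrix) -> str:
    """Sample whose upper-quartile (of scaled nonzero-inclusive counts)
    is closest to the mean upper-quartile."""
    lib = cm.library_sizes.to_numpy(dtype=float)
    scaled = cm.counts.to_numpy(dtype=float) / lib[None, :]
    uq = np.quantile(scaled, 0.75, axis=0)
    idx = int(np.argmin(np.abs(uq - uq.mean())))
    return str(cm.sample_ids[idx])


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """Compute TMM scale factors for every sample.

    A sample with no positive-count overlap with the reference gets
    factor 1 with a warning.  Returned factors have geometric mean 1.
    """
    if cm.n_samples < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = cm.library_sizes.astype(float)
    if (lib == 0).any():
        raise ValidationError("zero library size")
    if reference is None:
        reference = choose_reference(cm)
    ref_col = cm.counts[reference].to_numpy()
    raw = {}
    for sample in cm.sample_ids:
        if sample == reference:
            raw[sample] = 1.0
            continue
        f = _tmm_one_sample(
            cm.counts[sample].to_numpy(), ref_col, lib[sample], lib[reference],
            trim_m, trim_a,
        )
        if not np.isfinite(f):
            logger.warning("sample %s has no usable overlap with reference; factor 1", sample)
            f = 1.0
        raw[sample] = f
    factors = pd.Series(raw).reindex(cm.sample_ids)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, reference=reference, library_sizes=lib)


def cpm(cm: CountMatrix, factors: NormFactors | None = None) -> ExpressionMatrix:
    """Counts per million of effective (TMM-scaled) library size."""
    if factors is None:
        eff = cm.library_sizes.astype(float)
    else:
        eff = factors.effective_library_sizes.reindex(cm.sample_ids)
    if (eff <= 0).any() or eff.isna().any():
        raise ValidationError("library sizes must be positive for all samples")
    values = cm.counts * 1e6 / eff
    return ExpressionMatrix(values=values, unit="CPM", factors=factors)


def fpkm(cm: CountMatrix, factors: NormFactors | None = None) -> ExpressionMatrix:
    """Fragments per kilobase per million: counts scaled by gene length (kb)
    and effective sequencing depth (millions)."""
    if factors is None:
        eff = cm.library_sizes.astype(float)
    else:
        eff = factors.effective_library_sizes.reindex(cm.sample_ids)
    if (eff <= 0).any() or eff.isna().any():
        raise ValidationError("library sizes must be positive for all samples")
    lengths = cm.lengths.astype(float)
    values = cm.counts.mul(1e9).div(lengths, axis=0).div(eff, axis=1)
    return ExpressionMatrix(values=values, unit="FPKM", factors=factors)
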