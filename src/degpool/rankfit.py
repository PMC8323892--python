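"""Rank-based linear models and the reduction-in-dispersion test.

A rank (R) fit minimizes Jaeckel's dispersion

    D(beta) = sum_i a(R(e_i)) * e_i,   e = y - X beta,

with Wilcoxon scores a(i) = sqrt(12) * (i/(n+1) - 1/2) and midranks for
ties.  For Wilcoxon scores the identity

    D(beta) = sqrt(12) / (2 (n+1)) * sum_{i<j} |e_i - e_j|

reduces the minimization to an L1 (median) regression on the pairwise-
differenced data, which is solved exactly; a Nelder-Mead polish on D
itself guards against solver corner cases.  Nested models are compared
with the drop-in-dispersion F statistic

    F = (RD / q) / (tau_hat / 2),  RD = D(reduced) - D(full),

where tau_hat is the Koul-Sievers-McKean estimate of the Wilcoxon scale
parameter tau = (sqrt(12) * integral of f^2)^(-1), referenced to
F(q, n - p_full - 1).  The response (here: DEG counts per cell) is
treated as continuous for ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .categories import CountCell, cells_frame
from .datatypes import ValidationError


def wilcoxon_scores(n: int) -> np.ndarray:
    """a(i) = sqrt(12) (i/(n+1) - 1/2), i = 1..n; sums to 0, mean-square -> 1."""
    i = np.arange(1, n + 1)
    return np.sqrt(12.0) * (i / (n + 1) - 0.5)


def jaeckel_dispersion(residuals: np.ndarray) -> float:
    """D(e) = sum a(R(e_i)) e_i with Wilcoxon scores and midranks."""
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    ranks = stats.rankdata(e)
    a = np.sqrt(12.0) * (ranks / (n + 1) - 0.5)
    return float(np.sum(a * e))


@dataclass
class RankFitResult:
    labels: list[str]
    coefficients: np.ndarray
    intercept: float
    dispersion: float
    tau_hat: float
    n: int
    rank: int
    residuals: np.ndarray

    @property
    def p(self) -> int:
        """Number of fitted parameters including the intercept."""
        return len(self.coefficients) + 1


@dataclass
class DropTestResult:
    full_label: str
    reduced_label: str
    reduction: float
    df_num: int
    df_den: int
    f_statistic: float
    p_value: float
    notes: str = ""

    def __post_init__(self) -> None:
        if self.reduction < 0:
            raise ValidationError("reduction in dispersion must be >= 0")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


def _design_array(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), [str(c) for c in design.columns]
    arr = np.asarray(design, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _check_full_rank(xc: np.ndarray, labels: list[str]) -> int:
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        _, rmat = np.linalg.qr(xc)
        diag = np.abs(np.diag(rmat))
        tol = max(xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [labels[j] for j in np.where(diag <= tol)[0]]
        raise ValidationError(
            f"design is rank deficient after centering; collinear columns: {bad or labels}"
        )
    return rank


def koul_sievers_mckean_tau(
    residuals: np.ndarray, p: int, delta: float | None = None
) -> float:
    """KSM window estimator of the Wilcoxon scale parameter tau.

    Bandwidth: the delta-quantile of the pairwise absolute residual
    differences (the p smallest dropped) scaled by 1/sqrt(n); delta
    defaults to 0.80 (0.95 when n/p <= 5).  A degrees-of-freedom
    correction sqrt(n / (n - p - 1)) is applied.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if n <= p + 1:
        raise ValidationError("too few observations to estimate tau")
    if delta is None:
        delta = 0.80 if n / max(p, 1) > 5 else 0.95
    diffs = np.abs(e[:, None] - e[None, :])[np.triu_indices(n, k=1)]
    diffs = np.sort(diffs)[p:]
    if len(diffs) == 0 or diffs[-1] == 0:
        return np.finfo(float).tiny  # exact fit: no dispersion scale
    tdelta = np.quantile(diffs, delta) / np.sqrt(n)
    n_window = int(np.sum(diffs <= tdelta))
    cn = 2.0 / (n * (n - 1))
    scores = wilcoxon_scores(n)
    scores = (scores - scores.mean()) / np.sqrt(np.sum((scores - scores.mean()) ** 2) / (n + 1))
    dn = scores[-1] - scores[0]
    tau = np.sqrt(n / (n - p - 1.0)) * (2.0 * tdelta) / (dn * n_window * cn)
    return float(tau)


def _weighted_median_line_search(x_col: np.ndarray, partial: np.ndarray) -> float | None:
    """Exact minimizer of b -> D(partial - b * x_col) (midpoint convention).

    Over pairs (i, j), D is proportional to sum w_k |t_k - b| with
    breakpoints t_k = (c_i - c_j)/(x_i - x_j) and weights |x_i - x_j|;
    the minimum is the weighted median of the t_k, taking the interval
    midpoint when the optimum is flat.
    """
    n = len(x_col)
    iu, ju = np.triu_indices(n, k=1)
    dx = x_col[iu] - x_col[ju]
    keep = dx != 0
    if not keep.any():
        return None
    dc = partial[iu][keep] - partial[ju][keep]
    t = dc / dx[keep]
    w = np.abs(dx[keep])
    order = np.argsort(t)
    t, w = t[order], w[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half, side="left"))
    if np.isclose(cum[k], half) and k + 1 < len(t):
        return float(0.5 * (t[k] + t[k + 1]))
    return float(t[k])


def rank_fit(design, response, polish: bool = True) -> RankFitResult:
    """Wilcoxon-score rank regression by exact pairwise-difference LAD.

    ``design`` (n x p, no intercept column) may be a DataFrame or array;
    the intercept is estimated afterwards as the median of the residuals.
    """
    x, labels = _design_array(design)
    y = np.asarray(response, dtype=float)
    n, p_cols = x.shape
    if n <= p_cols:
        raise ValidationError(f"need n > p, got n={n}, p={p_cols}")
    if p_cols == 0:
        # Intercept-only model: dispersion of the raw response.
        residuals = y.copy()
        return RankFitResult(
            labels=[], coefficients=np.empty(0), intercept=float(np.median(y)),
            dispersion=max(jaeckel_dispersion(y), 0.0),
            tau_hat=koul_sievers_mckean_tau(y, 0), n=n, rank=0, residuals=residuals,
        )
    xc = x - x.mean(axis=0)
    rank = _check_full_rank(xc, labels)

    beta_ls, *_ = np.linalg.lstsq(xc, y - y.mean(), rcond=None)
    d_ls = jaeckel_dispersion(y - x @ beta_ls)
    best_beta, best_d = beta_ls, d_ls

    if best_d > 1e-12:
        iu, ju = np.triu_indices(n, k=1)
        dy = y[iu] - y[ju]
        dx = x[iu] - x[ju]
        try:
            from statsmodels.regression.quantile_regression import QuantReg

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qr = QuantReg(dy, dx).fit(q=0.5, max_iter=2000)
            beta_qr = np.asarray(qr.params, dtype=float)
            d_qr = jaeckel_dispersion(y - x @ beta_qr)
            if d_qr < best_d:
                best_beta, best_d = beta_qr, d_qr
        except Exception:  # solver failure: fall through to polish
            pass

        if polish:
            res = optimize.minimize(
                lambda b: jaeckel_dispersion(y - x @ b),
                best_beta,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if res.fun < best_d:
                best_beta, best_d = res.x, float(res.fun)
        # Exact coordinate-wise line searches: D is piecewise linear in each
        # coordinate, so the 1-D minimum is a weighted median over the
        # breakpoints; the midpoint rule centers flat optima (making the
        # binary-covariate slope the classical Hodges-Lehmann midpoint).
        best_beta = np.asarray(best_beta, dtype=float).copy()
        for _ in range(20):
            moved = 0.0
            for j in range(p_cols):
                partial = y - x @ best_beta + x[:, j] * best_beta[j]
                new = _weighted_median_line_search(x[:, j], partial)
                if new is not None:
                    moved = max(moved, abs(new - best_beta[j]))
                    best_beta[j] = new
            if moved < 1e-12:
                break
        best_d = jaeckel_dispersion(y - x @ best_beta)

    residuals = y - x @ best_beta
    intercept = float(np.median(residuals))
    tau = koul_sievers_mckean_tau(residuals, p_cols)
    return RankFitResult(
        labels=labels,
        coefficients=np.asarray(best_beta, dtype=float),
        intercept=intercept,
        dispersion=max(best_d, 0.0),
        tau_hat=tau,
        n=n,
        rank=rank,
        residuals=residuals,
    )


def drop_in_dispersion_test(
    full_design, reduced_design, response,
    full_label: str = "full", reduced_label: str = "reduced",
) -> DropTestResult:
    """F-type test of the columns present in full but not in reduced."""
    xf, labels_f = _design_array(full_design)
    xr, labels_r = _design_array(reduced_design)
    if isinstance(full_design, pd.DataFrame) and isinstance(reduced_design, pd.DataFrame):
        if not set(reduced_design.columns) <= set(full_design.columns):
            raise ValidationError("models are not nested: reduced columns not in full")
    else:
        # Nestedness for unlabeled arrays: every reduced column must lie in
        # the full design's column space.
        proj, *_ = np.linalg.lstsq(xf, xr, rcond=None)
        if not np.allclose(xf @ proj, xr, atol=1e-8):
            raise ValidationError("models are not nested")
    q = xf.shape[1] - xr.shape[1]
    if q < 0:
        raise ValidationError("reduced model has more columns than full model")

    fit_full = rank_fit(xf if not isinstance(full_design, pd.DataFrame) else full_design, response)
    if q == 0:
        return DropTestResult(full_label, reduced_label, 0.0, 0, fit_full.n - fit_full.p, 0.0, 1.0,
                              notes="identical models")
    fit_red = rank_fit(xr if not isinstance(reduced_design, pd.DataFrame) else reduced_design, response)
    rd = max(fit_red.dispersion - fit_full.dispersion, 0.0)
    df_den = fit_full.n - fit_full.p
    if fit_full.tau_hat <= np.finfo(float).tiny * 10:
        f_stat = 0.0 if rd == 0 else np.inf
        p = 1.0 if rd == 0 else 0.0
        return DropTestResult(full_label, reduced_label, rd, q, df_den, f_stat, p,
                              notes="degenerate: exact fit")
    f_stat = (rd / q) / (fit_full.tau_hat / 2.0)
    p = float(stats.f.sf(f_stat, q, df_den))
    return DropTestResult(full_label, reduced_label, rd, q, df_den, f_stat, p)


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment coding: first (sorted) level is the reference."""
    levels = sorted(series.unique())
    return pd.DataFrame(
        {f"{prefix}[{lev}]": (series == lev).astype(float) for lev in levels[1:]},
        index=series.index,
    )


def _interaction(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for ca in a.columns:
        for cb in b.columns:
            cols[f"{ca}:{cb}"] = a[ca] * b[cb]
    return pd.DataFrame(cols, index=a.index)


INTERACTIONS = (
    ("host", "tissue"),
    ("host", "functional_group"),
    ("tissue", "functional_group"),
)


def interaction_tests(
    cells: list[CountCell], category: str | None = None
) -> list[DropTestResult]:
    """Test each pairwise interaction among host side, tissue and gene group.

    Response: upregulated-gene count per cell.  For every interaction,
    full = three main effects + that interaction; reduced = main effects
    only.  An interaction involving a single-level factor is skipped with
    an explanatory note.
    """
    frame = cells_frame(cells)
    if category is not None:
        from .categories import category_of_functional_group

        frame = frame[
            frame["functional_group"].map(category_of_functional_group) == category
        ]
    if frame.empty:
        raise ValidationError("no cells to test")
    frame = frame.reset_index(drop=True)
    factors = {
        "host": frame["side"],
        "tissue": frame["tissue"],
        "functional_group": frame["functional_group"],
    }
    y = frame["n_up"].astype(float)
    dummies = {name: _dummies(s, name) for name, s in factors.items()}
    main = pd.concat([d for d in dummies.values() if d.shape[1] > 0], axis=1)

    results = []
    for fa, fb in INTERACTIONS:
        label = f"{fa}:{fb}"
        if dummies[fa].shape[1] == 0 or dummies[fb].shape[1] == 0:
            single = fa if dummies[fa].shape[1] == 0 else fb
            results.append(
                DropTestResult(
                    full_label=f"main+{label}", reduced_label="main",
                    reduction=0.0, df_num=0, df_den=max(len(y) - main.shape[1] - 1, 1),
                    f_statistic=np.nan, p_value=np.nan,
                    notes=f"skipped: factor {single!r} has one level",
                )
            )
            continue
        inter = _interaction(dummies[fa], dummies[fb])
        full = pd.concat([main, inter], axis=1)
        results.append(
            drop_in_dispersion_test(full, main, y, full_label=f"main+{label}", reduced_label="main")
        )
    return results
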