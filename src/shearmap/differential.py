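"""Negative-binomial Wald testing with Benjamini-Hochberg adjustment.

One engine serves every two-condition count comparison in the pipeline:
differentially accessible regions (ATAC), differentially expressed genes
(RNA), differentially bound regions (TF/histone ChIP) and differential
loops (HiChIP). The test is a deliberately transparent DESeq2-style
procedure — median-of-ratios size factors, per-feature method-of-moments
dispersion shrunk toward a fitted mean-dispersion trend, a delta-method
standard error on the log2 fold-change, and a two-sided normal Wald
p-value — rather than a numerical clone of any particular tool.

The NB parameterization throughout is Var = mu + alpha * mu^2.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix

LN2 = np.log(2.0)

#: columns of the result table returned by :func:`nb_wald_test`
RESULT_COLUMNS = [
    "feature_id",
    "base_mean",
    "log2fc",
    "se",
    "pvalue",
    "padj",
    "significant",
]


def estimate_size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features whose counts are positive in every sample inform the
    median. When no such feature exists the per-sample totals (normalized
    to geometric mean 1) are used instead.
    """
    counts = np.asarray(m.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        log_geomean = logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logc - log_geomean, axis=0))
    else:
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts and no all-positive feature")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _fit_dispersion_trend(base_mean: np.ndarray, disp_mom: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0/mu + a1 across features.

    The fit uses the raw (possibly negative) method-of-moments estimates so
    that sampling noise averages out instead of biasing the trend upward;
    the fitted values are floored at 0 afterwards.
    """
    ok = base_mean > 0
    if ok.sum() < 2:
        return np.maximum(disp_mom, 0.0)
    X = np.column_stack([1.0 / base_mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, disp_mom[ok], rcond=None)
    a0, a1 = coef
    trend = np.zeros_like(base_mean)
    trend[ok] = a0 / base_mean[ok] + a1
    return np.maximum(trend, 0.0)


def nb_wald_test(
    m: CountMatrix,
    alpha_sig: float = 0.1,
    condition_a: Optional[str] = None,
    condition_b: Optional[str] = None,
    shrink_weight: float = 0.5,
    dispersion_floor: float = 1e-8,
    size_factors: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Two-sided NB Wald test of condition A over condition B per feature.

    By default A, B are the two conditions in sample order (the pipeline
    passes LSS as A and ST as B, so log2fc > 0 means higher under LSS).
    Returns a DataFrame with :data:`RESULT_COLUMNS`; ``significant`` is
    ``padj < alpha_sig``. All-zero features get log2fc 0 and p 1.

    ``size_factors`` overrides the median-of-ratios estimate (used e.g.
    for loop counts, which are normalized by per-sample total retained
    pairs instead).
    """
    conds = m.conditions
    if condition_a is None or condition_b is None:
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, found {conds}")
        condition_a, condition_b = conds[0], conds[1]
    cols_a = m.samples_of(condition_a)
    cols_b = m.samples_of(condition_b)
    if not cols_a or not cols_b:
        raise ValueError(f"condition without samples: {condition_a!r} vs {condition_b!r}")

    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (len(m.sample_ids),) or np.any(sf <= 0):
            raise ValueError("size_factors must be positive, one per sample")
    else:
        sf = estimate_size_factors(m)
    norm = np.asarray(m.counts, dtype=float) / sf[None, :]
    na, nb = len(cols_a), len(cols_b)
    norm_a, norm_b = norm[:, cols_a], norm[:, cols_b]
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # per-feature method-of-moments dispersion from within-condition variance,
    # then 50/50 shrinkage toward the fitted mean-dispersion trend
    if na > 1 or nb > 1:
        ss = np.zeros(norm.shape[0])
        df = 0
        if na > 1:
            ss += norm_a.var(axis=1, ddof=1) * (na - 1)
            df += na - 1
        if nb > 1:
            ss += norm_b.var(axis=1, ddof=1) * (nb - 1)
            df += nb - 1
        pooled_var = ss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            disp_mom = np.where(base_mean > 0, (pooled_var - base_mean) / base_mean**2, 0.0)
        disp_mom = np.nan_to_num(disp_mom, nan=0.0, posinf=0.0, neginf=0.0)
    else:
        disp_mom = np.zeros(norm.shape[0])
    trend = _fit_dispersion_trend(base_mean, disp_mom)
    disp = shrink_weight * np.maximum(disp_mom, 0.0) + (1.0 - shrink_weight) * trend
    disp = np.maximum(disp, dispersion_floor)

    # pseudocount 0.5 on the normalized group means before the log
    pa, pb = mu_a + 0.5, mu_b + 0.5
    log2fc = np.log2(pa / pb)

    # delta method on the NB group means: Var(mean_g) = (mu/n) * mean_j(1/s_j)
    # + alpha * mu^2 / n for each group, propagated through log2
    inv_sf_a = np.mean(1.0 / sf[cols_a])
    inv_sf_b = np.mean(1.0 / sf[cols_b])
    var_mu_a = (mu_a * inv_sf_a + disp * mu_a**2) / na
    var_mu_b = (mu_b * inv_sf_b + disp * mu_b**2) / nb
    se = np.sqrt(var_mu_a / pa**2 + var_mu_b / pb**2) / LN2

    all_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(all_zero | (se == 0), 1.0, pvalue)

    padj = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "significant": padj < alpha_sig,
        }
    )


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial P(X >= k | n, p0) (1.0 when k <= 0)."""
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must lie in [0, 1]")
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def poisson_tail(k, lam):
    """Upper-tail Poisson P(X >= k | lam), elementwise on arrays
    (1.0 wherever k <= 0)."""
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lam must be >= 0")
    out = np.where(k > 0, stats.poisson.sf(k - 1, lam), 1.0)
    return float(out) if out.ndim == 0 else out


def hypergeometric_enrichment(
    hit_set: set, annotated_set: set, universe: set
) -> float:
    """Upper-tail hypergeometric enrichment P(X >= k).

    k = |hit & annotated| successes among |hit| draws from a population of
    |universe| containing |annotated| successes (the statistic behind
    gene-set enrichment bar charts).
    """
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe or not annotated_set <= universe:
        raise ValueError("hit_set and annotated_set must be subsets of universe")
    M, K, n = len(universe), len(annotated_set), len(hit_set)
    k = len(hit_set & annotated_set)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def gene_set_enrichment(
    hits: set,
    gene_sets: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed hypergeometric enrichment over a collection of gene sets,
    BH-adjusted across sets."""
    names = sorted(gene_sets)
    pvals = [
        hypergeometric_enrichment(hits, gene_sets[name] & universe, universe)
        for name in names
    ]
    padj = bh_adjust(pvals) if names else np.array([])
    out = pd.DataFrame(
        {
            "gene_set": names,
            "n_hits": [len(hits & gene_sets[n]) for n in names],
            "n_set": [len(gene_sets[n] & universe) for n in names],
            "pvalue": pvals,
            "padj": padj,
            "significant": padj < alpha if names else [],
        }
    )
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
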