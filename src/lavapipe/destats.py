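"""Count-based differential expression: TMM normalisation factors, a
common-dispersion negative-binomial conditional exact test, BH FDR, and the
up/down/ns call rule (FDR < 0.05, |log2FC| > 1).

This is the classic count-DE pipeline (trimmed mean of M-values between-sample
scaling, conditional maximum likelihood for a single dispersion shared across
genes, and an exact test that conditions on the per-gene two-group total).
Numeric parity with any particular release of external DE packages is not a
goal; the algorithms are the published ones.

Model: counts y ~ NB(mu, phi) with Var(y) = mu + phi * mu^2, so phi = 0 is
the Poisson limit.  With a common per-sample mean within each group (achieved
by pseudo-scaling all samples to a common effective library size), the sum of
a group's counts is NB with size n/phi, and conditional on the two-group
total t the observed split follows a beta-binomial law; at phi = 0 it is
Binomial(t, n_a / (n_a + n_b)).  The two-sided p-value is the total
probability of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

__all__ = [
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "call_de",
    "exact_nb_de",
]

logger = logging.getLogger(__name__)

DISPERSION_GRID = (1e-4, 4.0)  # search interval for the common dispersion


def _as_counts(matrix) -> tuple[np.ndarray, pd.Index, pd.Index, np.ndarray]:
    if isinstance(matrix, CountMatrix):
        return (
            matrix.counts.to_numpy(dtype=float),
            matrix.features,
            matrix.samples,
            matrix.library_sizes.to_numpy(dtype=float),
        )
    df = pd.DataFrame(matrix)
    return df.to_numpy(dtype=float), df.index, df.columns, df.sum(axis=0).to_numpy(dtype=float)


def tmm_factors(
    matrix,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample vs the reference, per-gene log2 ratios (M) of
    library-scaled counts are trimmed (``logratio_trim`` from each M tail,
    ``abundance_trim`` from each A tail, rank-based) and averaged with inverse
    asymptotic-variance weights; the factor is 2 to that mean.  The automatic
    reference is the sample whose upper-quartile count fraction is closest to
    the mean upper quartile.
    """
    y, features, samples, lib = _as_counts(matrix)
    if y.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    if (y.sum(axis=0) == 0).any():
        bad = [s for s, tot in zip(samples, y.sum(axis=0)) if tot == 0]
        raise ValueError(f"samples with all-zero counts: {bad}")
    if reference is None:
        uq = np.array([np.quantile(y[:, j][y[:, j] >= 0], 0.75) / lib[j] for j in range(y.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in list(samples):
            raise ValueError(f"reference sample {reference!r} not in matrix")
        ref_idx = list(samples).index(reference)

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref_idx], lib[ref_idx]
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        yj, nj = y[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        oj, orr = yj[keep] / nj, yr[keep] / nr
        m = np.log2(oj / orr)
        a = 0.5 * np.log2(oj * orr)
        # delta-method asymptotic variance of M
        v = (nj - yj[keep]) / (nj * yj[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if trimmed.sum() == 0:
            continue
        w = 1.0 / v[trimmed]
        factors[j] = 2 ** (np.sum(w * m[trimmed]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _group_matrices(y: np.ndarray, groups: Sequence) -> list[np.ndarray]:
    labels = pd.Series(list(groups))
    return [y[:, (labels == g).to_numpy()] for g in labels.unique()]


def _cond_loglik(y_groups: list[np.ndarray], phi: float) -> float:
    """Summed conditional (on group totals) NB log-likelihood at dispersion phi."""
    r = 1.0 / phi
    total = 0.0
    for yg in y_groups:
        n = yg.shape[1]
        if n < 2:
            continue
        z = yg.sum(axis=1)
        total += float(
            np.sum(gammaln(yg + r) - gammaln(r) - gammaln(yg + 1))
            + np.sum(gammaln(z + 1) - gammaln(z + n * r) + gammaln(n * r))
        )
    return total


def _cond_loglik_poisson(y_groups: list[np.ndarray]) -> float:
    """phi -> 0 limit: counts given the total are multinomial with equal cells."""
    total = 0.0
    for yg in y_groups:
        n = yg.shape[1]
        if n < 2:
            continue
        z = yg.sum(axis=1)
        total += float(np.sum(gammaln(z + 1)) - np.sum(gammaln(yg + 1)) - np.sum(z) * np.log(n))
    return total


def estimate_common_dispersion(matrix, groups: Sequence, equalize: bool = True) -> float:
    """Estimate a single NB dispersion shared across genes by conditional ML.

    The conditional likelihood (given each gene's within-group total) is
    maximised over a log-spaced grid on [1e-4, 4] refined by bounded scalar
    optimisation.  Requires at least one group with >= 2 samples.  Library
    sizes are equalised first by scaling each sample to the geometric-mean
    library size (``equalize=False`` if the caller already did).  Returns 0.0
    when the Poisson limit fits at least as well as any positive dispersion.
    """
    y, _, _, lib = _as_counts(matrix)
    groups = list(groups)
    if len(groups) != y.shape[1]:
        raise ValueError("groups must label every sample")
    if equalize:
        geo = np.exp(np.mean(np.log(lib)))
        y = y * (geo / lib)[None, :]
    y_groups = _group_matrices(y, groups)
    if not any(g.shape[1] >= 2 for g in y_groups):
        raise ValueError("common dispersion is unidentifiable: no group has >= 2 samples")

    lo, hi = DISPERSION_GRID
    grid = np.geomspace(lo, hi, 25)
    lls = np.array([_cond_loglik(y_groups, p) for p in grid])
    best = int(np.argmax(lls))
    bracket_lo = grid[max(best - 1, 0)]
    bracket_hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -_cond_loglik(y_groups, float(np.exp(x))),
        bounds=(np.log(bracket_lo), np.log(bracket_hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    ll_phi = _cond_loglik(y_groups, phi)
    if phi <= grid[1] and _cond_loglik_poisson(y_groups) >= ll_phi - 1e-8:
        return 0.0
    return phi


def _exact_logpmf(x: np.ndarray, t: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """Log pmf of the group-A sum given total t under the conditional law."""
    if phi <= 0:
        p = n_a / (n_a + n_b)
        return (
            gammaln(t + 1)
            - gammaln(x + 1)
            - gammaln(t - x + 1)
            + x * np.log(p)
            + (t - x) * np.log1p(-p)
        )
    ra, rb = n_a / phi, n_b / phi
    return (
        gammaln(x + ra)
        - gammaln(x + 1)
        - gammaln(ra)
        + gammaln(t - x + rb)
        - gammaln(t - x + 1)
        - gammaln(rb)
        - (gammaln(t + ra + rb) - gammaln(t + 1) - gammaln(ra + rb))
    )


def nb_exact_test(
    count_sums: tuple[float, float],
    effective_sizes: tuple[float, float],
    phi: float,
) -> float:
    """Exact two-sided p-value for a two-group count split.

    ``count_sums`` are the per-group count totals after samples have been
    scaled to a common effective library size (rounded to integers here);
    ``effective_sizes`` are the group sample counts.  Conditioning on
    t = a + b, the p-value sums the probabilities of all splits no more
    likely than the observed one.  At ``phi=0`` the conditional law is
    Binomial(t, n_a/(n_a+n_b)).
    """
    a, b = count_sums
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n_a, n_b = effective_sizes
    if n_a <= 0 or n_b <= 0:
        raise ValueError("effective sizes must be positive")
    a, b = int(round(a)), int(round(b))
    t = a + b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    logp = _exact_logpmf(x, t, n_a, n_b, phi)
    obs = logp[a]
    # tolerance keeps symmetric outcomes with equal probability included
    p = float(np.exp(logp[logp <= obs + 1e-12]).sum())
    return min(p, 1.0)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Classify features as up/down/ns at FDR < fdr_max and |log2FC| > lfc_min
    (both strict)."""
    if not {"fdr", "log2fc"} <= set(table.columns):
        raise ValueError("table must carry 'fdr' and 'log2fc' columns")
    out = table.copy()
    sig = out["fdr"] < fdr_max
    out["call"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_min), "call"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_min), "call"] = "down"
    return out


def exact_nb_de(
    matrix,
    groups: Sequence,
    group_a,
    group_b,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full two-group DE pipeline: TMM -> pseudo-scaling -> common dispersion
    -> conditional exact test -> BH -> calls.

    ``groups`` labels every sample; samples outside ``group_a``/``group_b``
    are ignored.  log2FC is log2((mean CPM_A + 0.5)/(mean CPM_B + 0.5)) with
    TMM-adjusted CPM (group A over group B).  Returns a DataFrame with
    feature, log2fc, pvalue, fdr, call.
    """
    y, features, samples, lib = _as_counts(matrix)
    groups = np.asarray(list(groups))
    if len(groups) != len(samples):
        raise ValueError("groups must label every sample")
    sel_a = groups == group_a
    sel_b = groups == group_b
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {int(sel_a.sum())} vs {int(sel_b.sum())})"
        )
    sel = sel_a | sel_b
    y = y[:, sel]
    lib = lib[sel]
    sub_samples = pd.Index(samples)[sel]
    sub_groups = groups[sel]
    in_a = sub_groups == group_a

    f = tmm_factors(pd.DataFrame(y, index=features, columns=sub_samples)).to_numpy()
    eff = lib * f
    geo = np.exp(np.mean(np.log(eff)))
    pseudo = y * (geo / eff)[None, :]

    if dispersion is None:
        dispersion = estimate_common_dispersion(
            pd.DataFrame(pseudo, index=features, columns=sub_samples),
            np.where(in_a, "A", "B"),
            equalize=False,
        )
    logger.info("common dispersion: %.4g", dispersion)

    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    a_sums = pseudo[:, in_a].sum(axis=1)
    b_sums = pseudo[:, ~in_a].sum(axis=1)
    pvals = np.array(
        [nb_exact_test((a, b), (n_a, n_b), dispersion) for a, b in zip(a_sums, b_sums)]
    )

    cpm = y / eff[None, :] * 1e6
    lfc = np.log2((cpm[:, in_a].mean(axis=1) + 0.5) / (cpm[:, ~in_a].mean(axis=1) + 0.5))

    table = pd.DataFrame(
        {"feature": features, "log2fc": lfc, "pvalue": pvals, "fdr": bh_fdr(pvals)}
    )
    return call_de(table, fdr_max=fdr_max, lfc_min=lfc_min)
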