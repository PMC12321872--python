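"""Harmonization and group statistics.

Empirical-Bayes location/scale batch harmonization (ComBat), edge-wise
two-sample differential-connection tests, subnetwork chord aggregation,
one-way ANOVA with Tukey HSD, chi-square tests for discrete variables,
clinical-scale correlations with Bonferroni correction, and cross-cohort
matrix similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasMap

__all__ = [
    "combat",
    "DifferentialConnectionSet",
    "differential_connections",
    "chord_aggregate",
    "anova_tukey",
    "chi_square_test",
    "scale_correlations",
    "similarity_coefficient",
]


# ---------------------------------------------------------------------------
# ComBat harmonization
# ---------------------------------------------------------------------------

def _it_solve(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8, max_iter=10000):
    """Iterative conditional posterior means for one batch (parametric EB)."""
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(
    features: pd.DataFrame,
    batch,
    covariates: pd.DataFrame | np.ndarray | None = None,
    empirical_bayes: bool = True,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch-effect harmonization.

    Features are standardized on a covariate-adjusted fit, per-batch
    locations are shrunk under a normal prior and scales under an
    inverse-gamma prior (moment-matched, iterative conditional posteriors),
    and the data are reconstructed with covariate effects preserved.

    Parameters
    ----------
    features : DataFrame, subjects x features
    batch : array-like of batch/site labels, one per subject
    covariates : optional design columns (e.g. group dummies) whose effects
        must be preserved
    empirical_bayes : if False, use the direct per-batch location/scale
        estimates (no shrinkage)

    Single-batch input is returned unchanged with a warning.
    """
    Y = np.asarray(features, dtype=float)
    n, p = Y.shape
    batch = np.asarray(batch)
    if batch.shape[0] != n:
        raise ValueError("batch length must match number of subjects")
    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    if n_batch < 2:
        warnings.warn("single batch: ComBat is an identity transform", RuntimeWarning)
        return features.copy() if isinstance(features, pd.DataFrame) else Y.copy()
    counts = np.bincount(batch_idx)
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 subjects")
    if counts.min() < 3:
        warnings.warn("batches with < 3 subjects give unstable variance estimates", RuntimeWarning)

    B = np.zeros((n, n_batch))
    B[np.arange(n), batch_idx] = 1.0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([B, C])
    else:
        C = np.zeros((n, 0))
        X = B
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (batch + covariates)")

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    grand_mean = (counts / n) @ beta[:n_batch]
    resid = Y - X @ beta
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    stand_mean = grand_mean[None, :] + C @ beta[n_batch:]
    s_data = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.vstack([s_data[batch_idx == i].mean(axis=0) for i in range(n_batch)])
    # population (ddof=0) variance, consistent with var_pooled: keeps the
    # transform idempotent instead of shrinking variance by (n-1)/n each pass
    delta_hat = np.vstack(
        [s_data[batch_idx == i].var(axis=0, ddof=0) for i in range(n_batch)]
    )

    if empirical_bayes:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(n_batch):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1) if p > 1 else 0.0
            m = delta_hat[i].mean()
            s2 = delta_hat[i].var(ddof=1) if p > 1 else 0.0
            degenerate = t2 < 1e-12 or s2 < 1e-12 or not np.isfinite(t2) or not np.isfinite(s2)
            if degenerate:
                # flat feature-wise priors carry no information: posterior = estimate
                gamma_star[i] = gamma_hat[i]
                delta_star[i] = delta_hat[i]
                continue
            a = (2.0 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
            gamma_star[i], delta_star[i] = _it_solve(
                s_data[batch_idx == i], gamma_hat[i], delta_hat[i], g_bar, t2, a, b
            )
    else:
        gamma_star, delta_star = gamma_hat, delta_hat
    delta_star = np.where(delta_star <= 0, 1e-12, delta_star)

    adjusted = (s_data - gamma_star[batch_idx]) / np.sqrt(delta_star[batch_idx])
    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(out, index=features.index, columns=features.columns)
    return out


# ---------------------------------------------------------------------------
# Differential connections
# ---------------------------------------------------------------------------

@dataclass
class DifferentialConnectionSet:
    """Edges significant at the (corrected) alpha for one group pair."""

    group_pair: tuple[str, str]
    entries: pd.DataFrame  # columns: feature, t, p, p_corrected, mean_diff
    alpha: float
    correction: str
    all_tests: pd.DataFrame = field(repr=False, default=None)

    @property
    def count(self) -> int:
        return len(self.entries)


def differential_connections(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    group_pair: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
) -> DifferentialConnectionSet:
    """Two-sample t-test per feature; entries with corrected p < alpha.

    Student's equal-variance t by default (Welch with ``equal_var=False``);
    correction in {none, bonferroni, fdr}. Zero-pooled-variance features get
    t = 0, p = 1 and a flag. Entries are ordered by p then feature label.
    """
    if correction not in ("none", "bonferroni", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    cols = list(features_a.columns)
    if cols != list(features_b.columns):
        raise ValueError("feature columns differ between groups")
    if len(features_a) < 2 or len(features_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    A = np.asarray(features_a, dtype=float)
    Bm = np.asarray(features_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sst.ttest_ind(A, Bm, axis=0, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if correction == "none":
        p_corr = p
    elif correction == "bonferroni":
        p_corr = np.minimum(p * len(cols), 1.0)
    else:
        p_corr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "feature": cols,
            "t": t,
            "p": p,
            "p_corrected": p_corr,
            "mean_diff": A.mean(axis=0) - Bm.mean(axis=0),
            "degenerate": degenerate,
        }
    ).sort_values(["p", "feature"], kind="mergesort", ignore_index=True)
    entries = table[table["p_corrected"] < alpha].reset_index(drop=True)
    return DifferentialConnectionSet(
        group_pair=group_pair,
        entries=entries,
        alpha=alpha,
        correction=correction,
        all_tests=table,
    )


def chord_aggregate(diff: DifferentialConnectionSet, atlas: AtlasMap) -> pd.DataFrame:
    """Sum |mean difference| of differential edges into subnetwork blocks.

    Edge features must be named ``node_i-node_j``; the result is a symmetric
    subnetwork x subnetwork matrix over the atlas's block order.
    """
    blocks = atlas.subnetworks
    chord = pd.DataFrame(0.0, index=blocks, columns=blocks)
    for _, row in diff.entries.iterrows():
        try:
            ni, nj = row["feature"].split("-", 1)
        except ValueError:
            raise ValueError(f"feature {row['feature']!r} is not an edge label") from None
        si = atlas.subnetwork_of(ni)
        sj = atlas.subnetwork_of(nj)
        chord.loc[si, sj] += abs(row["mean_diff"])
        if si != sj:
            chord.loc[sj, si] += abs(row["mean_diff"])
    return chord


# ---------------------------------------------------------------------------
# Demographic / clinical tests
# ---------------------------------------------------------------------------

def anova_tukey(values, groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

    Returns (F, p, tukey table with group1/group2/meandiff/p_adj/reject).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 observations per group")
    F, p = sst.f_oneway(*samples)
    if not np.isfinite(F):  # zero between- and within-group variance
        F, p = 0.0, 1.0
    tk = pairwise_tukeyhsd(values, groups)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return float(F), float(p), table


def chi_square_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (Yates by flag). Zero marginals are
    rejected.
    """
    T = np.asarray(table)
    if np.any(T < 0) or not np.issubdtype(T.dtype, np.integer):
        T = np.asarray(table, dtype=float)
        if np.any(T < 0) or np.any(T != np.round(T)):
            raise ValueError("counts must be nonnegative integers")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = sst.chi2_contingency(T, correction=yates)
    return float(stat), float(p)


def scale_correlations(
    features: pd.DataFrame,
    scales: pd.DataFrame,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pearson r between every (feature, clinical scale) pair.

    Pairwise-complete observations; two-sided p with Bonferroni correction
    over all tested pairs. Constant scale or feature columns are flagged with
    undefined r.
    """
    rows = []
    n_tests = features.shape[1] * scales.shape[1]
    for fname in features.columns:
        for sname in scales.columns:
            x = np.asarray(features[fname], dtype=float)
            y = np.asarray(scales[sname], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 4:
                raise ValueError(f"fewer than 4 complete pairs for ({fname}, {sname})")
            if x.std() == 0 or y.std() == 0:
                rows.append((fname, sname, np.nan, np.nan, np.nan, True))
                continue
            r, p = sst.pearsonr(x, y)
            rows.append((fname, sname, r, p, min(p * n_tests, 1.0), False))
    out = pd.DataFrame(
        rows, columns=["feature", "scale", "r", "p", "p_bonferroni", "degenerate"]
    )
    if correction == "none":
        out["p_bonferroni"] = out["p"]
    return out


def similarity_coefficient(fc_a: np.ndarray, fc_b: np.ndarray) -> float:
    """Pearson correlation of the vectorized upper triangles of two matrices."""
    A = np.asarray(fc_a, dtype=float)
    Bm = np.asarray(fc_b, dtype=float)
    if A.shape != Bm.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix shapes differ or are not square: {A.shape} vs {Bm.shape}")
    iu = np.triu_indices(A.shape[0], k=1)
    r, _ = sst.pearsonr(A[iu], Bm[iu])
    return float(r)
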