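"""Statistical machinery for the pipeline: a negative-binomial exact count
test with Benjamini-Hochberg FDR control for differential transcription,
rank correlation, and group-comparison tests.

The differential test conditions on the total count of a gene across both
conditions.  With library sizes equalized via size factors, the conditional
distribution of the condition-A sum given the total is beta-binomial
(negative hypergeometric) under a common negative-binomial dispersion phi;
at phi = 0 it reduces to the exact conditional binomial test.  Two-sided
p-values double the smaller tail (capped at 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
    "group_tests",
    "differential_expression",
]


def size_factors(count_matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample scale factors (columns = samples).

    Each sample's factor is the median, over genes expressed in all samples,
    of its count divided by the gene's geometric-mean reference.  Falls back
    to total-count ratios when no gene is usable.
    """
    m = np.asarray(count_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("count matrix must be 2-D (genes x samples)")
    usable = np.all(m > 0, axis=1)
    if not np.any(usable):
        warnings.warn("no gene with nonzero counts in all samples; "
                      "using total-count size factors")
        totals = m.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total count")
        return totals / np.exp(np.mean(np.log(totals)))
    sub = m[usable]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / ref[:, None], axis=0)


def estimate_dispersion(count_matrix: np.ndarray, factors: np.ndarray,
                        groups: list | np.ndarray) -> float:
    """Common NB dispersion by method of moments on within-condition
    mean/variance of size-factor-normalized counts.

    Per-gene excess variance is pooled across genes as
    ``phi = sum_g (s_g^2 - m_g) / sum_g m_g^2`` (clipped at 0).  Pooling
    before the ratio keeps the estimator consistent with only two replicates
    per condition, where per-gene variance estimates are far too noisy to
    summarize individually.
    """
    m = np.asarray(count_matrix, dtype=float) / np.asarray(factors)[None, :]
    groups = np.asarray(groups)
    num = den = 0.0
    replicated = False
    for g in np.unique(groups):
        cols = m[:, groups == g]
        if cols.shape[1] < 2:
            continue
        replicated = True
        mean = cols.mean(axis=1)
        var = cols.var(axis=1, ddof=1)
        ok = mean > 0
        num += float(np.sum(var[ok] - mean[ok]))
        den += float(np.sum(mean[ok] ** 2))
    if not replicated:
        warnings.warn("no replicated condition; dispersion set to 0 (Poisson)")
        return 0.0
    return max(0.0, num / den) if den > 0 else 0.0


def _conditional_pmf(total: int, r_a: float, r_b: float) -> np.ndarray:
    """P(A = a | A + B = total) for A ~ NB(r_a, q), B ~ NB(r_b, q) with a
    shared success probability q (equal per-unit means): beta-binomial in a."""
    a = np.arange(total + 1)
    logp = (
        gammaln(a + r_a) - gammaln(a + 1)
        + gammaln(total - a + r_b) - gammaln(total - a + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def nb_exact_test(counts_a, counts_b, phi: float,
                  factors_a=None, factors_b=None) -> float:
    """Two-sided exact test of equal means for two groups of NB counts.

    Counts are scaled to a common library via size factors, summed per
    condition, and the condition-A sum is tested against its conditional
    distribution given the total.  At ``phi = 0`` this is the exact
    conditional binomial test with success probability n_a / (n_a + n_b).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise ValueError("counts must be >= 0")
    fa = np.ones(len(counts_a)) if factors_a is None else np.asarray(factors_a, float)
    fb = np.ones(len(counts_b)) if factors_b is None else np.asarray(factors_b, float)
    sum_a = float(np.round((counts_a / fa).sum()))
    sum_b = float(np.round((counts_b / fb).sum()))
    total = int(sum_a + sum_b)
    if total == 0:
        return 1.0
    n_a, n_b = len(counts_a), len(counts_b)
    a_obs = int(sum_a)
    if phi <= 0:
        frac = n_a / (n_a + n_b)
        lower = sps.binom.cdf(a_obs, total, frac)
        upper = sps.binom.sf(a_obs - 1, total, frac)
    else:
        pmf = _conditional_pmf(total, n_a / phi, n_b / phi)
        lower = pmf[: a_obs + 1].sum()
        upper = pmf[a_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x, y, n_perm: int = 0, rng=None) -> tuple[float, float | None]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns ``(r_s, p)``; p is a permutation p-value when ``n_perm > 0``,
    otherwise the scipy t-approximation.  Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n_perm > 0:
        rng = np.random.default_rng(rng)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ry)
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rs) - 1e-12:
                hits += 1
        return rs, (hits + 1) / (n_perm + 1)
    return rs, float(sps.spearmanr(x, y).pvalue)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (with tie correction) and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        raise ValueError("all pooled values identical")
    h /= tie
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def dunn_posthoc(groups: list) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc test, BH-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    means, sizes = [], []
    i = 0
    for g in groups:
        means.append(ranks[i : i + len(g)].mean())
        sizes.append(len(g))
        i += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (means[i] - means[j]) / se if se > 0 else 0.0
            rows.append({"group_a": i, "group_b": j, "z": z,
                         "pvalue": 2 * sps.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
    return df


def group_tests(groups: list) -> dict:
    """Omnibus Kruskal-Wallis with Dunn post-hoc, plus pairwise
    Mann-Whitney and Welch t for two-group contrasts."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    h, p = kruskal_wallis(groups)
    out = {"kruskal_h": h, "kruskal_p": p, "dunn": dunn_posthoc(groups)}
    if len(groups) == 2:
        out["mannwhitney_p"] = float(
            sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue
        )
        out["t_p"] = float(sps.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    return out


def differential_expression(
    counts: pd.DataFrame,
    groups: list | np.ndarray,
    condition_a: str = "C",
    condition_b: str = "HS",
    fdr: float = 0.01,
    fc: float = 2.0,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB exact tests with BH FDR and fold-change calls.

    ``counts``: genes x samples; ``groups``: condition label per sample.
    Calls ``induced`` (B over A) or ``repressed`` when adjusted p < ``fdr``
    and the normalized fold change exceeds ``fc``.
    """
    groups = np.asarray(groups)
    mat = counts.to_numpy(dtype=float)
    factors = size_factors(mat)
    phi = estimate_dispersion(mat, factors, groups)
    a_cols = groups == condition_a
    b_cols = groups == condition_b
    if not a_cols.any() or not b_cols.any():
        raise ValueError("both conditions must be present in groups")
    norm = mat / factors[None, :]
    mean_a = norm[:, a_cols].mean(axis=1)
    mean_b = norm[:, b_cols].mean(axis=1)
    log2_fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    pvals = np.array([
        nb_exact_test(mat[i, a_cols], mat[i, b_cols], phi,
                      factors[a_cols], factors[b_cols])
        for i in range(mat.shape[0])
    ])
    adj = bh_fdr(pvals)
    call = np.where(
        (adj < fdr) & (log2_fc > np.log2(fc)), "induced",
        np.where((adj < fdr) & (log2_fc < -np.log2(fc)), "repressed", "unchanged"),
    )
    return pd.DataFrame(
        {
            "sum_a": mat[:, a_cols].sum(axis=1),
            "sum_b": mat[:, b_cols].sum(axis=1),
            "log2_fc": log2_fc,
            "pvalue": pvals,
            "fdr": adj,
            "call": call,
            "dispersion": phi,
        },
        index=counts.index,
    )
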