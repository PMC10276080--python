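"""Two-cohort inference: rank-sum group comparisons, per-V-gene differential
usage with Benjamini-Hochberg correction, PCA of log-transformed usage, and
pairwise-complete Pearson correlation.

The Wilcoxon rank-sum test is the single group-comparison test throughout
(exact null distribution for combined n <= 25 without ties, otherwise the
normal approximation with tie and continuity correction); BH correction is
applied over the family of genes tested within one isotype.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum ``(U statistic, p)``.

    Exact enumeration is used for combined samples up to ``exact_max_n``
    without ties; larger or tied samples use the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class DifferentialUsageResult:
    table: pd.DataFrame  # gene, mean per cohort, statistic, p, p_adj
    cohorts: tuple[str, str]


def differential_usage(
    usage: pd.DataFrame, labels: pd.Series, alpha: float = DEFAULT_ALPHA
) -> DifferentialUsageResult:
    """Per-gene rank-sum tests of usage between two cohorts with BH
    adjustment.

    ``usage``: samples x genes percent matrix; ``labels``: cohort per sample.
    Genes with zero usage in every sample are excluded from testing and from
    the BH family size.
    """
    labels = pd.Series(labels, index=usage.index) if not isinstance(labels, pd.Series) else labels
    cohorts = sorted(labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly two cohorts, got {cohorts}")
    a_rows = usage.loc[labels == cohorts[0]]
    b_rows = usage.loc[labels == cohorts[1]]
    if len(a_rows) < 2 or len(b_rows) < 2:
        raise ValueError("need at least 2 samples per cohort")
    rows = []
    for gene in usage.columns:
        if (usage[gene] == 0).all():
            continue
        stat, p = wilcoxon_rank_sum(a_rows[gene], b_rows[gene])
        rows.append(
            {
                "gene": gene,
                f"mean_{cohorts[0]}": float(a_rows[gene].mean()),
                f"mean_{cohorts[1]}": float(b_rows[gene].mean()),
                "statistic": stat,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] <= alpha
    return DifferentialUsageResult(table, (cohorts[0], cohorts[1]))


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    percent_variance: np.ndarray


def pca_usage(usage: pd.DataFrame) -> PcaResult:
    """PCA of ``log2(percent usage + 1)``, columns centred.

    Components are ordered by explained variance (summing to 100%); each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    if usage.shape[0] < 2 or usage.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    x = np.log2(usage.to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    # deterministic sign: largest |loading| positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=usage.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=usage.columns, columns=comps),
        percent_variance=pct,
    )


@dataclasses.dataclass
class CorrelationResult:
    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    masked_r: pd.DataFrame  # r where p <= alpha, else NaN
    alpha: float


def pearson_pairwise_complete(
    features: pd.DataFrame, alpha: float = DEFAULT_ALPHA, min_pairs: int = 3
) -> CorrelationResult:
    """All-by-all Pearson correlation over pairwise-complete observations.

    For each feature pair the correlation is computed over the samples where
    both values are present; pairs with fewer than ``min_pairs`` complete
    observations, or zero variance among them, are undefined (NaN).  p-values
    are two-sided t-tests with ``n - 2`` degrees of freedom; ``masked_r``
    keeps only correlations with p <= alpha.
    """
    cols = list(features.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    p = np.full((k, k), np.nan)
    x = features.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            m = int(both.sum())
            n[i, j] = n[j, i] = m
            if i == j:
                if m >= 2:
                    r[i, j] = 1.0
                    p[i, j] = 0.0
                continue
            if m < min_pairs:
                continue
            xi, xj = x[both, i], x[both, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            res = sps.pearsonr(xi, xj)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    masked = rdf.where(pdf <= alpha)
    return CorrelationResult(
        r=rdf,
        n=pd.DataFrame(n, index=cols, columns=cols),
        p=pdf,
        masked_r=masked,
        alpha=alpha,
    )


def compare_group_summaries(
    metrics: pd.DataFrame, labels: pd.Series, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Rank-sum test of each per-sample metric column between two cohorts.

    Samples with a missing metric are excluded from that metric's test (a
    metric present in only one cohort raises).  Returns a table with group
    means, the test statistic, and p.
    """
    labels = pd.Series(labels, index=metrics.index) if not isinstance(labels, pd.Series) else labels
    cohorts = sorted(labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly two cohorts, got {cohorts}")
    rows = []
    for col in metrics.columns:
        vals = metrics[col]
        a = vals[(labels == cohorts[0]) & vals.notna()]
        b = vals[(labels == cohorts[1]) & vals.notna()]
        if a.empty or b.empty:
            raise ValueError(f"metric {col!r} missing for an entire cohort")
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "metric": col,
                f"mean_{cohorts[0]}": float(a.mean()),
                f"mean_{cohorts[1]}": float(b.mean()),
                "statistic": stat,
                "p": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows)
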