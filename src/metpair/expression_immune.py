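"""Expression normalization, immune scoring, clustering, and
methylation-expression integration.

Raw counts are library-size normalized to log2 CPM (log2(1e6 * count /
library_size + 1)) and z-scored per gene; the immune score of a sample
is the unweighted mean of the z-scored expression of a curated immune
gene panel (cytolytic markers, HLA, IFN-gamma pathway, chemokines,
adhesion molecules — the panel is a user-supplied input). Sample
clustering uses complete linkage on the 1 - Pearson correlation
distance. Promoter methylation is linked to expression by per-gene
Spearman correlation (genes with rho <= -0.5 are considered
methylation-regulated), and paired differential methylation uses a
two-sided Wilcoxon signed-rank test with Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def normalize_log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalization: log2(1e6 * count / library_size + 1)."""
    if (counts.values < 0).any():
        raise ValueError("raw counts must be non-negative")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample(s) with zero library size")
    return np.log2(1e6 * counts / libsize + 1)


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across samples; constant genes are dropped."""
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
        matrix = matrix.loc[~constant]
        sd = sd[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def immune_score(zscored: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Per-sample immune score: mean z-scored expression over the panel
    genes present in the matrix. Missing panel genes warn; none present
    is an error."""
    present = [g for g in gene_set if g in zscored.index]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no immune panel gene present in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} panel gene(s) missing from matrix")
    return zscored.loc[present].mean(axis=0).rename("immune_score")


def select_variable_genes(matrix: pd.DataFrame,
                          sd_threshold: float = 2.0) -> list[str]:
    """Genes whose across-sample standard deviation strictly exceeds the
    threshold (on the log scale)."""
    sd = matrix.std(axis=1, ddof=1)
    return list(matrix.index[sd > sd_threshold])


def cluster_samples(matrix: pd.DataFrame, linkage_method: str = "complete"):
    """Hierarchical clustering of samples on 1 - Pearson correlation.

    Returns (linkage matrix, sample order). Deterministic: ties are
    resolved by scipy's stable ordering over the lexicographically
    sorted sample columns.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    matrix = matrix[sorted(matrix.columns)]
    corr = np.corrcoef(matrix.values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return z, list(matrix.columns)


def methylation_expression_filter(beta: pd.DataFrame,
                                  expression: pd.DataFrame,
                                  rho_threshold: float = -0.5) -> list[str]:
    """Genes whose promoter methylation anti-correlates with expression.

    Spearman rho is computed per gene across the shared samples; genes
    with rho <= threshold are returned. Constant rows (in either matrix)
    are excluded.
    """
    genes = beta.index.intersection(expression.index)
    samples = beta.columns.intersection(expression.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    kept = []
    for gene in genes:
        b = beta.loc[gene, samples].values.astype(float)
        e = expression.loc[gene, samples].values.astype(float)
        if np.ptp(b) == 0 or np.ptp(e) == 0:
            continue
        rho = stats.spearmanr(b, e).statistic
        if rho <= rho_threshold:
            kept.append(gene)
    return kept


def differential_methylation(beta_primary: pd.DataFrame,
                             beta_metastasis: pd.DataFrame,
                             fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Paired differential methylation per gene with BH FDR control.

    Inputs are beta-value matrices (genes x patients) with matched
    columns (one primary and one metastasis per patient). Returns a
    frame with the per-gene two-sided paired Wilcoxon p-value and the
    BH-adjusted q-value.
    """
    if list(beta_primary.columns) != list(beta_metastasis.columns):
        raise ValueError("paired matrices must share patient columns")
    if beta_primary.shape[1] < 4:
        raise ValueError("need at least 4 pairs for a meaningful test")
    genes = beta_primary.index.intersection(beta_metastasis.index)
    pvals = []
    for gene in genes:
        a = beta_primary.loc[gene].values.astype(float)
        b = beta_metastasis.loc[gene].values.astype(float)
        if np.allclose(a, b):
            pvals.append(1.0)
        else:
            pvals.append(float(stats.wilcoxon(a, b, alternative="two-sided").pvalue))
    reject, qvals, _, _ = multipletests(pvals, method=fdr_method)
    return pd.DataFrame({"p": pvals, "q": qvals, "significant": reject},
                        index=genes)
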