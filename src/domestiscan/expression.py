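"""Expression filtering, τ tissue specificity, clustering, enrichment.

The specificity index τ is computed on log-transformed FPKM,
``x̂_j = log2(FPKM_j + 1)``::

    τ = Σ_j (1 − x̂_j / x̂_max) / (n − 1)

so a uniformly expressed gene scores exactly 0 and a gene expressed in a
single library scores exactly 1.  Expression profiles are clustered by
Ward-linkage hierarchical agglomeration on z-scored log profiles (a
deterministic procedure), family-in-cluster enrichment uses the
one-sided hypergeometric tail with Benjamini–Hochberg FDR control, and
co-expression partners are ranked by Pearson correlation of log
profiles — a deliberately simple, honest stand-in for module-based
intramodular connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "filter_expressed",
    "tau_index",
    "tau_table",
    "cluster_profiles",
    "family_cluster_enrichment",
    "top_coexpressed",
    "bh_adjust",
]


def filter_expressed(matrix: pd.DataFrame, min_libraries: int = 1) -> pd.Index:
    """Genes with FPKM > 0 in at least ``min_libraries`` libraries."""
    if min_libraries < 1:
        raise ValueError("min_libraries must be >= 1")
    keep = (matrix > 0).sum(axis=1) >= min_libraries
    return matrix.index[keep]


def _log_profile(v: np.ndarray) -> np.ndarray:
    return np.log2(v + 1.0)


def tau_index(fpkm_vector) -> float:
    """Tissue-specificity index τ of one gene's FPKM vector.

    Returns NaN for an all-zero vector (undefined); otherwise a value in
    [0, 1], clamped against floating-point noise.
    """
    v = np.asarray(fpkm_vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of at least two libraries")
    if np.any(v < 0):
        raise ValueError("FPKM values cannot be negative")
    if v.max() == 0:
        return float("nan")
    x = _log_profile(v)
    tau = float(np.sum(1.0 - x / x.max()) / (v.size - 1))
    return min(1.0, max(0.0, tau))


def tau_table(matrix: pd.DataFrame, min_libraries: int = 1) -> pd.DataFrame:
    """Per-gene τ with the expressed flag; τ is NaN for unexpressed genes."""
    expressed = set(filter_expressed(matrix, min_libraries))
    rows = []
    for gene, row in matrix.iterrows():
        is_exp = gene in expressed
        rows.append(
            {
                "gene_id": gene,
                "expressed": is_exp,
                "tau": tau_index(row.to_numpy()) if is_exp else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def cluster_profiles(matrix: pd.DataFrame, k: int = 7, seed=None) -> pd.Series:
    """Ward/Euclidean hierarchical clustering of z-scored log profiles.

    The tree is cut at ``k`` clusters (labels 1..k).  The procedure is
    deterministic; ``seed`` is accepted for interface symmetry and
    ignored.  Genes with a constant profile get a zero z-score vector.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError(f"fewer genes ({len(matrix)}) than clusters ({k})")
    X = _log_profile(matrix.to_numpy(dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    link = hierarchy.linkage(Z, method="ward")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def family_cluster_enrichment(
    labels: pd.Series, family_map: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric family-in-cluster enrichment with BH FDR control.

    For every (family, cluster) pair the one-sided tail
    ``P(X ≥ overlap)`` is computed over the universe of labelled genes;
    significance is called at FDR < ``alpha`` across all pairs.
    """
    labels = labels.dropna()
    fam = family_map.reindex(labels.index)
    if fam.isna().any():
        missing = list(fam.index[fam.isna()])[:5]
        raise ValueError(f"genes without family labels, e.g. {missing}")
    universe = len(labels)
    rows = []
    for family, fam_genes in fam.groupby(fam):
        n_family = len(fam_genes)
        for cluster, cl_genes in labels.groupby(labels):
            n_cluster = len(cl_genes)
            overlap = len(set(fam_genes.index) & set(cl_genes.index))
            p = float(stats.hypergeom.sf(overlap - 1, universe, n_family, n_cluster))
            rows.append(
                {
                    "family": family,
                    "cluster": cluster,
                    "universe": universe,
                    "n_family": n_family,
                    "n_cluster": n_cluster,
                    "overlap": overlap,
                    "pvalue": min(p, 1.0),
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out


def top_coexpressed(matrix: pd.DataFrame, gene: str, k: int = 20) -> pd.DataFrame:
    """Top-k co-expression partners by Pearson r of log2(FPKM+1) profiles.

    Self is excluded; partners with undefined correlation (constant
    profile) are dropped; ties are broken by gene id.  Raises for a
    constant-profile query gene (correlation undefined).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gene not in matrix.index:
        raise KeyError(gene)
    X = _log_profile(matrix.to_numpy(dtype=float))
    idx = matrix.index.get_loc(gene)
    target = X[idx]
    if np.std(target) == 0:
        raise ValueError(f"{gene}: constant profile, correlation undefined")
    tc = target - target.mean()
    denom_t = np.sqrt(np.sum(tc**2))
    rows = []
    for j, other in enumerate(matrix.index):
        if other == gene:
            continue
        oc = X[j] - X[j].mean()
        denom_o = np.sqrt(np.sum(oc**2))
        if denom_o == 0:
            continue
        r = float(np.dot(tc, oc) / (denom_t * denom_o))
        rows.append({"gene_id": other, "r": r})
    out = pd.DataFrame(rows, columns=["gene_id", "r"])
    out = out.sort_values(["r", "gene_id"], ascending=[False, True], kind="stable")
    return out.head(k).reset_index(drop=True)
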