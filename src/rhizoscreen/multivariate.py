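"""Trait screening and multivariate genotype grouping.

Covers the screening chain used after univariate analysis: selection
of variable traits by coefficient of variation (CV >= 0.3 by default,
with an explicit drop-list for traits that are deterministic functions
of others), Pearson correlation matrices with significance stars,
standardized PCA with the eigenvalue > 1 retention rule, agglomerative
hierarchical clustering (Euclidean distance, average linkage) cut into
a fixed number of groups, and one-dimensional clustering of the
summed stress tolerance score.

Traits are z-standardized before any Euclidean distance or PCA;
without standardization distances would be dominated by large-unit
traits (specific root length is of order 10^4 while tissue density is
of order 10^-1). Missing trait values are mean-imputed for PCA and
clustering only, never for univariate statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from rhizoscreen.stress import normalize_profile

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "ClusterResult",
    "filter_by_cv",
    "pearson_with_p",
    "pca_standardized",
    "ahc_cluster",
    "sts_grouping",
    "group_profiles",
]


def filter_by_cv(
    cvs: pd.Series,
    threshold: float = 0.3,
    drop: tuple[str, ...] = (),
) -> list[str]:
    """Traits whose CV meets the threshold (inclusive), minus ``drop``.

    ``drop`` lists traits excluded a priori, e.g. those computed
    deterministically from already-selected ones (root growth rate
    from maximum depth; length density from total length).
    """
    keep = cvs[cvs >= threshold].index
    return [t for t in keep if t not in set(drop)]


@dataclass
class CorrelationMatrix:
    """Pearson r, two-sided p and star classes for trait pairs."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Upper-triangle pairs as rows (trait_i, trait_j, r, p, stars)."""
        cols = self.r.columns
        rows = [
            {
                "trait_i": cols[i],
                "trait_j": cols[j],
                "r": self.r.iat[i, j],
                "p": self.p.iat[i, j],
                "stars": self.stars.iat[i, j],
            }
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
        ]
        return pd.DataFrame(rows)


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def pearson_with_p(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with t-based p-values.

    ``matrix`` is observations × traits. For each pair, r uses the
    complete cases and p comes from t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom. Pairs with fewer than 3 complete cases, or
    involving a constant trait, are missing-flagged.
    """
    cols = list(matrix.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    x = matrix.to_numpy(dtype=float)
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, np.isfinite(x[:, i]).sum()
        for j in range(i + 1, k):
            mask = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            nij = int(mask.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3:
                continue
            xi, xj = x[mask, i], x[mask, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            rij, pij = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    stars = np.vectorize(_star)(p)
    np.fill_diagonal(stars, "")
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationMatrix(r=as_df(r), p=as_df(p), stars=as_df(stars), n=as_df(n))


@dataclass
class PCAResult:
    """Correlation-matrix PCA: eigenvalues, loadings and retention."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # traits × components
    explained_pct: np.ndarray
    n_retained: int
    imputed: list[str]
    dropped: list[str]

    @property
    def retained_pct(self) -> float:
        return float(self.explained_pct[: self.n_retained].sum())


def pca_standardized(matrix: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a genotype × trait table.

    Traits are z-scored; components with eigenvalue > 1 are retained
    (Kaiser rule). Missing values are imputed with the trait mean and
    the affected traits recorded; constant traits are dropped with a
    warning. Needs at least 2 traits and 3 observations.
    """
    matrix = matrix.copy()
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 observations for PCA")
    dropped = [c for c in matrix.columns if matrix[c].std(ddof=0) == 0
               or matrix[c].isna().all()]
    if dropped:
        warnings.warn(f"dropping constant trait(s) from PCA: {dropped}",
                      stacklevel=2)
        matrix = matrix.drop(columns=dropped)
    imputed = [c for c in matrix.columns if matrix[c].isna().any()]
    if imputed:
        matrix = matrix.fillna(matrix.mean())
    corr = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    explained = 100.0 * eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval)[None, :],
        index=matrix.columns,
        columns=[f"PC{j + 1}" for j in range(len(eigval))],
    )
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        explained_pct=explained,
        n_retained=int((eigval > 1.0).sum()),
        imputed=imputed,
        dropped=dropped,
    )


@dataclass
class ClusterResult:
    """Average-linkage hierarchy with a k-group cut."""

    linkage: np.ndarray
    labels: pd.Series  # group number per genotype, 1..k
    profiles: pd.DataFrame | None  # normalized per-group trait means


def group_profiles(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-group trait means normalized to proportions across groups.

    For each trait, group means are divided by their sum over groups,
    so every trait column sums to 1 across groups.
    """
    means = matrix.groupby(labels).mean()
    return means.apply(lambda col: normalize_profile(col.to_numpy()), axis=0,
                       result_type="broadcast")


def ahc_cluster(
    matrix: pd.DataFrame, k: int = 5, standardize: bool = True
) -> ClusterResult:
    """Hierarchical clustering of genotypes into ``k`` groups.

    Euclidean distance on (optionally z-standardized) traits with
    average linkage; the tree is cut to exactly ``k`` clusters. Group
    numbers follow first-merge order and labels partition all
    genotypes. Missing values are trait-mean imputed.
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of genotypes ({len(matrix)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = matrix.copy()
    if x.isna().any().any():
        x = x.fillna(x.mean())
    if standardize:
        sd = x.std(ddof=0)
        sd = sd.replace(0, 1.0)
        x = (x - x.mean()) / sd
    z = hierarchy.linkage(pdist(x.to_numpy(dtype=float)), method="average")
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.index, name="group")
    profiles = group_profiles(matrix, labels) if matrix.shape[1] > 1 else None
    return ClusterResult(linkage=z, labels=labels, profiles=profiles)


def sts_grouping(sts_sum: pd.Series, k: int = 5) -> pd.Series:
    """Group genotypes by summed stress tolerance score.

    One-dimensional hierarchical clustering (Euclidean distance,
    average linkage) of STS_SUM cut at ``k``; groups are renumbered in
    descending order of mean score, so Group 1 contains the
    highest-scoring (most stress-tolerant) genotypes. All values must
    be present; if fewer than ``k`` distinct values exist the cut is
    unreachable and an error is raised.
    """
    if sts_sum.isna().any():
        missing = sts_sum[sts_sum.isna()].index.tolist()
        raise ValueError(f"missing STS_SUM for genotypes {missing[:5]}")
    if sts_sum.nunique() < k:
        raise ValueError(
            f"cannot form {k} groups from {sts_sum.nunique()} distinct scores"
        )
    res = ahc_cluster(sts_sum.to_frame(), k=k, standardize=False)
    order = (
        sts_sum.groupby(res.labels).mean().sort_values(ascending=False).index
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return res.labels.map(remap).rename("group")
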