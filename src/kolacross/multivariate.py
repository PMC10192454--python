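"""Cross grouping and characterization: PCA, Ward clustering, v-tests,
correlations.

The workflow mirrors hierarchical clustering on principal components (HCPC):
traits are standardized, crosses are projected on the principal components,
Ward agglomeration runs on the scores of the components that reach a
cumulative-variance threshold (80% by default), and each cluster is
characterized by comparing its per-trait category mean against the overall
mean with the v-test statistic

    v = (mean_c - mean) / sqrt((s^2 / n_c) * (N - n_c) / (N - 1))

where ``s^2`` is the overall (population) variance of the trait — |v| large
means the cluster is atypical for that trait; the two-sided normal p-value is
flagged at P < 0.001 in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "PCAResult",
    "ClusterReport",
    "CorrelationReport",
    "pca_standardized",
    "hcpc_cluster",
    "describe_clusters",
    "correlation_matrix",
    "feature_table",
]

log = logging.getLogger(__name__)


def feature_table(dataset) -> pd.DataFrame:
    """Crosses × traits matrix for multivariate analysis: per-cross trait
    means plus pod-set / pseudo-pod-set percentages where available."""
    from .heterosis import cross_value_table
    from .crossdata import TRAIT_FIELDS

    traits = ["pod_set", "pseudo_pod_set", *TRAIT_FIELDS]
    table = cross_value_table(dataset, traits)
    return table.dropna(axis=1, how="all")


@dataclass
class PCAResult:
    """Standardized PCA of a crosses × traits table."""

    scores: pd.DataFrame  # crosses × components
    explained_pct: np.ndarray  # per component, sums to 100
    loadings: pd.DataFrame  # traits × components
    dropped_traits: List[str] = field(default_factory=list)
    imputed_cells: int = 0


def pca_standardized(table: pd.DataFrame) -> PCAResult:
    """PCA on columns centered and scaled to unit variance.

    Equivalent to the eigendecomposition of the trait correlation matrix.
    Missing cells are mean-imputed (logged); zero-variance traits are dropped
    with a warning. The sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    df = table.astype(float).copy()
    if df.shape[0] < 3:
        raise ValueError("PCA needs at least 3 crosses")
    imputed = int(df.isna().sum().sum())
    if imputed:
        log.warning("mean-imputing %d missing cells before PCA", imputed)
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        log.warning("dropping zero-variance trait(s): %s", ", ".join(dropped))
        df = df.drop(columns=dropped)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 traits with variance")
    X = (df - df.mean()) / df.std(ddof=1)
    n, p = X.shape
    U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    n_comp = min(n - 1, p)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # deterministic sign: largest-|loading| positive per component
    for j in range(n_comp):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    explained = 100.0 * var / var.sum()
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    scores = pd.DataFrame(U * s, index=df.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=df.columns, columns=comp_names)
    return PCAResult(scores, explained, loadings, dropped, imputed)


@dataclass
class ClusterReport:
    """Ward clustering of PCA scores plus per-cluster trait characterization."""

    assignments: Dict[str, int]  # cross label → cluster id (1..k)
    k: int
    merge_heights: np.ndarray
    n_components_used: int
    within_inertia: Dict[int, float]  # candidate k → within-cluster inertia
    category_stats: Optional[pd.DataFrame] = None


def _within_inertia(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k in order of first appearance (row order)."""
    mapping: Dict[int, int] = {}
    out = np.empty_like(labels)
    for i, c in enumerate(labels):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def hcpc_cluster(
    pca: PCAResult,
    k: Union[int, str] = "auto",
    retain_pct: float = 80.0,
    k_range: Tuple[int, int] = (3, 6),
) -> ClusterReport:
    """Ward-linkage clustering on the PCA scores.

    Components are retained up to ``retain_pct`` cumulative variance.
    With ``k="auto"`` the partition size is searched over ``k_range`` and
    chosen as the k with the largest relative drop of within-cluster inertia
    from k-1 to k; ties break toward smaller k.
    """
    n = pca.scores.shape[0]
    cum = np.cumsum(pca.explained_pct)
    m = int(np.searchsorted(cum, retain_pct - 1e-9) + 1)
    m = min(max(m, 1), pca.scores.shape[1])
    X = pca.scores.to_numpy()[:, :m]
    Z = linkage(X, method="ward")

    def cut(kk: int) -> np.ndarray:
        return fcluster(Z, t=kk, criterion="maxclust")

    if k == "auto":
        kmin, kmax = k_range
        kmax = min(kmax, n)
        kmin = max(2, min(kmin, kmax))
        inertia = {
            kk: _within_inertia(X, cut(kk)) for kk in range(max(kmin - 1, 1), kmax + 1)
        }
        best_k, best_gain = None, -math.inf
        for kk in range(kmin, kmax + 1):
            prev = inertia[kk - 1] if kk - 1 in inertia else _within_inertia(X, cut(kk - 1))
            gain = (prev - inertia[kk]) / prev if prev > 0 else 0.0
            if gain > best_gain + 1e-12:  # strict: ties keep the smaller k
                best_k, best_gain = kk, gain
        k_used = int(best_k)
    else:
        k_used = int(k)
        if k_used > n:
            raise ValueError(f"k={k_used} exceeds number of crosses ({n})")
        inertia = {k_used: _within_inertia(X, cut(k_used))}

    labels = _relabel(cut(k_used))
    assignments = {lab: int(c) for lab, c in zip(pca.scores.index, labels)}
    return ClusterReport(
        assignments=assignments,
        k=k_used,
        merge_heights=Z[:, 2].copy(),
        n_components_used=m,
        within_inertia={kk: float(v) for kk, v in inertia.items()},
    )


def describe_clusters(
    assignments: Dict[str, int],
    table: pd.DataFrame,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Characterize clusters by trait: category mean vs overall mean (v-test).

    Returns one row per cluster × trait with category_mean, overall_mean,
    category_sd, v_statistic, p_value and a significance flag at ``alpha``
    (0.001 by default, the reporting threshold). The v statistic is
    undefined (NaN) for a cluster containing all crosses.
    """
    labels = pd.Series(assignments).reindex(table.index)
    if labels.isna().any():
        raise ValueError("assignments must cover every cross in the table")
    ks = sorted(set(int(v) for v in labels))
    if len(ks) < 2:
        raise ValueError("need at least 2 clusters to characterize")
    N = len(table)
    rows = []
    for trait in table.columns:
        col = table[trait].astype(float)
        overall = float(col.mean())
        s2 = float(col.var(ddof=0))
        for c in ks:
            sub = col[labels == c]
            n_c = len(sub)
            mean_c = float(sub.mean())
            sd_c = float(sub.std(ddof=0))
            if n_c == N or s2 == 0:
                v, p = float("nan"), float("nan")
            else:
                denom = math.sqrt((s2 / n_c) * (N - n_c) / (N - 1))
                v = (mean_c - overall) / denom
                p = 2.0 * stats.norm.sf(abs(v))
            rows.append(
                {
                    "cluster": c,
                    "trait": trait,
                    "n": n_c,
                    "category_mean": mean_c,
                    "overall_mean": overall,
                    "category_sd": sd_c,
                    "v_statistic": v,
                    "p_value": p,
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with significance."""

    matrix: pd.DataFrame  # traits × traits, r
    p_values: pd.DataFrame
    n_pairs: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Render significance stars: * 0.05, ** 0.01, *** 0.001."""
        def star(p):
            if pd.isna(p):
                return ""
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

        return self.p_values.map(star)


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationReport:
    """Pearson correlation among traits with t-distributed p-values.

    Uses pairwise-complete observations; cells with fewer than ``min_pairs``
    complete pairs are reported missing.
    """
    cols = list(table.columns)
    p = len(cols)
    r_mat = pd.DataFrame(np.eye(p), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((p, p)), index=cols, columns=cols)
    n_mat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        n_mat.at[a, a] = int(table[a].notna().sum())
        p_mat.at[a, a] = float("nan")
        for b in cols[i + 1 :]:
            ok = table[[a, b]].dropna()
            n = len(ok)
            n_mat.at[a, b] = n_mat.at[b, a] = n
            if n < min_pairs:
                r, pv = float("nan"), float("nan")
            elif ok[a].nunique() == 1 or ok[b].nunique() == 1:
                r, pv = float("nan"), float("nan")  # constant: r undefined
            else:
                r, pv = stats.pearsonr(ok[a], ok[b])
            r_mat.at[a, b] = r_mat.at[b, a] = float(r)
            p_mat.at[a, b] = p_mat.at[b, a] = float(pv)
    return CorrelationReport(matrix=r_mat, p_values=p_mat, n_pairs=n_mat)
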