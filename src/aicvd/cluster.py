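"""Genetic-pattern discovery: categorical P-value profiles, Gower distance,
Ward hierarchical clustering, and Fisher-combined cluster association.

Each pruned pleiotropic SNP is described by its six per-disease association
P-values discretized into four significance categories; SNPs with similar
cross-disease profiles form a genetic pattern.  Pairwise dissimilarity is the
Gower mismatch fraction over the six (unordered) categorical attributes, and
patterns are cut from a Ward dendrogram.  Each pattern's association with CVD
per disease combines its member SNPs' P-values with Fisher's method and is
Bonferroni-corrected over pattern x disease tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2
from sklearn.metrics import silhouette_score

from .io_formats import DISEASES

logger = logging.getLogger(__name__)

#: Category boundaries: [0.05,1] -> 1, [0.02,0.05) -> 2, [0.005,0.02) -> 3,
#: (0,0.005) -> 4.  A boundary P-value falls in the less-significant category.
CATEGORY_EDGES = (0.05, 0.02, 0.005)


def discretize(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Map per-disease P-values to the four significance categories."""
    vals = p_matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1):
        raise ValueError("P-values must lie in (0, 1]")
    cats = np.select(
        [vals >= 0.05, vals >= 0.02, vals >= 0.005],
        [1, 2, 3],
        default=4,
    )
    return pd.DataFrame(cats, index=p_matrix.index, columns=p_matrix.columns)


def gower_distance(categories: pd.DataFrame) -> np.ndarray:
    """Pairwise Gower dissimilarity: fraction of mismatching categories.

    Categories are unordered symbols; d(i,j) = (1/m) * #{attributes where
    the two rows differ}, hence values on the grid {0, 1/m, ..., 1}.
    """
    x = categories.to_numpy()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 SNPs")
    n, m = x.shape
    dist = np.zeros((n, n))
    for col in range(m):
        c = x[:, col]
        dist += (c[:, None] != c[None, :]).astype(float)
    dist /= m
    return dist


def gower_distance_ordered(categories: pd.DataFrame) -> np.ndarray:
    """Sensitivity variant: categories as ordered levels (range-scaled Manhattan)."""
    x = categories.to_numpy(dtype=float)
    n, m = x.shape
    dist = np.zeros((n, n))
    for col in range(m):
        c = x[:, col]
        rng = np.ptp(c)
        if rng == 0:
            continue
        dist += np.abs(c[:, None] - c[None, :]) / rng
    return dist / m


@dataclass
class ClusterModel:
    rsids: list[str]
    categories: pd.DataFrame
    distance: np.ndarray
    linkage_matrix: np.ndarray
    k: int
    assignments: pd.Series
    cluster_assoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def ward_cluster(
    distance: np.ndarray,
    rsids: list[str],
    categories: pd.DataFrame,
    k: int | str = "auto",
    method: str = "ward.D",
    k_max: int = 15,
) -> ClusterModel:
    """Agglomerative Ward clustering of the SNP dissimilarity matrix.

    ``ward.D`` applies the Lance-Williams recurrence directly to the supplied
    dissimilarities (the classic R convention); ``ward.D2`` treats them as
    Euclidean distances.  The ward.D tree is computed via the identity
    ward.D(d) = ward.D2(sqrt(d)) with merge heights squared — the merge
    sequence is identical because the transform is monotone.

    ``k='auto'`` cuts the dendrogram at the largest merge-height gap over
    k in [2, k_max]: on the coarse Gower grid, mean silhouette
    (``k='silhouette'``) systematically over-splits because duplicate
    category profiles form zero-distance shards with silhouette near 1,
    whereas the height gap tracks where merging starts to join genuinely
    different profiles.
    """
    n = distance.shape[0]
    if n < 3:
        raise ValueError("need at least 3 SNPs to cluster")
    if distance.shape != (n, n) or not np.allclose(distance, distance.T):
        raise ValueError("distance matrix must be square symmetric")
    if np.abs(np.diag(distance)).max() > 1e-12:
        raise ValueError("distance matrix must have zero diagonal")
    cond = squareform(distance, checks=False)
    if method == "ward.D":
        Z = linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    elif method == "ward.D2":
        Z = linkage(cond, method="ward")
    else:
        raise ValueError(f"unknown linkage method {method!r}")

    if k == "auto":
        # cut at the largest jump in merge height: the last (k-1) merges sit
        # above the cut, so the gap between merge heights n-k and n-k+1
        # measures how much worse forcing k-1 clusters would be
        heights = Z[:, 2]
        best_k, best_gap = 2, -np.inf
        for kk in range(2, min(k_max, n - 1) + 1):
            gap = heights[n - kk] - heights[n - kk - 1] if n - kk - 1 >= 0 else heights[n - kk]
            if gap > best_gap + 1e-12:
                best_k, best_gap = kk, gap
        k = best_k
        logger.info("auto k: %d clusters (height gap %.4f)", k, best_gap)
    elif k == "silhouette":
        # mean-silhouette selection, skipping cuts with singleton clusters
        # (silhouette is degenerate there); falls back to the unconstrained
        # best if every cut has singletons
        best_k, best_score = None, -np.inf
        fallback_k, fallback_score = None, -np.inf
        for kk in range(2, min(k_max, n - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(distance, labels, metric="precomputed")
            if score > fallback_score + 1e-12:
                fallback_k, fallback_score = kk, score
            if np.bincount(labels)[1:].min() < 2:
                continue
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        if best_k is None:
            best_k, best_score = fallback_k, fallback_score
        if best_k is None:
            raise ValueError("no valid cluster cut found")
        k = best_k
        logger.info("auto k: %d clusters (mean silhouette %.3f)", k, best_score)
    else:
        k = int(k)
        if not 2 <= k <= n - 1:
            raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_labels(raw)
    return ClusterModel(
        rsids=list(rsids),
        categories=categories,
        distance=distance,
        linkage_matrix=Z,
        k=int(len(np.unique(labels))),
        assignments=pd.Series(labels, index=rsids, name="cluster"),
    )


def fisher_combine(
    assignments: pd.Series,
    p_matrix: pd.DataFrame,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Fisher's method per cluster x disease, Bonferroni-corrected.

    X = -2 * sum(ln p) over the cluster's SNPs, referred to chi-square with
    2*|cluster| df.  ``n_tests`` defaults to (number of clusters) x
    (number of diseases).
    """
    clusters = sorted(assignments.unique())
    diseases = [d for d in DISEASES if d in p_matrix.columns]
    if n_tests is None:
        n_tests = len(clusters) * len(diseases)
    rows = []
    for c in clusters:
        members = assignments.index[assignments == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        sub = p_matrix.loc[members, diseases]
        if sub.isna().any().any():
            raise ValueError(f"cluster {c}: missing P-values")
        for d in diseases:
            x = float(-2.0 * np.log(sub[d]).sum())
            df = 2 * len(members)
            p = float(max(chi2.sf(x, df), np.finfo(float).tiny))
            rows.append({
                "cluster": c, "disease": d, "n_snps": len(members),
                "fisher_X": x, "df": df, "p": p,
                "p_bonferroni": min(1.0, p * n_tests),
            })
    return pd.DataFrame(rows)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string (heights as branch lengths)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        sub_a, sub_b = node(a), node(b)
        la = max(0.0, h - heights[a])
        lb = max(0.0, h - heights[b])
        heights[i] = h
        return f"({sub_a}:{la:.6g},{sub_b}:{lb:.6g})"

    root = n + len(Z) - 1
    return node(root) + ";"
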