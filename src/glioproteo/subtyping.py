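"""Proteome subtype discovery.

Samples are clustered hierarchically (complete linkage) on
1 - Pearson-correlation distances.  Consensus clustering repeats the
clustering over random sample subsets; the fraction of runs in which
two samples co-cluster (given both were drawn) forms the consensus
matrix.  The proportion of ambiguous clustering (PAC) — the share of
consensus values falling strictly between 0.1 and 0.9 — measures how
indecisive a K-cluster solution is, and the K minimizing PAC is taken
as the number of subtypes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from glioproteo.containers import ConsensusResult, IntensityMatrix, PCAResult


def _as_frame(m) -> pd.DataFrame:
    return m.values if isinstance(m, IntensityMatrix) else pd.DataFrame(m)


def correlation_distance(m) -> pd.DataFrame:
    """Sample x sample distances d = 1 - Pearson r over shared observed features."""
    values = _as_frame(m)
    var = values.var(axis=0, skipna=True)
    if (var.fillna(0) <= 0).any():
        bad = var.index[var.fillna(0) <= 0][0]
        raise ValueError(f"sample {bad!r} has zero variance")
    corr = values.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        raise ValueError("a sample pair shares fewer than two observed features")
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return dist


def hcluster(
    dist: pd.DataFrame, k: int | None = None, method: str = "complete",
    height: float | None = None,
):
    """Agglomerative clustering of a precomputed distance matrix.

    Returns ``(labels, Z)``: integer labels (1..k) aligned with the
    distance-matrix index, and the scipy linkage matrix.
    """
    n = dist.shape[0]
    condensed = squareform(np.asarray(dist, dtype=float), checks=False)
    Z = linkage(condensed, method=method)
    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} samples")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        raise ValueError("either k or height is required")
    return pd.Series(labels, index=dist.index, name="cluster"), Z


def pac_score(consensus: pd.DataFrame | np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering of a consensus matrix.

    Fraction of defined off-diagonal entries strictly inside (u1, u2).
    """
    if u1 >= u2:
        raise ValueError(f"require u1 < u2, got ({u1}, {u2})")
    c = np.asarray(consensus, dtype=float)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal consensus entries")
    return float(np.mean((vals > u1) & (vals < u2)))


def consensus_cluster(
    m,
    k_range=range(2, 7),
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    method: str = "complete",
) -> ConsensusResult:
    """Subsampled consensus clustering with PAC-based selection of K.

    Each iteration draws ``subsample_frac`` of the samples without
    replacement, clusters them (complete linkage on correlation
    distance) and cuts the tree at every K in ``k_range``.  Consensus
    for a sample pair is co-clustering count over co-sampling count;
    pairs never co-sampled stay NaN and are excluded from PAC.  Final
    labels cut a complete-linkage tree of 1 - consensus at the optimal
    K (PAC ties break toward the smaller K).
    """
    values = _as_frame(m)
    samples = values.columns
    n = len(samples)
    k_values = sorted(k_range)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not k_values or k_values[0] < 2 or k_values[-1] > n - 1:
        raise ValueError(f"K range must lie within [2, {n - 1}]")
    n_sub = max(k_values[-1] + 1, int(round(subsample_frac * n)))
    rng = np.random.default_rng(seed)
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_values}
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = values.iloc[:, idx]
        dist = correlation_distance(sub)
        condensed = squareform(dist.to_numpy(), checks=False)
        Z = linkage(condensed, method=method)
        co_sampled[np.ix_(idx, idx)] += 1
        for k in k_values:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = {
            k: pd.DataFrame(
                np.where(co_sampled > 0, co_clustered[k] / co_sampled, np.nan),
                index=samples, columns=samples,
            )
            for k in k_values
        }
    pac = {k: pac_score(consensus[k]) for k in k_values}
    optimal_k = min(k_values, key=lambda k: (pac[k], k))
    cdist = 1.0 - consensus[optimal_k].fillna(0.0)
    np.fill_diagonal(cdist.values, 0.0)
    labels, _ = hcluster(cdist, k=optimal_k, method=method)
    return ConsensusResult(
        k_values=k_values, consensus=consensus, pac=pac,
        optimal_k=optimal_k, labels=labels,
    )


def pca(m, n_components: int | None = None) -> PCAResult:
    """PCA of samples over features (samples as observations, centered)."""
    values = _as_frame(m)
    X = values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix; impute first")
    n_components = n_components or min(X.shape)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCAResult(
        loadings=pd.DataFrame(model.components_.T, index=values.index, columns=comp_names),
        scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def pc1_top_loadings(pca_result: PCAResult, frac: float = 0.10) -> list[str]:
    """Features in the top ``frac`` of absolute PC1 loadings.

    Selects floor(frac * n_features) features by descending |loading|,
    breaking ties by feature id order.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    pc1 = pca_result.loadings["PC1"].abs()
    n_select = math.floor(frac * len(pc1))
    order = sorted(pc1.index, key=lambda f: (-pc1[f], f))
    return order[:n_select]


def label_association_test(
    clusters, phenotypes, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Permutation test of cluster / phenotype label association.

    The statistic is within-phenotype pair purity: among sample pairs
    sharing a phenotype, the fraction that also share a cluster.  The
    null permutes phenotype labels; p = (1 + #{perm >= obs}) /
    (n_perm + 1).  Returns ``(statistic, p_value)``.
    """
    cl = np.asarray(clusters)
    ph = np.asarray(phenotypes)
    if cl.shape != ph.shape:
        raise ValueError("clusters and phenotypes must have equal length")
    if len(np.unique(ph)) < 2:
        raise ValueError("phenotype must have at least two classes")

    iu = np.triu_indices(len(cl), k=1)
    same_cl = (cl[:, None] == cl[None, :])[iu]

    def purity(p: np.ndarray) -> float:
        same_ph = (p[:, None] == p[None, :])[iu]
        if not same_ph.any():
            return 0.0
        return float(same_cl[same_ph].mean())

    obs = purity(ph)
    rng = np.random.default_rng(seed)
    hits = sum(purity(rng.permutation(ph)) >= obs for _ in range(n_perm))
    return obs, (1 + hits) / (n_perm + 1)
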