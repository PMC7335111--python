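"""Surrogate proteome-subtype (sGPC) classification of RNA data.

Bulk tumors and single cells lacking proteome measurements inherit a
GPC1/GPC2 call through an equal-sized two-sided gene signature.  For a
cell with per-gene z-scores Z the statistic is

    delta_Z = mean(Z over GPC1-high genes) - mean(Z over GPC2-high genes)

whose null distribution is obtained by permuting which signature genes
belong to which side (1000 gene-label permutations); a cell is called
GPC1 (delta_Z > 0) or GPC2 (delta_Z < 0) only when the two-sided
permutation p-value falls below 0.05, and stays unassigned otherwise.
Bulk cohorts are instead classified by a random-forest model trained on
the top differential genes after quantile-normalized cohort merging,
with calls emitted only at >= 60% class probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV

from glioproteo.containers import SignatureSet


def zscore_genes(matrix: pd.DataFrame, axis: str = "gene") -> pd.DataFrame:
    """Z-score a cells/samples x genes matrix.

    ``axis="gene"`` (default) standardizes each gene across the
    cells/samples; ``axis="cell"`` standardizes each row across genes.
    """
    if axis == "gene":
        mu = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        return (matrix - mu) / sd.replace(0, np.nan)
    if axis == "cell":
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=1)
        return matrix.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    raise ValueError(f"axis must be 'gene' or 'cell', got {axis!r}")


def single_cell_gene_filter(
    bulk_expr: pd.DataFrame, cell_matrix: pd.DataFrame,
    top_n: int = 1000, min_cell_fraction: float = 0.5,
) -> list[str]:
    """Candidate genes for a single-cell signature.

    Keeps the ``top_n`` genes with the highest mean expression in the
    bulk training cohort that are also expressed (value > 0) in at
    least ``min_cell_fraction`` of the single cells.
    """
    shared = bulk_expr.index.intersection(cell_matrix.columns)
    mean_expr = bulk_expr.loc[shared].mean(axis=1)
    top = mean_expr.sort_values(ascending=False, kind="stable").index[:top_n]
    frac = (cell_matrix[top] > 0).mean(axis=0)
    return sorted(frac.index[frac >= min_cell_fraction])


def build_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    mode: str = "top_n",
    n: int = 100,
    fdr: float = 0.10,
    candidate_genes: list[str] | None = None,
) -> SignatureSet:
    """Select an equal-sized two-sided differential signature.

    ``expr`` is gene x sample, ``labels`` a two-level series over the
    samples (the lexicographically first level is treated as GPC1).
    ``mode="top_n"`` takes the ``n`` smallest-p genes on each side;
    ``mode="fdr"`` takes an equal number from each side among genes
    with BH q below ``fdr``.  ``candidate_genes`` restricts the pool
    (e.g. the single-cell expression prefilter).
    """
    from glioproteo.diffexp import dep_test

    if candidate_genes is not None:
        expr = expr.loc[expr.index.intersection(candidate_genes)]
    table = dep_test(expr, labels)
    up = table[table["direction"] > 0].sort_values(["p", "t"], kind="stable")
    down = table[table["direction"] < 0].sort_values(["p", "t"], kind="stable")
    if mode == "top_n":
        if len(up) < n or len(down) < n:
            raise ValueError(
                f"need {n} genes per side, have {len(up)} up / {len(down)} down"
            )
        gpc1, gpc2 = list(up.index[:n]), list(down.index[:n])
    elif mode == "fdr":
        up = up[up["q"] < fdr]
        down = down[down["q"] < fdr]
        m = min(len(up), len(down))
        if m == 0:
            raise ValueError(
                f"no genes pass FDR < {fdr} on both sides "
                f"({len(up)} up / {len(down)} down)"
            )
        gpc1, gpc2 = list(up.index[:m]), list(down.index[:m])
    else:
        raise ValueError(f"mode must be 'top_n' or 'fdr', got {mode!r}")
    return SignatureSet(
        gpc1_high=gpc1, gpc2_high=gpc2,
        meta={"mode": mode, "n": n, "fdr": fdr},
    )


def _signature_z(zvec: pd.Series, sig: SignatureSet) -> np.ndarray:
    missing = [g for g in sig.genes if g not in zvec.index]
    if missing:
        raise ValueError(f"signature genes missing from z-vector: {missing}")
    return zvec.loc[sig.genes].to_numpy(dtype=float)


def delta_z(zvec: pd.Series, sig: SignatureSet) -> float:
    """mean z over GPC1-high genes minus mean z over GPC2-high genes."""
    z = _signature_z(zvec, sig)
    m = len(sig.gpc1_high)
    return float(z[:m].mean() - z[m:].mean())


def _permutation_deltas(
    n_genes: int, n_side: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm x n_genes matrix of +-1/n_side side assignments."""
    P = np.empty((n_perm, n_genes))
    base = np.concatenate(
        [np.full(n_side, 1.0 / n_side), np.full(n_genes - n_side, -1.0 / n_side)]
    )
    for i in range(n_perm):
        P[i] = rng.permutation(base)
    return P


def permutation_pvalue(
    zvec: pd.Series, sig: SignatureSet, n_perm: int = 1000, seed: int = 0
) -> float:
    """Two-sided gene-label permutation p-value for the delta-Z score.

    Side memberships are permuted over the signature union with sizes
    preserved; p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = _signature_z(zvec, sig)
    m = len(sig.gpc1_high)
    obs = z[:m].mean() - z[m:].mean()
    rng = np.random.default_rng(seed)
    P = _permutation_deltas(len(z), m, n_perm, rng)
    perm = P @ z
    return float((1 + np.sum(np.abs(perm) >= abs(obs))) / (n_perm + 1))


def classify_cells(
    zmat: pd.DataFrame,
    sig: SignatureSet,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Delta-Z permutation classification of every cell (rows) at once.

    Each cell receives its own ``n_perm`` independent gene-label
    permutations (a random size-preserving reassignment of the
    signature sides), so cells are mutually independent under the null;
    the work is vectorized in chunks of cells.  Returns per-cell
    ``delta_z``, ``p_perm`` and ``call`` in {GPC1, GPC2, unassigned}.
    """
    missing = [g for g in sig.genes if g not in zmat.columns]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Z = zmat[sig.genes].to_numpy(dtype=float)
    m = len(sig.gpc1_high)
    n_genes = Z.shape[1]
    obs = Z[:, :m].mean(axis=1) - Z[:, m:].mean(axis=1)
    rng = np.random.default_rng(seed)
    chunk = max(1, int(2e7) // (n_perm * n_genes))
    exceed = np.empty(Z.shape[0], dtype=int)
    for lo in range(0, Z.shape[0], chunk):
        hi = min(lo + chunk, Z.shape[0])
        k = hi - lo
        # argpartition of iid uniforms -> a uniform random m-subset per
        # (cell, permutation); delta = (2 * sum_subset - sum_all) / m
        draws = rng.random((k, n_perm, n_genes), dtype=np.float32)
        subset = np.argpartition(draws, m - 1, axis=2)[:, :, :m]
        del draws
        gathered = np.take_along_axis(Z[lo:hi, None, :], subset, axis=2)
        perm = (2 * gathered.sum(axis=2) - Z[lo:hi].sum(axis=1)[:, None]) / m
        exceed[lo:hi] = np.sum(np.abs(perm) >= np.abs(obs[lo:hi])[:, None], axis=1)
    p = (1 + exceed) / (n_perm + 1)
    call = np.where(
        p < alpha, np.where(obs > 0, "GPC1", "GPC2"), "unassigned"
    )
    call[(p < alpha) & (obs == 0)] = "unassigned"
    return pd.DataFrame(
        {"delta_z": obs, "p_perm": p, "call": call}, index=zmat.index
    )


def quantile_merge(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two gene x sample cohorts and quantile-normalize the union.

    Shared genes are intersected, the columns concatenated, and every
    sample mapped onto the mean-of-order-statistics reference so all
    sorted sample vectors coincide (ties keep input order).
    """
    genes = cohort_a.index.intersection(cohort_b.index)
    if genes.empty:
        raise ValueError("cohorts share no genes")
    merged = pd.concat([cohort_a.loc[genes], cohort_b.loc[genes]], axis=1)
    if merged.columns.has_duplicates:
        raise ValueError("sample ids overlap between cohorts")
    X = merged.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=merged.index, columns=merged.columns)


def surrogate_bulk_classify(
    train: pd.DataFrame,
    train_labels: pd.Series,
    test: pd.DataFrame,
    prob_threshold: float = 0.60,
    top_n_genes: int = 100,
    seed: int = 0,
    cv: int = 5,
) -> pd.DataFrame:
    """Probability-thresholded surrogate subtyping of a bulk RNA cohort.

    The top ``top_n_genes`` differential genes (by t-test p-value) are
    selected on the training cohort, both cohorts are merged and
    quantile-normalized, and a random forest tuned by ``cv``-fold
    cross-validated grid search is trained on the training block.  Test
    samples receive a call only when the winning class probability
    reaches ``prob_threshold``; otherwise ``unassigned``.
    """
    from glioproteo.diffexp import dep_test

    train_labels = pd.Series(train_labels).loc[train.columns]
    classes = sorted(train_labels.unique())
    if len(classes) < 2:
        raise ValueError("training cohort must contain both classes")
    table = dep_test(train, train_labels)
    top = table.sort_values(["p", "t"], kind="stable").index[:top_n_genes]
    merged = quantile_merge(train.loc[top], test.loc[test.index.intersection(top)])
    Xtr = merged[train.columns].to_numpy().T
    Xte = merged[test.columns].to_numpy().T
    grid = GridSearchCV(
        RandomForestClassifier(n_estimators=300, random_state=seed),
        param_grid={"max_features": ["sqrt", 0.3, 0.5]},
        cv=cv,
        scoring="accuracy",
    )
    grid.fit(Xtr, train_labels.to_numpy())
    model = grid.best_estimator_
    proba = model.predict_proba(Xte)
    cols = list(model.classes_)
    best = proba.max(axis=1)
    call = np.where(
        best >= prob_threshold,
        np.asarray(cols)[proba.argmax(axis=1)],
        "unassigned",
    )
    out = pd.DataFrame(proba, index=test.columns, columns=[f"prob_{c}" for c in cols])
    out["call"] = call
    return out
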