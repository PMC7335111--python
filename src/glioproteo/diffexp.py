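"""Differential expression between sample groups.

Two-sided unpaired Student's t-tests (equal variance by default, Welch
behind a flag) with Benjamini-Hochberg FDR.  Differential phosphoprotein
hits whose parent protein changes in the same direction are filtered
out, so that surviving phospho signals reflect phosphorylation changes
rather than protein-abundance changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glioproteo.containers import IntensityMatrix


def _split_groups(values: pd.DataFrame, groups: pd.Series):
    groups = pd.Series(groups)
    groups = groups.loc[values.columns.intersection(groups.index)]
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = values[groups.index[groups == levels[0]]]
    b = values[groups.index[groups == levels[1]]]
    return a, b, levels


def normality_screen(m, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk screen per feature and group (advisory only).

    Features with fewer than three observed values in a group, or zero
    variance, are skipped and flagged.  The attached
    ``.attrs["reject_fraction"]`` reports the per-group fraction of
    testable features rejecting normality at ``alpha``.
    """
    values = m.values if isinstance(m, IntensityMatrix) else pd.DataFrame(m)
    a, b, levels = _split_groups(values, groups)
    rows = {}
    for level, block in zip(levels, (a, b)):
        ps = []
        for _, row in block.iterrows():
            obs = row.dropna().to_numpy()
            if obs.size < 3 or np.ptp(obs) == 0:
                ps.append(np.nan)
            else:
                ps.append(stats.shapiro(obs).pvalue)
        rows[level] = ps
    out = pd.DataFrame(rows, index=values.index)
    out.attrs["reject_fraction"] = {
        level: float((out[level].dropna() < alpha).mean()) for level in levels
    }
    return out


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def dep_test(
    m,
    groups: pd.Series,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature two-sided unpaired t-test between two groups.

    Returns a table with group means, t statistic, p, BH q, direction
    (sign of mean(first) - mean(second)) and the ``dep`` flag p < alpha.
    Features constant in both groups with equal means get p = 1.
    """
    values = m.values if isinstance(m, IntensityMatrix) else pd.DataFrame(m)
    a, b, levels = _split_groups(values, groups)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    res = stats.ttest_ind(
        a, b, axis=1, equal_var=equal_var, nan_policy="omit"
    )
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    mean_a = a.mean(axis=1, skipna=True).to_numpy()
    mean_b = b.mean(axis=1, skipna=True).to_numpy()
    degenerate = np.isnan(t) & np.isclose(mean_a, mean_b)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    table = pd.DataFrame(
        {
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.sign(mean_a - mean_b),
        },
        index=values.index,
    )
    table["dep"] = table["p"] < alpha
    table.attrs["groups"] = levels
    return table


def depp_filter(
    depp: pd.DataFrame, dep: pd.DataFrame, parent_map: pd.Series | dict
) -> pd.DataFrame:
    """Drop phospho hits explained by a same-direction parent-protein change.

    A phospho feature is removed when its parent protein is a DEP
    (p < alpha flag from :func:`dep_test`) changing in the same
    direction.  Phospho features without a mapped parent are kept and
    flagged in the ``unmapped_parent`` column.
    """
    parent_map = pd.Series(parent_map)
    out = depp.copy()
    out["unmapped_parent"] = True
    keep = pd.Series(True, index=out.index)
    for feat in out.index:
        parent = parent_map.get(feat)
        if parent is None or (isinstance(parent, float) and np.isnan(parent)) \
                or parent not in dep.index:
            continue
        out.loc[feat, "unmapped_parent"] = False
        if bool(dep.loc[parent, "dep"]) and \
                dep.loc[parent, "direction"] == out.loc[feat, "direction"]:
            keep[feat] = False
    return out.loc[keep]


def rna_protein_correlation(
    rna, protein, gene_map: pd.Series | dict | None = None, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-gene Spearman correlation between mRNA and protein abundance.

    ``gene_map`` translates protein feature ids to the RNA matrix's gene
    ids (identity when omitted).  Genes with fewer than three shared
    observed samples are skipped.  ``.attrs["positive_significant_fraction"]``
    reports the share of tested genes with rho > 0 at BH FDR < ``fdr``.
    """
    rna_v = rna.values if isinstance(rna, IntensityMatrix) else pd.DataFrame(rna)
    prot_v = protein.values if isinstance(protein, IntensityMatrix) else pd.DataFrame(protein)
    shared_samples = rna_v.columns.intersection(prot_v.columns)
    rows = []
    for feat in prot_v.index:
        gene = pd.Series(gene_map).get(feat, None) if gene_map is not None else feat
        if gene is None or gene not in rna_v.index:
            continue
        x = rna_v.loc[gene, shared_samples].astype(float)
        y = prot_v.loc[feat, shared_samples].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"gene": gene, "feature": feat, "rho": rho, "p": p, "n": int(ok.sum())})
    if not rows:
        raise ValueError("no gene had three or more shared observed samples")
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_fdr(table["p"])
    table.attrs["positive_significant_fraction"] = float(
        ((table["rho"] > 0) & (table["q"] < fdr)).mean()
    )
    return table
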