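"""Gene-set enrichment: hypergeometric over-representation, overlap-
coefficient similarity edges, and single-sample GSEA (ssGSEA).

Over-representation of a query gene list in curated sets uses the
upper-tail hypergeometric test over a stated background, keeping only
sets with at least four query hits, with BH FDR across tested sets.
ssGSEA walks each sample's expression ranking and accumulates a
rank-weighted running sum (exponent 0.75 on the descending rank weight)
for in-set genes against a uniform decrement for out-of-set genes; the
enrichment score is the sum of the running difference over the walk,
which depends on the expression values only through their ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from glioproteo.diffexp import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with the standard size/redundancy filters."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            name: sorted({g.upper() for g in genes})
            for name, genes in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def filtered(self, min_size: int = 5, max_size: int = 150) -> "GeneSetCollection":
        """Drop too-small/too-large sets and exact-duplicate memberships."""
        seen: set[tuple[str, ...]] = set()
        kept: dict[str, list[str]] = {}
        for name in sorted(self.sets):
            genes = self.sets[name]
            if not min_size <= len(genes) <= max_size:
                continue
            key = tuple(genes)
            if key in seen:
                continue
            seen.add(key)
            kept[name] = genes
        return GeneSetCollection(kept, self.descriptions)


def hypergeom_ora(
    query,
    sets: GeneSetCollection,
    background,
    min_hits: int = 4,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation analysis.

    P(X >= k) for k query genes hitting a set of size K (both restricted
    to the background of size M) with a query of size n; sets with fewer
    than ``min_hits`` hits are excluded before testing and BH FDR is
    computed over the tested sets only.
    """
    background = {g.upper() for g in background}
    query = {g.upper() for g in query}
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    M, n = len(background), len(query)
    rows = []
    for name, genes in sets.items():
        in_bg = set(genes) & background
        k = len(in_bg & query)
        if k < min_hits:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, len(in_bg), n))
        rows.append(
            {"set": name, "k": k, "set_size": len(in_bg),
             "query_size": n, "background_size": M, "p": p}
        )
    table = pd.DataFrame(
        rows, columns=["set", "k", "set_size", "query_size", "background_size", "p"]
    ).set_index("set")
    table["q"] = bh_fdr(table["p"]) if len(table) else np.nan
    return table


def overlap_coefficient(set_a, set_b) -> float:
    """|A n B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def similarity_edges(sets: GeneSetCollection, cutoff: float = 0.5) -> pd.DataFrame:
    """Edges between gene sets with overlap coefficient >= cutoff."""
    names = sorted(dict(sets.items()))
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            oc = overlap_coefficient(sets[na], sets[nb])
            if oc >= cutoff:
                rows.append({"set_a": na, "set_b": nb, "overlap_coefficient": oc})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "overlap_coefficient"])


def _ssgsea_sample(ranks: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    # walk genes from highest to lowest rank; ranks are 1..N (1 = lowest)
    order = np.argsort(-ranks, kind="stable")
    r = ranks[order]
    s = in_set[order]
    w = np.where(s, r**exponent, 0.0)
    denom_in = w.sum()
    n_out = (~s).sum()
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~s) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection | dict,
    exponent: float = 0.75,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA enrichment scores, sets x samples.

    ``expr`` is gene x sample (any monotone transform of expression
    yields identical scores).  ``normalize=True`` divides all scores by
    the global score range, mapping them to a comparable scale.
    """
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    gene_index = pd.Index([g.upper() for g in expr.index])
    if gene_index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    ranks = np.apply_along_axis(stats.rankdata, 0, expr.to_numpy(dtype=float))
    out = {}
    for name, genes in items:
        in_set = gene_index.isin({g.upper() for g in genes})
        if not in_set.any():
            raise ValueError(f"gene set {name!r} shares no genes with the matrix")
        if in_set.all():
            raise ValueError(f"gene set {name!r} covers every measured gene")
        out[name] = [
            _ssgsea_sample(ranks[:, j], in_set, exponent)
            for j in range(expr.shape[1])
        ]
    es = pd.DataFrame(out, index=expr.columns).T
    if normalize:
        rng = float(es.to_numpy().max() - es.to_numpy().min())
        if rng > 0:
            es = es / rng
    return es


def assign_rna_subtype(
    es: pd.DataFrame, order: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample subtype call = signature with the highest ssGSEA score.

    ``order`` fixes the signature precedence for exact ties (defaults to
    the row order of ``es``); tied samples are flagged.
    """
    order = list(order) if order is not None else list(es.index)
    missing = [s for s in order if s not in es.index]
    if missing:
        raise ValueError(f"missing signature scores: {missing}")
    sub = es.loc[order]
    calls, ties = [], []
    for sample in sub.columns:
        col = sub[sample]
        best = col.max()
        winners = [s for s in order if col[s] == best]
        calls.append(winners[0])
        ties.append(len(winners) > 1)
    return pd.DataFrame({"subtype": calls, "tie": ties}, index=sub.columns)
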