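"""Drug-screen processing: viability smoothing, trapezoidal AUC,
four-parameter log-logistic ED50, subtype selectivity and biomarker
correlation.

Normalized viabilities per drug and concentration are smoothed by
removing abnormally high points (> 1.5 AND > Q3 + 3 x IQR of the
stratum across cells) on the assumption that targeted agents do not
boost proliferation.  The dose-response model is the four-parameter
log-logistic

    f(x) = c + (d - c) / (1 + exp(b * (log x - log e)))

with lower/upper asymptotes c, d, slope b and inflection e (the ED50);
fitted ED50s above the highest tested dose are assigned that dose.
AUC is the trapezoid rule of viability over log10 dose, normalized by
the log10 dose range so a flat fully-viable curve scores 1 (lower AUC
means higher sensitivity).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from glioproteo.containers import DoseResponseFit
from glioproteo.diffexp import bh_fdr

REQUIRED_COLUMNS = ["drug", "cell", "conc_um", "viability"]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table lacks columns {missing}")
    if (df["conc_um"] <= 0).any():
        raise ValueError("concentrations must be positive")
    if (df["viability"] < 0).any():
        raise ValueError("viabilities must be non-negative")
    return df


def smooth_viability(df: pd.DataFrame) -> pd.DataFrame:
    """Flag abnormally high viability points and drop empty drug-cell pairs.

    Within each (drug, concentration) stratum across cells, a point is
    removed when its viability exceeds both 1.5 and Q3 + 3 x IQR
    (linear-interpolation quantiles).  Strata with fewer than four
    points skip the IQR rule (the point is kept and flagged
    ``small_stratum``).  Drug-cell pairs left with no retained point at
    any concentration are dropped entirely.
    """
    df = _validate(df).copy().reset_index(drop=True)
    df["retained"] = True
    df["small_stratum"] = False
    for (_, _), idx in df.groupby(["drug", "conc_um"], sort=False).groups.items():
        v = df.loc[idx, "viability"]
        if len(v) < 4:
            df.loc[idx, "small_stratum"] = True
            continue
        q3 = np.quantile(v, 0.75)
        iqr = q3 - np.quantile(v, 0.25)
        remove = (v > 1.5) & (v > q3 + 3 * iqr)
        df.loc[idx[remove.to_numpy()], "retained"] = False
    alive = df[df["retained"]].groupby(["drug", "cell"]).size()
    keep_pairs = set(alive.index)
    pair = list(zip(df["drug"], df["cell"]))
    df = df[[p in keep_pairs for p in pair]].reset_index(drop=True)
    return df


def auc_trapezoid(conc: np.ndarray, viability: np.ndarray) -> float:
    """Normalized trapezoidal AUC over log10 concentration.

    Trapezoid rule of viability against log10 dose, divided by the
    log10 dose range; a flat viability-1 curve scores exactly 1.
    Returns NaN with fewer than two points.
    """
    conc = np.asarray(conc, dtype=float)
    v = np.asarray(viability, dtype=float)
    if conc.size < 2:
        return np.nan
    order = np.argsort(conc)
    x = np.log10(conc[order])
    return float(np.trapezoid(v[order], x) / (x[-1] - x[0]))


def four_pl(x, b, c, d, e):
    """Four-parameter log-logistic viability curve."""
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def fit_4pl(
    conc: np.ndarray,
    viability: np.ndarray,
    max_dose: float = 20.0,
    drug: str = "",
    cell: str = "",
) -> DoseResponseFit:
    """Multi-start least-squares 4PL fit with the ED50 cap rule.

    The inflection is initialized at several dose quantiles to avoid
    local minima; bounds keep 0 <= c and d <= 1.5.  ``ed50_assigned``
    is min(e, max_dose); a failed fit is assigned ``max_dose`` with
    status ``"failed"``.
    """
    conc = np.asarray(conc, dtype=float)
    v = np.asarray(viability, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, v = conc[order], v[order]
    best = None
    lo, hi = conc.min(), conc.max()
    e_starts = np.exp(
        np.quantile(np.log(conc), [0.15, 0.5, 0.85])
    )
    bounds = (
        [-100.0, 0.0, 0.0, lo * 1e-6],
        [100.0, 1.5, 1.5, hi * 1e6],
    )
    for e0 in e_starts:
        for b0 in (0.5, 2.0):
            p0 = [b0, max(float(v.min()), 0.0), min(float(v.max()), 1.5), e0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        four_pl, conc, v, p0=p0, bounds=bounds, maxfev=5000
                    )
                sse = float(np.sum((four_pl(conc, *popt) - v) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt)
            except (RuntimeError, ValueError):
                continue
    if best is None:
        return DoseResponseFit(
            drug=drug, cell=cell, auc=auc_trapezoid(conc, v),
            b=np.nan, c=np.nan, d=np.nan, e=np.nan,
            ed50_assigned=max_dose, status="failed",
        )
    b, c, d, e = best[1]
    capped = e > max_dose
    return DoseResponseFit(
        drug=drug, cell=cell, auc=auc_trapezoid(conc, v),
        b=float(b), c=float(c), d=float(d), e=float(e),
        ed50_assigned=float(min(e, max_dose)),
        status="capped" if capped else "ok",
    )


def summarize_screen(
    df: pd.DataFrame, max_dose: float | None = None, smooth: bool = True
) -> pd.DataFrame:
    """Per drug-cell AUC/ED50 summary of a long-format screen table.

    Applies :func:`smooth_viability` (unless already smoothed), then
    fits every retained curve.  ``max_dose`` defaults to the highest
    tested concentration in the table.
    """
    df = _validate(df)
    if smooth:
        df = smooth_viability(df)
    elif "retained" not in df.columns:
        df = df.assign(retained=True)
    if max_dose is None:
        max_dose = float(df["conc_um"].max())
    rows = []
    for (drug, cell), grp in df[df["retained"]].groupby(["drug", "cell"], sort=True):
        if len(grp) < 2:
            continue
        if len(grp) >= 4:
            fit = fit_4pl(
                grp["conc_um"].to_numpy(), grp["viability"].to_numpy(),
                max_dose=max_dose, drug=drug, cell=cell,
            )
        else:
            fit = DoseResponseFit(
                drug=drug, cell=cell,
                auc=auc_trapezoid(grp["conc_um"].to_numpy(), grp["viability"].to_numpy()),
                b=np.nan, c=np.nan, d=np.nan, e=np.nan,
                ed50_assigned=max_dose, status="failed",
            )
        rows.append(vars(fit))
    return pd.DataFrame(rows)


def subtype_selectivity(
    summary: pd.DataFrame,
    labels: pd.Series,
    metrics: tuple[str, ...] = ("auc", "ed50_assigned"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-drug two-sided Kolmogorov-Smirnov subtype-selectivity test.

    For each drug and metric, compares the metric between the two
    subtype groups; ``direction`` names the subtype with the lower mean
    (the sensitive one, since low AUC/ED50 means high sensitivity).
    Drugs with fewer than ``min_n`` cells in either group are skipped.
    """
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two subtype groups, got {groups}")
    rows = []
    for drug, grp in summary.groupby("drug", sort=True):
        lab = labels.reindex(grp["cell"])
        for metric in metrics:
            a = grp.loc[(lab == groups[0]).to_numpy(), metric].dropna()
            b = grp.loc[(lab == groups[1]).to_numpy(), metric].dropna()
            if len(a) < min_n or len(b) < min_n:
                continue
            res = stats.ks_2samp(a, b, alternative="two-sided")
            direction = groups[0] if a.mean() < b.mean() else groups[1]
            rows.append(
                {"drug": drug, "metric": metric, "ks_stat": res.statistic,
                 "p": res.pvalue, "mean_diff": a.mean() - b.mean(),
                 "sensitive_subtype": direction}
            )
    return pd.DataFrame(
        rows, columns=["drug", "metric", "ks_stat", "p", "mean_diff", "sensitive_subtype"]
    )


def biomarker_correlation(
    features: pd.DataFrame,
    summary: pd.DataFrame,
    metrics: tuple[str, ...] = ("auc", "ed50_assigned"),
    min_shared: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of feature abundance with drug response.

    ``features`` is feature x cell abundance; for every (feature, drug,
    metric) with at least ``min_shared`` shared cells the rank
    correlation is reported, with BH FDR computed per metric across all
    tested pairs.
    """
    rows = []
    for metric in metrics:
        wide = summary.pivot(index="cell", columns="drug", values=metric)
        for drug in wide.columns:
            resp = wide[drug].dropna()
            for feat in features.index:
                x = features.loc[feat, features.columns.intersection(resp.index)]
                x = x.dropna()
                shared = x.index.intersection(resp.index)
                if len(shared) < min_shared:
                    continue
                rho, p = stats.spearmanr(x[shared], resp[shared])
                rows.append(
                    {"feature": feat, "drug": drug, "metric": metric,
                     "rho": rho, "p": p, "n": len(shared)}
                )
    table = pd.DataFrame(rows, columns=["feature", "drug", "metric", "rho", "p", "n"])
    table["q"] = np.nan
    for metric in metrics:
        sel = table["metric"] == metric
        if sel.any():
            table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"])
    return table
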