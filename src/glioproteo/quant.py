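"""TMT quantification: GIS normalization, centering, imputation, and
phospho-site aggregation.

Samples in one multiplex set share a pooled global internal standard
(GIS) channel; dividing each reporter intensity by the GIS intensity of
the same feature makes sets comparable, after which values live on the
log2-ratio scale.  Phosphopeptide intensities are collapsed to a single
phospho-site value by a self-weighted mean over the mono-, di- and
tri-or-more phosphorylated classes:

    I_s = sum_n I_sn^2 / sum_n I_sn

which up-weights the phosphorylation class with the higher intensity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from glioproteo.containers import IntensityMatrix

PHOSPHO_CLASSES = (1, 2, 3)


def gis_normalize(raw: IntensityMatrix, gis: pd.DataFrame) -> IntensityMatrix:
    """Divide raw reporter intensities by the matching GIS channel and log2.

    Parameters
    ----------
    raw
        Raw (non-log) intensity matrix whose ``samples`` annotation maps
        every sample to a ``tmt_set``.
    gis
        Feature x TMT-set frame of GIS channel intensities.

    Returns
    -------
    IntensityMatrix of log2(sample / GIS) ratios; missing raw values
    stay missing.
    """
    if raw.log2:
        raise ValueError("gis_normalize expects raw (non-log) intensities")
    sets = raw.batch_of("tmt_set")
    out = pd.DataFrame(
        np.nan, index=raw.values.index, columns=raw.values.columns, dtype=float
    )
    for sample in raw.values.columns:
        tmt_set = sets[sample]
        if tmt_set not in gis.columns:
            raise ValueError(f"no GIS column for TMT set {tmt_set!r}")
        col = raw.values[sample]
        ref = gis.loc[raw.values.index, tmt_set]
        quantified = col.notna()
        bad = quantified & ((ref <= 0) | ref.isna())
        if bad.any():
            feat = bad.index[bad][0]
            raise ValueError(
                f"non-positive or missing GIS intensity for feature {feat!r} "
                f"in TMT set {tmt_set!r}"
            )
        out[sample] = np.log2(col / ref)
    return IntensityMatrix(out, log2=True, samples=raw.samples)


def median_center(m: IntensityMatrix, batches: pd.Series | None = None) -> IntensityMatrix:
    """Sample-wise median centering, then feature-wise centering per GIS batch.

    Step 1 subtracts each sample's median over features; step 2
    subtracts, within each GIS batch, each feature's median across that
    batch's samples.  After step 2 every feature's within-batch median
    is exactly zero.
    """
    if not m.log2:
        raise ValueError("median_center expects log2 ratios")
    if batches is None:
        batches = m.batch_of("gis_batch")
    else:
        batches = pd.Series(batches)
        missing = m.values.columns.difference(batches.index)
        if len(missing):
            raise ValueError(f"samples without batch assignment: {list(missing)}")
        batches = batches.loc[m.values.columns]
    centered = m.values.sub(m.values.median(axis=0, skipna=True), axis=1)
    for _, cols in centered.columns.to_series().groupby(batches, sort=False):
        block = centered[cols.index]
        centered[cols.index] = block.sub(block.median(axis=1, skipna=True), axis=0)
    return IntensityMatrix(centered, log2=True, samples=m.samples)


def impute_second_smallest(m: IntensityMatrix, scope: str = "feature") -> IntensityMatrix:
    """Replace missing entries with the second-smallest observed value.

    ``scope="feature"`` (default) takes the second order statistic of
    the feature's own observed values; ``scope="global"`` uses the
    second-smallest value of the whole matrix.
    """
    values = m.values.copy()
    if scope == "global":
        flat = np.sort(values.to_numpy().ravel())
        flat = flat[~np.isnan(flat)]
        if flat.size < 2:
            raise ValueError("need at least two observed values to impute")
        values = values.fillna(flat[1])
    elif scope == "feature":
        arr = values.to_numpy()
        for i in range(arr.shape[0]):
            row = arr[i]
            miss = np.isnan(row)
            if not miss.any():
                continue
            obs = np.sort(row[~miss])
            if obs.size < 2:
                raise ValueError(
                    f"feature {values.index[i]!r} has {obs.size} observed "
                    "values; second-smallest imputation needs at least two"
                )
            row[miss] = obs[1]
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return IntensityMatrix(values, log2=m.log2, samples=m.samples)


def filter_gis_coverage(m: IntensityMatrix, min_gis: int) -> IntensityMatrix:
    """Keep features observed in at least ``min_gis`` GIS batches.

    A feature counts as observed in a batch when it has at least one
    non-missing value among that batch's samples.  The global-proteome
    default is coverage in all batches; phospho data conventionally uses
    a minimum of three.
    """
    batches = m.batch_of("gis_batch")
    n_batches = batches.nunique()
    if min_gis > n_batches:
        raise ValueError(f"min_gis={min_gis} exceeds the {n_batches} GIS batches present")
    observed = pd.DataFrame(
        {b: m.values[cols.index].notna().any(axis=1)
         for b, cols in m.values.columns.to_series().groupby(batches, sort=False)}
    )
    keep = observed.sum(axis=1) >= min_gis
    return IntensityMatrix(m.values.loc[keep], log2=m.log2, samples=m.samples)


def phospho_site_intensity(class_values: np.ndarray | list[float]) -> float:
    """Self-weighted mean over phosphorylation-class intensities.

    Absent (NaN) and zero classes are excluded from both sums; with no
    contributing class the result is NaN rather than 0/0.
    """
    v = np.asarray(class_values, dtype=float)
    v = v[~np.isnan(v)]
    v = v[v > 0]
    if v.size == 0:
        return np.nan
    return float(np.sum(v**2) / np.sum(v))


def aggregate_phospho_sites(
    table: pd.DataFrame, log2: bool = True
) -> IntensityMatrix:
    """Collapse a phosphopeptide table to site x sample intensities.

    ``table`` is long-format with columns ``site``, ``phospho_class``
    (1, 2 or 3 = tri-or-more), ``sample`` and ``intensity``.  Peptide
    intensities sharing a (site, class, sample) cell are first averaged
    arithmetically; the class-level averages are then combined by the
    self-weighted mean and, by default, log2 transformed.
    """
    required = {"site", "phospho_class", "sample", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["intensity"].dropna() < 0).any():
        raise ValueError("peptide intensities must be non-negative")
    bad = set(table["phospho_class"].unique()) - set(PHOSPHO_CLASSES)
    if bad:
        raise ValueError(f"phospho_class must be in {PHOSPHO_CLASSES}, got {sorted(bad)}")
    class_means = (
        table.groupby(["site", "sample", "phospho_class"], sort=True)["intensity"]
        .mean()
        .reset_index()
    )
    site_vals = (
        class_means.groupby(["site", "sample"], sort=True)["intensity"]
        .apply(lambda v: phospho_site_intensity(v.to_numpy()))
        .unstack("sample")
    )
    samples = pd.unique(table["sample"])
    site_vals = site_vals.reindex(columns=sorted(samples))
    if log2:
        with np.errstate(divide="ignore"):
            site_vals = np.log2(site_vals)
    return IntensityMatrix(site_vals, log2=log2)


def collapse_isoforms(
    m: IntensityMatrix, gene_map: pd.Series | dict | None = None
) -> IntensityMatrix:
    """Merge feature rows with identical value vectors.

    Protein isoform IDs that quantify identically across all samples are
    redundant and collapse to one row (the lexicographically first ID);
    rows with any differing value — genuinely distinct isoforms such as
    PKM1/PKM2 — are kept separate.  When ``gene_map`` is given, only
    rows sharing a gene symbol may merge.
    """
    values = m.values
    if gene_map is not None:
        genes = pd.Series(gene_map).reindex(values.index)
    else:
        genes = pd.Series("", index=values.index)
    keys: dict[tuple, str] = {}
    keep: list[str] = []
    for fid in sorted(values.index):
        row = values.loc[fid]
        key = (genes[fid],) + tuple(
            ("nan",) if pd.isna(x) else x for x in row.to_numpy()
        )
        if key not in keys:
            keys[key] = fid
            keep.append(fid)
    out = values.loc[keep].sort_index()
    return IntensityMatrix(out, log2=m.log2, samples=m.samples)
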