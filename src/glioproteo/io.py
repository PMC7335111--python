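"""Delimited-file readers and writers for the pipeline's formats.

TSV is the canonical matrix dialect (features in rows, header row of
sample ids, ``NA`` for missing); gene sets use GMT; sample maps are
three-column TSV (sample, tmt_set, gis_batch).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from glioproteo.containers import IntensityMatrix
from glioproteo.enrichment import GeneSetCollection

NA_TOKENS = ("NA", "NaN", "nan", "")


def read_matrix(path, sep: str = "\t", log2: bool = True,
                samples: pd.DataFrame | None = None) -> IntensityMatrix:
    """Read a feature x sample matrix, validating shape and ids."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        width = len(header)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != width:
                raise ValueError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {width}"
                )
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(NA_TOKENS),
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    df.index.name = None
    return IntensityMatrix(df.astype(float), log2=log2, samples=samples)


def write_matrix(m: IntensityMatrix | pd.DataFrame, path, sep: str = "\t") -> None:
    values = m.values if isinstance(m, IntensityMatrix) else m
    values.to_csv(path, sep=sep, na_rep="NA", index_label="feature")


def read_sample_map(path, sep: str = "\t") -> pd.DataFrame:
    """Sample annotation table indexed by sample id."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_sample_map(samples: pd.DataFrame, path, sep: str = "\t") -> None:
    samples.to_csv(path, sep=sep, index_label="sample")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 columns")
            name, desc = fields[0], fields[1]
            genes = sorted({g for g in fields[2:] if g})
            if not genes:
                continue  # empty sets are dropped
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sorted(sets.items()):
            desc = sets.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_drug_screen(path, sep: str = ",") -> pd.DataFrame:
    """Long-format drug screen table (drug, cell, conc_um, viability)."""
    df = pd.read_csv(path, sep=sep)
    required = {"drug", "cell", "conc_um", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
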