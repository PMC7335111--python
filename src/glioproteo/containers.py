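"""Shared in-memory containers for the analysis stages.

Matrices are pandas DataFrames with features in rows and samples in
columns; missing measurements are NaN, never sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntensityMatrix:
    """Feature x sample abundance table.

    Parameters
    ----------
    values
        Features in rows, samples in columns.  NaN marks a missing
        measurement.  Raw reporter intensities must be non-negative;
        after GIS normalization the matrix holds log2 ratios.
    log2
        False for raw intensities, True once the values are log2 ratios.
    samples
        Optional per-sample annotation frame indexed by sample id with
        columns such as ``tmt_set`` (multiplex set id) and ``gis_batch``
        (which pooled internal standard the set was referenced to).
    """

    values: pd.DataFrame
    log2: bool = False
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if not self.log2:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("raw intensities must be non-negative")
        if self.samples is not None:
            missing = self.values.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"samples without annotation: {list(missing)}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the measurement is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def batch_of(self, column: str = "gis_batch") -> pd.Series:
        if self.samples is None or column not in self.samples.columns:
            raise ValueError(f"sample annotation {column!r} is required")
        batches = self.samples.loc[self.values.columns, column]
        if batches.isna().any():
            bad = batches.index[batches.isna()][0]
            raise ValueError(f"sample {bad!r} has no {column!r} assignment")
        return batches

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            log2=self.log2,
            samples=None if self.samples is None else self.samples.copy(),
        )


@dataclass
class ConsensusResult:
    """Output of consensus clustering over a range of cluster numbers K.

    ``consensus[K]`` holds co-clustering frequencies (NaN where a sample
    pair was never co-sampled); ``pac[K]`` the proportion of ambiguous
    clustering; ``optimal_k`` minimizes PAC (ties to the smaller K);
    ``labels`` the final partition at ``optimal_k``.
    """

    k_values: list[int]
    consensus: dict[int, pd.DataFrame]
    pac: dict[int, float]
    optimal_k: int
    labels: pd.Series

    def pac_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.k_values, "PAC": [self.pac[k] for k in self.k_values]}
        ).set_index("K")


@dataclass
class PCAResult:
    """Principal components of a feature x sample matrix.

    ``loadings`` is features x components (unit-norm columns);
    ``scores`` samples x components; ``explained_variance_ratio`` per
    component.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass
class SignatureSet:
    """Equal-sized gene lists defining the two proteome subtypes.

    ``gpc1_high`` genes are elevated in GPC1, ``gpc2_high`` in GPC2; the
    two lists are disjoint and the same length.
    """

    gpc1_high: list[str]
    gpc2_high: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gpc1_high) != len(self.gpc2_high):
            raise ValueError(
                "signature sides must be the same size "
                f"({len(self.gpc1_high)} vs {len(self.gpc2_high)})"
            )
        if not self.gpc1_high:
            raise ValueError("signature is empty")
        if set(self.gpc1_high) & set(self.gpc2_high):
            raise ValueError("signature sides must be disjoint")

    @property
    def genes(self) -> list[str]:
        return list(self.gpc1_high) + list(self.gpc2_high)


@dataclass
class DoseResponseFit:
    """Summary of one drug x cell viability curve.

    ``ed50_assigned`` is the four-parameter log-logistic inflection
    capped at the highest tested dose; ``status`` is ``"ok"``,
    ``"capped"`` or ``"failed"``.
    """

    drug: str
    cell: str
    auc: float
    b: float
    c: float
    d: float
    e: float
    ed50_assigned: float
    status: str = "ok"
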