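"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage is exercised on generated data: two-batch TMT
log-ratio cohorts with a planted two-subtype structure (shaped like a
39-sample, 26/13 proteome cohort), phosphopeptide tables with known
site-level ground truth, z-scorable single-cell matrices with or
without subtype signal, four-parameter log-logistic viability screens
with injected high-viability artifacts, and a toy transcript/variant
fixture covering SNV, in-frame indel, stop-gain and depth-gated
stop-loss cases.  Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glioproteo.containers import IntensityMatrix, SignatureSet
from glioproteo.variantdb import TranscriptModel, VariantCall


@dataclass
class CohortConfig:
    """Shape and signal strength of a synthetic proteome cohort."""

    n_samples: int = 39
    group_sizes: tuple[int, ...] = (26, 13)
    n_proteins: int = 1000
    n_batches: int = 2
    effect_size: float = 1.0
    frac_informative: float = 0.2
    missing_rate: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError(
                f"group sizes {self.group_sizes} must sum to n_samples={self.n_samples}"
            )
        if not 0 <= self.frac_informative <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class DrugScreenConfig:
    """Shape of a synthetic viability screen (60 drugs x 50 cells, 7-dose
    4-fold dilution grid topping at the 20 uM highest tested dose)."""

    n_drugs: int = 60
    n_cells: int = 50
    concentrations: tuple[float, ...] = tuple(20.0 / 4**k for k in range(6, -1, -1))
    true_4pl: dict | None = None
    outlier_rate: float = 0.02
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if (conc <= 0).any() or (np.diff(conc) <= 0).any():
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.true_4pl is not None:
            for (b, c, d, e) in self.true_4pl.values():
                if not 0 <= c <= d:
                    raise ValueError("true 4PL parameters require 0 <= c <= d")


def generate_proteome_bundle(config: CohortConfig):
    """Two-batch log2-ratio cohort with a planted two-group structure.

    Returns ``(matrix, labels, batches)``: an :class:`IntensityMatrix`
    of log2 ratios with MCAR missingness, the true subtype label per
    sample, and the GIS-batch assignment.  The first half of the
    informative proteins is elevated in GPC1, the second half in GPC2,
    by ``effect_size`` log2 units between group means.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    features = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    labels = pd.Series(
        np.repeat(
            [f"GPC{k + 1}" for k in range(len(config.group_sizes))],
            config.group_sizes,
        ),
        index=samples, name="subtype",
    )
    batches = pd.Series(
        [f"GIS{(i % config.n_batches) + 1}" for i in range(config.n_samples)],
        index=samples, name="gis_batch",
    )
    X = rng.normal(0.0, config.noise_sd, size=(config.n_proteins, config.n_samples))
    n_inf = int(round(config.frac_informative * config.n_proteins))
    half = n_inf // 2
    in_g1 = (labels == "GPC1").to_numpy()
    X[:half, in_g1] += config.effect_size / 2
    X[:half, ~in_g1] -= config.effect_size / 2
    X[half:n_inf, in_g1] -= config.effect_size / 2
    X[half:n_inf, ~in_g1] += config.effect_size / 2
    if config.missing_rate > 0:
        miss = rng.random(X.shape) < config.missing_rate
        X[miss] = np.nan
    values = pd.DataFrame(X, index=features, columns=samples)
    sample_info = pd.DataFrame(
        {"tmt_set": batches.to_numpy(), "gis_batch": batches.to_numpy()},
        index=samples,
    )
    matrix = IntensityMatrix(values, log2=True, samples=sample_info)
    matrix.values.attrs["informative"] = features[:n_inf]
    return matrix, labels, batches


def generate_phosphopeptides(n_sites: int, n_samples: int, seed: int = 0):
    """Phosphopeptide table with known site-level ground truth.

    Each site populates one to three phosphorylation classes (mono, di,
    tri-or-more) per sample, with one or two peptides per class.
    Returns ``(table, truth)``: the long-format peptide table and the
    site x sample ground-truth intensities (the self-weighted mean of
    the planted class averages, pre-log).
    """
    if n_sites < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    rows = []
    truth = np.zeros((n_sites, n_samples))
    for s in range(n_sites):
        base = 10 ** rng.uniform(2, 4)
        for j in range(n_samples):
            n_classes = rng.integers(1, 4)
            classes = 1 + rng.permutation(3)[:n_classes]
            class_means = []
            for cls in sorted(classes):
                n_pep = rng.integers(1, 3)
                peps = base * rng.uniform(0.5, 1.5, size=n_pep)
                class_means.append(peps.mean())
                for k, inten in enumerate(peps):
                    rows.append(
                        {"site": f"site{s + 1:04d}", "phospho_class": int(cls),
                         "sample": samples[j], "peptide": f"pep{s}_{cls}_{k}",
                         "intensity": float(inten)}
                    )
            cm = np.array(class_means)
            truth[s, j] = float((cm**2).sum() / cm.sum())
    table = pd.DataFrame(rows)
    truth_df = pd.DataFrame(
        truth, index=[f"site{s + 1:04d}" for s in range(n_sites)], columns=samples
    )
    return table, truth_df


def generate_single_cells(
    n_cells: int,
    signature: SignatureSet,
    signal: float = 0.0,
    seed: int = 0,
    n_background_genes: int = 0,
):
    """Cell x gene z-scorable matrix with optional planted subtype signal.

    With ``signal == 0`` every entry is i.i.d. standard normal and all
    cells are labeled ``"null"`` (the calibration input).  With
    ``signal > 0`` cells alternate between GPC1 and GPC2 and their own
    side's signature genes are shifted upward by ``signal``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    genes = signature.genes + [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    if len(set(genes)) != len(genes):
        raise ValueError("background gene names collide with the signature")
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    Z = rng.standard_normal((n_cells, len(genes)))
    m = len(signature.gpc1_high)
    if signal == 0:
        labels = pd.Series("null", index=cells, name="truth")
    else:
        truth = np.where(np.arange(n_cells) % 2 == 0, "GPC1", "GPC2")
        labels = pd.Series(truth, index=cells, name="truth")
        Z[truth == "GPC1", :m] += signal
        Z[truth == "GPC2", m: 2 * m] += signal
    return pd.DataFrame(Z, index=cells, columns=genes), labels


def generate_dose_response(config: DrugScreenConfig):
    """Long-format viability screen from known 4PL truth.

    Returns ``(table, truth)``: the (drug, cell, conc_um, viability)
    table with an ``is_outlier`` flag, and the per-curve true
    parameters.  Injected outliers are placed above both removal
    thresholds (1.5 and Q3 + 3 x IQR of their clean drug/concentration
    stratum) so the smoothing rule is verifiable.
    """
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)
    drugs = [f"drug{i + 1:02d}" for i in range(config.n_drugs)]
    cells = [f"PDC{i + 1:02d}" for i in range(config.n_cells)]
    truth_rows = []
    params = {}
    for drug in drugs:
        for cell in cells:
            if config.true_4pl is not None and (drug, cell) in config.true_4pl:
                b, c, d, e = config.true_4pl[(drug, cell)]
            else:
                b = rng.uniform(0.5, 2.0)
                c = rng.uniform(0.0, 0.2)
                d = rng.uniform(0.9, 1.1)
                e = float(np.exp(rng.uniform(np.log(conc[0] * 4), np.log(conc[-1]))))
            params[(drug, cell)] = (b, c, d, e)
            truth_rows.append({"drug": drug, "cell": cell, "b": b, "c": c, "d": d, "e": e})
    rows = []
    for drug in drugs:
        clean = {}
        for cell in cells:
            b, c, d, e = params[(drug, cell)]
            v = c + (d - c) / (1.0 + np.exp(b * (np.log(conc) - np.log(e))))
            v = np.clip(v + rng.normal(0, config.noise_sd, size=conc.size), 0, None)
            clean[cell] = v
        for ci, x in enumerate(conc):
            stratum = np.array([clean[cell][ci] for cell in cells])
            # outliers must beat Q3 + 3*IQR of the stratum as observed
            # (outliers included); as long as fewer than a quarter of the
            # points are outliers, Q3 and Q1 stay within the clean range,
            # so max + 3*(max - min) of the clean values is a safe bound
            bound = max(1.5, stratum.max() + 3 * (stratum.max() - stratum.min()))
            k_max = int((len(cells) - 1) * 0.25)
            flags = rng.random(len(cells)) < config.outlier_rate
            if flags.sum() > k_max:
                drop = np.flatnonzero(flags)[k_max:]
                flags[drop] = False
            for cell, outlier in zip(cells, flags):
                v = clean[cell][ci]
                if outlier:
                    v = bound + rng.uniform(0.5, 1.5)
                rows.append(
                    {"drug": drug, "cell": cell, "conc_um": float(x),
                     "viability": float(v), "is_outlier": bool(outlier)}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


_CODON = {
    "M": "ATG", "A": "GCT", "K": "AAA", "R": "CGT", "L": "CTG", "D": "GAT",
    "E": "GAA", "G": "GGT", "S": "TCT", "T": "ACT", "N": "AAT", "P": "CCT",
    "F": "TTT", "V": "GTT", "I": "ATT", "H": "CAT", "Q": "CAA", "W": "TGG",
    "Y": "TAT", "*": "TAA",
}


def _encode(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def generate_variant_fixture(seed: int = 0):
    """Toy transcripts and variant calls covering the translation rules.

    Returns ``(transcripts, variants)`` with one missense SNV, one
    in-frame deletion, one stop-gain SNV, and one stop-loss SNV whose
    downstream depth profile supports exactly five read-through codons
    before dropping to the depth floor.
    """
    rng = np.random.default_rng(seed)
    fpkm = rng.uniform(2.0, 50.0, size=4)

    # T1: missense SNV G -> D at residue 5 (GGT -> GAT)
    p1 = "MASTKGHILRADEFGSK" + "*"
    t1 = TranscriptModel("T1", _encode(p1), fpkm=float(fpkm[0]))
    v1 = VariantCall("T1", 5 * 3 + 1, "G", "A")

    # T2: in-frame deletion of the L at residue 8 (CTG removed)
    p2 = "MNSTKGHILRADEFGHK" + "*"
    t2 = TranscriptModel("T2", _encode(p2), fpkm=float(fpkm[1]))
    v2 = VariantCall("T2", 8 * 3 - 1, _encode(p2)[8 * 3 - 1: 8 * 3 + 3], _encode(p2)[8 * 3 - 1])

    # T3: stop-gain SNV K -> * at residue 10 (AAA -> TAA)
    p3 = "MASTKGHILRKDEFGHK" + "*"
    t3 = TranscriptModel("T3", _encode(p3), fpkm=float(fpkm[2]))
    v3 = VariantCall("T3", 10 * 3, "A", "T")

    # T4: stop-loss SNV at the terminal stop (TAA -> CAA = Q); the
    # downstream sequence supports 5 deep codons, then depth drops to 2.
    p4 = "MASTKGHILRADEFGHK" + "*"
    downstream_aa = "ILKAGWYVDE"
    three_prime = _encode(downstream_aa)
    depth = np.array([10] * 15 + [2] * (len(three_prime) - 15))
    t4 = TranscriptModel(
        "T4", _encode(p4), fpkm=float(fpkm[3]),
        three_prime=three_prime, depth_three_prime=depth,
    )
    v4 = VariantCall("T4", len(_encode(p4)) - 3, "T", "C")

    return [t1, t2, t3, t4], [v1, v2, v3, v4]
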