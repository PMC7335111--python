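"""Pipeline orchestration: seeded stage execution with logged parameters.

A single global seed is fanned out to per-stage seeds through
:func:`derive_seed` (SeedSequence over the global seed and a stable
hash of the stage name), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import pandas as pd

from glioproteo import diffexp, io, quant, subtyping
from glioproteo.synthetic import CohortConfig, generate_proteome_bundle

logger = logging.getLogger("glioproteo")

STAGES = ("simulate", "normalize", "subtype", "diffexp")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    logger.addHandler(fh)


def run_pipeline(config: dict, outdir) -> dict:
    """Run the enabled stages in dependency order.

    ``config`` keys: ``seed`` (global seed), ``stages`` (subset of
    simulate/normalize/subtype/diffexp; default all), ``cohort``
    (CohortConfig field overrides), ``subtype`` (k_min/k_max/n_iter).
    Artifacts (matrices, labels, tables) are written under ``outdir``;
    rerunning with the same config reproduces them bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    artifacts: dict = {}
    try:
        if "simulate" in stages:
            stage_seed = derive_seed(seed, "simulate")
            logger.info("stage=simulate seed=%d", stage_seed)
            cohort = CohortConfig(**{**config.get("cohort", {}), "seed": stage_seed})
            matrix, labels, batches = generate_proteome_bundle(cohort)
            io.write_matrix(matrix, outdir / "matrix.tsv")
            labels.to_frame().to_csv(outdir / "true_labels.tsv", sep="\t")
            io.write_sample_map(matrix.samples, outdir / "samples.tsv")
            artifacts.update(matrix=matrix, true_labels=labels, batches=batches)
        if "normalize" in stages:
            logger.info("stage=normalize")
            m = artifacts.get("matrix")
            if m is None:
                m = io.read_matrix(outdir / "matrix.tsv",
                                   samples=io.read_sample_map(outdir / "samples.tsv"))
            m = quant.median_center(m)
            m = quant.impute_second_smallest(m)
            io.write_matrix(m, outdir / "normalized.tsv")
            artifacts["normalized"] = m
        if "subtype" in stages:
            stage_seed = derive_seed(seed, "subtype")
            sub_cfg = config.get("subtype", {})
            k_range = range(sub_cfg.get("k_min", 2), sub_cfg.get("k_max", 6) + 1)
            n_iter = sub_cfg.get("n_iter", 1000)
            logger.info("stage=subtype seed=%d k=%s iters=%d", stage_seed, list(k_range), n_iter)
            result = subtyping.consensus_cluster(
                artifacts["normalized"], k_range=k_range, n_iter=n_iter, seed=stage_seed
            )
            result.labels.to_frame().to_csv(outdir / "subtype_labels.tsv", sep="\t")
            result.pac_table().to_csv(outdir / "pac.tsv", sep="\t")
            for k, cm in result.consensus.items():
                cm.to_csv(outdir / f"consensus_K{k}.tsv", sep="\t", na_rep="NA")
            artifacts["consensus"] = result
        if "diffexp" in stages:
            logger.info("stage=diffexp")
            labels = artifacts["consensus"].labels
            table = diffexp.dep_test(artifacts["normalized"], labels)
            table.to_csv(outdir / "diffexp.tsv", sep="\t")
            artifacts["diffexp"] = table
    except Exception as exc:  # annotate which stage died
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    with open(outdir / "config.json", "w") as fh:
        json.dump({"seed": seed, "stages": list(stages)}, fh, indent=2)
    return artifacts
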