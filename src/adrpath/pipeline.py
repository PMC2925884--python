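"""End-to-end pipeline configuration and orchestration.

The pipeline wires the stages together: cohort filters → docking
post-processing → feature build → ADR harmonization → two-phase inference,
optionally followed by the permutation null and the literature filter.
Every run writes a manifest recording the config hash, input checksums and
per-stage record counts, so outputs are reproducible byte-for-byte from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import docking, filters, inference, io, nulls, vocab

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    # inputs
    drugs: str
    adr: str
    proteins: Optional[str] = None
    similarity: Optional[str] = None
    docking: str
    pathway_map: str
    hits: Optional[str] = None
    # outputs
    out_dir: str = "results"
    # docking post-processing
    better_direction: str
    axis: str = "receptor"
    # cohort filters
    mw_min: float = 100.0
    mw_max: float = 800.0
    max_rot: int = 10
    max_res: float = 3.0
    min_len: int = 50
    organism: str = "human"
    id_thresh: float = Field(90.0, gt=0, le=100)
    cov_thresh: float = Field(90.0, gt=0, le=100)
    # ADR harmonization
    min_freq: float = Field(1.0, ge=0)
    min_drugs: int = Field(3, ge=0)
    max_frac: float = Field(0.05, gt=0, le=1)
    stemmer: str = "suffix"
    # inference
    rel_lambda: float = Field(0.1, gt=0, le=1)
    fdr: float = Field(0.02, gt=0, lt=1)
    tol: float = Field(1e-6, gt=0)
    max_iter: int = Field(100_000, ge=1)
    # nulls / literature
    n_trials: int = Field(0, ge=0)   # 0 = skip the permutation control
    min_hits: int = Field(5, ge=0)
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("better_direction")
    @classmethod
    def _direction(cls, v: str) -> str:
        io.Direction.coerce(v)
        return v

    @field_validator("axis")
    @classmethod
    def _axis(cls, v: str) -> str:
        docking.Axis.coerce(v)
        return v

    @field_validator("stemmer")
    @classmethod
    def _stemmer(cls, v: str) -> str:
        if v not in vocab.STEMMERS:
            raise ValueError(f"unknown stemmer {v!r}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Writes to ``config.out_dir``: associations.tsv, features.tsv,
    adr_matrix.tsv, network.sif, manifest.json, and (when ``n_trials`` > 0)
    null.json; literature-filtered associations when a hit table is given.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "inputs": {},
        "stages": {},
    }

    def stage(name: str):
        def run(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return run

    for key in ("drugs", "adr", "proteins", "similarity", "docking", "pathway_map", "hits"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = io.file_sha256(path)

    drugs_df = stage("read drugs")(lambda: io.read_table(config.drugs, "drugs"))
    adr_df = stage("read adr")(lambda: io.read_table(config.adr, "adr"))
    dsm = stage("read docking")(lambda: io.read_docking(config.docking, config.better_direction))
    pathway_map = stage("read pathway_map")(lambda: io.read_table(config.pathway_map, "pathway_map"))

    kept_drugs, drug_log = stage("filter ligands")(
        lambda: filters.filter_ligands(drugs_df, config.mw_min, config.mw_max, config.max_rot)
    )
    manifest["stages"]["drugs_retained"] = len(kept_drugs)

    kept_proteins: list[str] | None = None
    if config.proteins:
        proteins_df = io.read_table(config.proteins, "proteins")
        kept_proteins, _ = stage("filter targets")(
            lambda: filters.filter_targets(proteins_df, config.max_res, config.min_len, config.organism)
        )
        if config.similarity:
            sim = io.read_table(config.similarity, "similarity")
            sim = sim[sim.protein_a.isin(kept_proteins) & sim.protein_b.isin(kept_proteins)]
            kept_proteins, _ = stage("cluster targets")(
                lambda: filters.cluster_redundant(
                    kept_proteins, sim, config.id_thresh, config.cov_thresh,
                    filters.protein_quality_key(proteins_df),
                )
            )
        manifest["stages"]["proteins_retained"] = len(kept_proteins)

    entries = dsm.entries[dsm.entries.drug_id.isin(kept_drugs)]
    if kept_proteins is not None:
        entries = entries[entries.protein_id.isin(kept_proteins)]
    dsm = io.DockingScoreMatrix(entries.reset_index(drop=True), dsm.better_direction)

    best = stage("merge pockets")(lambda: docking.merge_pockets(dsm))
    ztab = stage("normalize")(
        lambda: docking.normalize_scores(best, dsm.better_direction, config.axis)
    )
    called = stage("call interactions")(lambda: docking.call_interactions(ztab))
    manifest["stages"]["interactions_retained"] = int(called.retained.sum())

    adr_matrix = stage("filter ADRs")(
        lambda: vocab.filter_adrs(
            adr_df, kept_drugs,
            min_freq=config.min_freq, min_drugs=config.min_drugs,
            max_frac=config.max_frac, stemmer=config.stemmer,
        )
    )
    manifest["stages"]["adr_groups_retained"] = len(adr_matrix.adr_groups)

    X = stage("build features")(
        lambda: docking.build_pathway_features(called, pathway_map, drugs=kept_drugs)
    )
    Y = adr_matrix.occurrence.reindex(X.index)

    assoc = stage("infer")(
        lambda: inference.infer_associations(
            X, Y, rel_lambda=config.rel_lambda, fdr=config.fdr,
            tol=config.tol, max_iter=config.max_iter,
        )
    )
    manifest["stages"]["phase1_candidates"] = len(assoc)
    manifest["stages"]["significant"] = int(assoc.significant.sum())

    io.write_table(X.reset_index(), out_dir / "features.tsv")
    io.write_table(Y.reset_index(), out_dir / "adr_matrix.tsv")
    io.write_table(assoc, out_dir / "associations.tsv")
    stage("export network")(
        lambda: io.export_network(
            assoc[assoc.significant], called, pathway_map, Y, out_dir / "network.sif"
        )
    )

    if config.n_trials > 0:
        null = stage("null run")(
            lambda: nulls.null_distribution(
                X, Y, n_trials=config.n_trials, seed=config.seed,
                rel_lambda=config.rel_lambda, fdr=config.fdr,
                tol=config.tol, max_iter=config.max_iter,
            )
        )
        manifest["stages"]["null"] = {
            "mean": null.mean, "sd": null.sd, "observed": null.observed,
            "empirical_p": null.empirical_p,
        }
        with open(out_dir / "null.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"trial_counts": null.trial_counts, "observed": null.observed,
                 "mean": null.mean, "sd": null.sd,
                 "empirical_p": null.empirical_p, "normal_p": null.normal_p},
                fh, indent=2,
            )

    if config.hits:
        hits = io.read_table(config.hits, "hits")
        filtered = stage("literature filter")(
            lambda: nulls.literature_filter(assoc[assoc.significant], hits, config.min_hits)
        )
        manifest["stages"]["literature_supported"] = len(filtered)
        io.write_table(filtered, out_dir / "associations_literature.tsv")

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
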