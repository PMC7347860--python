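"""Pipeline orchestration: run configured stages and write result tables.

A run is described by a structured config (usually YAML): an input table
(or a synthetic-data stage), the panels, the stages to run, an output
directory and an RNG seed.  Each enabled stage writes its result tables
as TSV; a JSON manifest records the config hash, seed and stage
versions, so a rerun with the same config and seed is bit-identical for
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from tei.core_io import (
    DEFAULT_PANELS,
    Dialect,
    ExpressionTable,
    GenePanel,
    ValidationError,
    read_expression_table,
    read_sample_metadata,
    write_expression_table,
    write_sample_metadata,
)
from tei import cluster_support, ei_ratio, probe_selection, signatures, synthetic_data

logger = logging.getLogger("tei")

KNOWN_STAGES = ("simulate", "probe_selection", "signatures", "clustering", "ei_ratio")

__all__ = ["run_pipeline", "ConfigError", "OrderingError"]


class ConfigError(ValueError):
    """The pipeline config is malformed."""


class OrderingError(ConfigError):
    """A stage's input requirement is unmet by the preceding stages."""


def _config_hash(config: dict) -> str:
    # outdir is excluded: where results land does not change what they are
    hashed = {k: v for k, v in config.items() if k != "outdir"}
    blob = json.dumps(hashed, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_panels(config: dict) -> dict[str, GenePanel]:
    panels = dict(DEFAULT_PANELS)
    for name, genes in (config.get("panels") or {}).items():
        panels[name] = GenePanel(name, tuple(genes))
    return panels


def _simulate(cfg: dict, seed: int):
    kind = cfg.get("kind", "regional")
    overrides = {k: v for k, v in cfg.items() if k != "kind"}
    if kind == "regional":
        sim = synthetic_data.default_regional_config(seed=seed)
    elif kind == "cells":
        sim = synthetic_data.default_cell_config(seed=seed)
    elif kind == "development":
        sim = synthetic_data.default_dev_config(seed=seed)
    else:
        raise ConfigError(f"unknown simulate kind {kind!r}")
    for k, v in overrides.items():
        if not hasattr(sim, k):
            raise ConfigError(f"unknown simulate option {k!r}")
        setattr(sim, k, v)
    gen = {"regional": synthetic_data.gen_regional_microarray,
           "cells": synthetic_data.gen_single_cell,
           "development": synthetic_data.gen_developmental}[kind]
    return gen(sim)


def _clustering_matrix(table: ExpressionTable, item_key: str):
    """Items x (gene x subject) matrix for structure clustering.

    Each item (substructure by default) is described by its per-gene
    expression in every subject — the feature axis the bootstrap
    resamples.  Falls back to per-gene means when no subject column
    exists.
    """
    meta = table.sample_meta
    if item_key not in meta.columns:
        raise OrderingError(f"clustering needs a {item_key!r} metadata column")
    genevals = pd.DataFrame(
        {g: table.values[table.features_for_gene(g)].mean(axis=1)
         for g in table.genes()},
        index=table.values.index,
    )
    if "subject_id" in meta.columns and meta["subject_id"].nunique() > 1:
        long = genevals.copy()
        long["_item"] = meta[item_key]
        long["_subj"] = meta["subject_id"]
        wide = long.groupby(["_item", "_subj"], observed=True).mean()
        mat = wide.unstack("_subj")
        mat = mat.dropna(axis=1, how="any")
    else:
        mat = genevals.groupby(meta[item_key], observed=True).mean()
    if mat.isna().any().any():
        raise ValidationError("missing values in clustering matrix")
    return mat


def run_pipeline(config: dict, seed: int | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the configured stages; return the manifest (also written to disk)."""
    config = dict(config)
    stages = list(config.get("stages") or [])
    if not stages:
        raise ConfigError("config names no stages")
    for s in stages:
        if s not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    if seed is None:
        seed = int(config.get("seed", 0))
    outdir = Path(outdir if outdir is not None else config.get("outdir", "tei_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    panels = _build_panels(config)
    outputs: dict[str, list[str]] = {}

    def write_tsv(df: pd.DataFrame, stage: str, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs.setdefault(stage, []).append(name)

    table: ExpressionTable | None = None
    truth = None

    if "simulate" in stages:
        table, meta, truth = _simulate(config.get("simulate") or {}, seed)
        write_expression_table(table, outdir / "expression.tsv")
        write_sample_metadata(meta, outdir / "sample_meta.tsv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
        outputs["simulate"] = ["expression.tsv", "sample_meta.tsv",
                               "ground_truth.json"]
    elif "input" in config:
        inp = config["input"]
        dialect = Dialect(**(inp.get("dialect") or {"scale": "linear"}))
        meta = None
        if inp.get("sample_meta"):
            meta = read_sample_metadata(inp["sample_meta"])
        table = read_expression_table(inp["expression"], dialect, meta)
    if table is None:
        raise ConfigError("no input table: configure 'input' or a simulate stage")

    if "probe_selection" in stages:
        if table.is_gene_level():
            logger.info("table already gene-level; probe selection skipped")
        else:
            report, table, _ = probe_selection.select_representative_probes(table)
            write_tsv(report, "probe_selection", "probe_selection.tsv")
            write_expression_table(table, outdir / "gene_expression.tsv")
            outputs["probe_selection"].append("gene_expression.tsv")

    if "signatures" in stages:
        if not table.is_gene_level():
            raise OrderingError("signatures needs a gene-level table; run "
                                "probe_selection first")
        panel = panels["AMPAR"]
        if "age" in table.sample_meta.columns:
            table, age_report = signatures.adjust_age(table)
            write_tsv(age_report, "signatures", "age_adjustment.tsv")
        group = next((k for k in ("structure", "cell_type")
                      if k in table.sample_meta.columns), None)
        contrib = signatures.proportional_contribution(
            table, panel, group_by=group, policy="subset")
        write_tsv(contrib, "signatures", "contributions.tsv")
        if "substructure" in table.sample_meta.columns:
            enrich = signatures.fold_enrichment(table, panel, policy="subset")
            write_tsv(enrich, "signatures", "enrichment.tsv")
            anova_rows = []
            for gene in panel:
                try:
                    anova_rows.append(
                        signatures.nested_anova(table, gene).to_dict())
                except ValidationError as exc:
                    logger.warning("nested ANOVA skipped for %s: %s", gene, exc)
            if anova_rows:
                write_tsv(pd.DataFrame(anova_rows), "signatures", "anova.tsv")

    if "clustering" in stages:
        if not table.is_gene_level():
            raise OrderingError("clustering needs a gene-level table; run "
                                "probe_selection first")
        item_key = config.get("clustering", {}).get("item_key", "substructure")
        mat = _clustering_matrix(table, item_key)
        bcfg = cluster_support.BootstrapConfig(
            b_per_scale=int(config.get("clustering", {}).get("b_per_scale", 100)),
            seed=seed,
        )
        support = cluster_support.multiscale_bootstrap(
            mat.to_numpy(), bcfg, labels=[str(i) for i in mat.index])
        write_tsv(support.to_dataframe(), "clustering", "cluster_support.tsv")
        with open(outdir / "dendrogram.nwk", "w") as fh:
            fh.write(support.dendrogram.to_newick(support.support_map("au")))
        outputs["clustering"].append("dendrogram.nwk")

    if "ei_ratio" in stages:
        group = next((k for k in ("cell_type", "substructure", "structure")
                      if k in table.sample_meta.columns), None)
        records = ei_ratio.compute_tei(table, panels["AMPAR"], panels["GABAAR"],
                                       group_by=group, policy="subset")
        write_tsv(records.reset_index(names="sample_id"), "ei_ratio",
                  "ei_records.tsv")
        if group:
            write_tsv(ei_ratio.group_summary(records, group), "ei_ratio",
                      "ei_group_summary.tsv")

    from tei import __version__ as pkg_version

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": pkg_version,
        "stages": stages,
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
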