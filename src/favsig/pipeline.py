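"""End-to-end workflows and artifact management.

Three workflows mirror the analysis branches:

* tumor — low-count filter, log2 normalization, genome-wide Cox screen,
  confounder filter, favorability scoring, k-means subgroups, subgroup
  survival comparison, cross-validation, and Fisher enrichment of the
  favorable and unfavorable signatures separately;
* cellline — CV filter, Kendall-tau IC-50 screen, favorability scoring,
  subgroups, Wilcoxon IC-50 comparison, enrichment;
* phenotype — growth-rate computation, per-trait Spearman correlations
  with -log10(IC-50) (kp, volume, kg and CORE metabolites), drug
  similarity matrix and dendrogram.

Every run writes a manifest recording the configuration (and its hash),
the per-stage gene-count funnel, and the paths of all artifacts. Reruns
with the same configuration and inputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import DoseResponsePanel, ExpressionMatrix
from .enrich import GeneSetCollection, enrichment_table, fisher_enrichment
from .estimators import CellLineStratifier, FavorabilityStratifier
from .phenotype import core_vs_sensitivity, correlate_sensitivity, drug_similarity
from .preprocess import filter_low_count, log2_normalize
from .stratify import CVResult, cross_validate

__all__ = [
    "RunConfig",
    "run_tumor_workflow",
    "run_cellline_workflow",
    "run_phenotype_workflow",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one workflow run."""

    workflow: str = "tumor"  # tumor | cellline | phenotype
    expression_path: Optional[str] = None
    expression_scale: str = "log2"
    survival_path: Optional[str] = None
    ic50_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    gmt_path: Optional[str] = None
    drug: Optional[str] = None
    output_dir: Optional[str] = None
    alpha: float = 0.05
    confounder_alpha: float = 0.05
    binary_covariates: Sequence[str] = ()
    ordinal_or_continuous_covariates: Sequence[str] = ()
    mode: str = "gene_direction"
    gene_subset: Optional[Sequence[str]] = None
    k: int = 2
    n_restarts: int = 50
    n_folds: int = 5
    min_cv: float = 0.05
    min_tau: float = 0.2
    max_tau_p: float = 0.01
    lower_q: float = 0.25
    upper_q: float = 0.75
    enrich_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.binary_covariates = tuple(self.binary_covariates)
        self.ordinal_or_continuous_covariates = tuple(
            self.ordinal_or_continuous_covariates)
        if self.gene_subset is not None:
            self.gene_subset = tuple(self.gene_subset)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("binary_covariates", "ordinal_or_continuous_covariates"):
            d[key] = list(d[key])
        if d["gene_subset"] is not None:
            d["gene_subset"] = list(d["gene_subset"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: RunConfig, funnel: dict,
                    artifacts: dict, extras: dict) -> dict:
    manifest = {
        "workflow": config.workflow,
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "funnel": funnel,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        **extras,
    }
    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _enrich_both(model, gene_sets: Optional[GeneSetCollection],
                 universe, alpha: float, out_dir: Optional[Path],
                 artifacts: dict) -> dict:
    if gene_sets is None:
        return {}
    coll = gene_sets if gene_sets.universe else gene_sets.with_universe(universe)
    out = {}
    for direction in ("favorable", "unfavorable"):
        genes = model.hits_.index[model.hits_["direction"] == direction]
        if len(genes) == 0:
            out[direction] = []
            continue
        try:
            res = fisher_enrichment(genes, coll, alpha=alpha)
        except ValueError:
            out[direction] = []
            continue
        out[direction] = res
        if out_dir is not None:
            p = out_dir / f"enrichment_{direction}.tsv"
            enrichment_table(res).to_csv(p, sep="\t", index=False)
            artifacts[f"enrichment_{direction}"] = p
    return {"enrichment": out}


def run_tumor_workflow(
    m: ExpressionMatrix,
    surv: pd.DataFrame,
    config: RunConfig,
    gene_sets: Optional[GeneSetCollection] = None,
    out_dir=None,
) -> dict:
    """Run the tumor-survival branch end to end; returns the manifest dict
    with the fitted model, CV result and enrichment attached under
    ``objects``."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    if m.scale == "raw_count":
        m = filter_low_count(m)
        m = log2_normalize(m)
    model = FavorabilityStratifier(
        alpha=config.alpha,
        mode=config.mode,
        binary_covariates=tuple(config.binary_covariates),
        ordinal_or_continuous_covariates=tuple(
            config.ordinal_or_continuous_covariates),
        confounder_alpha=config.confounder_alpha,
        gene_subset=config.gene_subset,
        k=config.k,
        n_restarts=config.n_restarts,
        random_state=config.seed,
    )
    model.fit(m.values.T, surv)
    cv = cross_validate(
        m, surv, n_folds=config.n_folds, seed=config.seed,
        alpha=config.alpha,
        binary_covariates=tuple(config.binary_covariates),
        ordinal_or_continuous_covariates=tuple(
            config.ordinal_or_continuous_covariates),
        mode=config.mode, n_restarts=config.n_restarts,
    )
    if out_dir is not None:
        p = out_dir / "screen.tsv"
        model.screen_table_.to_csv(p, sep="\t")
        artifacts["screen"] = p
        p = out_dir / "favorability.tsv"
        model.favorability_.to_tsv(p, out_dir / "favorability.json")
        artifacts["favorability"] = p
        p = out_dir / "subgroups.tsv"
        model.labels_.rename("subgroup").to_csv(p, sep="\t")
        artifacts["subgroups"] = p
        if model.comparison_ is not None and model.comparison_.km_curves is not None:
            p = out_dir / "km_curves.tsv"
            model.comparison_.km_curves.to_csv(p, sep="\t", index=False)
            artifacts["km_curves"] = p
        p = out_dir / "cv_folds.tsv"
        cv.folds.to_csv(p, sep="\t", index=False)
        artifacts["cv_folds"] = p
    extras = {
        "subgroup_comparison": None if model.comparison_ is None else {
            "p_value": model.comparison_.p_value,
            "hazard_ratio": model.comparison_.hazard_ratio,
            "n_per_group": model.comparison_.n_per_group,
        },
        "cross_validation": cv.summary(),
    }
    enr = _enrich_both(model, gene_sets, m.gene_ids, config.enrich_alpha,
                       out_dir, artifacts)
    manifest = _write_manifest(out_dir, config, model.funnel_, artifacts, extras)
    manifest["objects"] = {"model": model, "cv": cv,
                           "enrichment": enr.get("enrichment")}
    return manifest


def run_cellline_workflow(
    m: ExpressionMatrix,
    panel: DoseResponsePanel,
    config: RunConfig,
    gene_sets: Optional[GeneSetCollection] = None,
    out_dir=None,
) -> dict:
    """Run the cell-line sensitivity branch end to end."""
    if config.drug is None:
        raise ValueError("config.drug is required for the cellline workflow")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    model = CellLineStratifier(
        min_cv=config.min_cv, min_tau=config.min_tau, max_p=config.max_tau_p,
        mode=config.mode, lower_q=config.lower_q, upper_q=config.upper_q,
        k=config.k, n_restarts=config.n_restarts, random_state=config.seed,
    )
    ic50 = panel.ic50[config.drug]
    try:
        model.fit(m.values.T, ic50)
        fitted = True
    except ValueError as err:
        logger.warning("cellline workflow: %s", err)
        fitted = False
    if fitted and out_dir is not None:
        p = out_dir / "screen.tsv"
        model.screen_table_.to_csv(p, sep="\t")
        artifacts["screen"] = p
        p = out_dir / "favorability.tsv"
        model.favorability_.to_tsv(p, out_dir / "favorability.json")
        artifacts["favorability"] = p
        p = out_dir / "subgroups.tsv"
        model.labels_.rename("subgroup").to_csv(p, sep="\t")
        artifacts["subgroups"] = p
    extras = {"fitted": fitted}
    enr = {}
    if fitted:
        extras["ic50_comparison"] = {
            "p_value": model.comparison_.p_value,
            "median_log_ic50_diff": model.comparison_.median_diff,
            "n_per_group": model.comparison_.n_per_group,
        }
        enr = _enrich_both(model, gene_sets, m.gene_ids, config.enrich_alpha,
                           out_dir, artifacts)
    funnel = model.funnel_ if hasattr(model, "funnel_") else {}
    manifest = _write_manifest(out_dir, config, funnel, artifacts, extras)
    manifest["objects"] = {"model": model if fitted else None,
                           "enrichment": enr.get("enrichment")}
    return manifest


def run_phenotype_workflow(
    panel: DoseResponsePanel,
    config: RunConfig,
    out_dir=None,
) -> dict:
    """Run the phenotype-correlates branch: kp/volume/kg and CORE vs
    sensitivity, plus the drug-similarity clustering."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    tables = {}
    for trait in ("kp", "volume", "kg"):
        tables[trait] = correlate_sensitivity(panel, trait)
    tables["core"] = core_vs_sensitivity(panel)
    sim = drug_similarity(panel)
    if out_dir is not None:
        for name, tab in tables.items():
            p = out_dir / f"correlations_{name}.tsv"
            tab.to_csv(p, sep="\t", index=False)
            artifacts[f"correlations_{name}"] = p
        p = out_dir / "drug_similarity.tsv"
        sim.similarity.to_csv(p, sep="\t")
        artifacts["drug_similarity"] = p
        p = out_dir / "drug_dendrogram.nwk"
        with open(p, "w") as fh:
            fh.write(sim.to_newick() + "\n")
        artifacts["drug_dendrogram"] = p
    extras = {
        "significant_per_trait": {
            name: int(tab["significant"].sum()) if len(tab) else 0
            for name, tab in tables.items()
        },
        "drug_leaf_order": sim.leaf_order,
    }
    manifest = _write_manifest(out_dir, config, {}, artifacts, extras)
    manifest["objects"] = {"tables": tables, "similarity": sim}
    return manifest
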