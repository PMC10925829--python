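"""Pipeline orchestration: run the full analysis from one config.

Stages (in execution order):

1. ``features``    shadow-feature selection per trait
2. ``models``      random-forest trait models on confirmed descriptors
3. ``projection``  trait projection onto the genotyped target panel
4. ``clustering``  z-score, outlier removal, PAM partition, diagnostics
5. ``hydraulics``  per-cluster composite anatomies and kr/Kr/Kx
6. ``gwas``        gene-level association for projected traits and for the
                   environmental descriptors the models use
7. ``pooling``     top-k candidate sets and overlap matrices
8. ``maf``         cluster-level minor-allele-frequency clines

Every stage writes CSV outputs under the run directory; a manifest records
the config hash, seed, stage order and output files so a re-run with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, envmodels, hydraulics, structure, synthetic
from .errors import ConfigError, DataError, RootclinesError
from .io_formats import (
    GeneAnnotation,
    assign_snps_to_genes,
    read_genotypes,
    read_table,
    write_table,
)

logger = logging.getLogger(__name__)

STAGES = ["features", "models", "projection", "clustering",
          "hydraulics", "gwas", "pooling", "maf"]


@dataclass
class RunConfig:
    """Input paths plus stage parameters for one run."""

    traits: str
    descriptors_train: str
    descriptors_target: str
    genotypes: str
    annotation: str
    outdir: str
    genotype_format: str = "vcf"
    variety_assignments: str | None = None
    trait_columns: list[str] = field(default_factory=lambda: list(synthetic.PRIMARY_TRAITS))
    maf_min: float = 0.01
    alpha: float = 0.01
    max_runs: int = 100
    selection_trees: int = envmodels.SELECTION_N_TREES
    n_trees: int = envmodels.DEFAULT_N_TREES
    k_clusters: int = 7
    sd_limit: float = 3.0
    n_eigen: int = assoc.DEFAULT_N_EIGENVECTORS
    window_bp: int = 2500
    top_k: int = assoc.DEFAULT_TOP_K
    var_keep: float = assoc.DEFAULT_VAR_KEEP
    n_candidate_snps: int = 5
    lp: float = hydraulics.DEFAULT_LP
    k_wall: float = hydraulics.DEFAULT_K_WALL
    mu: float = hydraulics.DEFAULT_MU
    casparian: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def validate(config: RunConfig) -> dict:
    """Check paths and parameter ranges before any stage runs."""
    problems = []
    for name in ("traits", "descriptors_train", "descriptors_target",
                 "genotypes", "annotation"):
        p = getattr(config, name)
        if not Path(p).exists():
            problems.append(f"missing input path {name}: {p}")
    if config.variety_assignments and not Path(config.variety_assignments).exists():
        problems.append(f"missing variety assignment table: {config.variety_assignments}")
    if not (0 < config.alpha < 1):
        problems.append("alpha must be in (0, 1)")
    if config.k_clusters < 2:
        problems.append("k_clusters must be >= 2")
    if config.sd_limit <= 0:
        problems.append("sd_limit must be positive")
    if config.n_trees < 1 or config.selection_trees < 1:
        problems.append("tree counts must be >= 1")
    if config.window_bp < 0:
        problems.append("window_bp must be >= 0")
    if Path(config.descriptors_target).exists():
        n_target = len(read_table(config.descriptors_target, ["accession"]))
        if config.k_clusters >= n_target:
            problems.append(f"k_clusters={config.k_clusters} >= target panel size {n_target}")
    if problems:
        raise ConfigError("; ".join(problems))
    return {"ok": True, "config_hash": config.content_hash()}


@dataclass
class PipelineState:
    config: RunConfig
    outdir: Path
    traits: pd.DataFrame = None
    descriptors_train: pd.DataFrame = None
    descriptors_target: pd.DataFrame = None
    genotypes: object = None
    annotation: GeneAnnotation = None
    selections: dict = None
    models: list = None
    projection: envmodels.ProjectionResult = None
    cluster_model: structure.ClusterModel = None
    kinship: assoc.Kinship = None
    gene_tables: list = None
    candidate_sets: dict = None
    counts: dict = field(default_factory=dict)


def _load_inputs(state: PipelineState) -> None:
    cfg = state.config
    state.traits = read_table(cfg.traits, schema=["accession"])
    state.descriptors_train = read_table(cfg.descriptors_train, schema=["accession"])
    state.descriptors_target = read_table(cfg.descriptors_target, schema=["accession"])
    state.genotypes = read_genotypes(cfg.genotypes, format=cfg.genotype_format,
                                     maf_min=cfg.maf_min)
    state.annotation = GeneAnnotation.from_gff3(cfg.annotation, window_bp=cfg.window_bp)
    state.counts["n_train"] = len(state.descriptors_train)
    state.counts["n_target"] = len(state.descriptors_target)
    state.counts["n_snps"] = state.genotypes.n_snps
    state.counts["n_genes"] = state.annotation.n_genes


def stage_features(state: PipelineState) -> None:
    cfg = state.config
    traits = [t for t in cfg.trait_columns if t in state.traits.columns]
    if not traits:
        raise DataError("no requested trait columns present in the trait table")
    state.selections = envmodels.select_features(
        state.traits, state.descriptors_train, trait_columns=traits,
        alpha=cfg.alpha, max_runs=cfg.max_runs,
        n_trees=cfg.selection_trees, seed=cfg.seed)
    rows = [{"trait": t, "decision": dec, "descriptor": f}
            for t, sel in state.selections.items()
            for dec, fs in (("confirmed", sel.confirmed), ("rejected", sel.rejected),
                            ("tentative", sel.tentative))
            for f in fs]
    write_table(pd.DataFrame(rows), state.outdir / "feature_selection.csv")
    state.counts["n_modeled_traits"] = sum(
        1 for s in state.selections.values() if s.confirmed)


def stage_models(state: PipelineState) -> None:
    cfg = state.config
    merged = state.traits.merge(state.descriptors_train, on="accession")
    state.models = []
    skipped = []
    for t, sel in state.selections.items():
        if not sel.confirmed:
            skipped.append(t)
            continue
        m = envmodels.fit_trait_model(merged[t].to_numpy(float), merged, sel,
                                      trait=t, n_trees=cfg.n_trees, seed=cfg.seed)
        state.models.append(m)
    if not state.models:
        raise DataError("no trait could be modeled (all confirmed sets empty)")
    rows = [{"trait": m.trait, "n_descriptors": len(m.descriptors),
             "n_trees": m.n_trees, "split_candidates": m.split_candidates,
             "oob_r2": m.oob_r2, "fit_r": m.fit_r} for m in state.models]
    write_table(pd.DataFrame(rows), state.outdir / "trait_models.csv")
    envmodels.save_models(state.models, state.outdir / "trait_models.joblib")
    state.counts["n_skipped_traits"] = len(skipped)
    if skipped:
        logger.info("traits not modeled (empty confirmed set): %s", skipped)


def stage_projection(state: PipelineState) -> None:
    state.projection = envmodels.project(state.models, state.descriptors_target)
    out = state.projection.values.copy()
    out.insert(0, "accession", out.index)
    write_table(out, state.outdir / "projected_traits.csv")
    extrap = state.projection.extrapolation
    n_flag = int(extrap.any(axis=1).sum())
    state.counts["n_extrapolated_accessions"] = n_flag
    flagged = extrap[extrap.any(axis=1)]
    sidecar = flagged.reset_index(names="accession")
    write_table(sidecar, state.outdir / "extrapolation_report.csv")


def stage_clustering(state: PipelineState) -> None:
    cfg = state.config
    z, removed = structure.standardize_and_filter(
        state.projection.values.reset_index(names="accession"),
        sd_limit=cfg.sd_limit)
    model = structure.pam_cluster(z, cfg.k_clusters, seed=cfg.seed,
                                  removed_outliers=removed)
    state.cluster_model = model
    lab = model.labels.reset_index()
    lab.columns = ["accession", "cluster"]
    write_table(lab, state.outdir / "cluster_labels.csv")
    wss = structure.wss_curve(z, range(1, min(11, len(z))))
    wss_df = wss.rename_axis("k").reset_index()
    write_table(wss_df, state.outdir / "wss_curve.csv")
    diag = pd.DataFrame([{"k": model.k, "silhouette": model.silhouette,
                          "total_cost": model.total_cost, "wss": model.wss,
                          "n_removed_outliers": len(removed)}])
    write_table(diag, state.outdir / "cluster_diagnostics.csv")
    state.counts["n_outliers_removed"] = len(removed)
    if cfg.variety_assignments:
        var = read_table(cfg.variety_assignments, schema=["accession", "variety"])
        enr = structure.variety_enrichment(
            model.labels, var.set_index("accession")["variety"])
        write_table(enr, state.outdir / "variety_enrichment.csv")


def stage_hydraulics(state: PipelineState) -> None:
    cfg = state.config
    hyd = hydraulics.HydraulicParams(lp=cfg.lp, k_wall=cfg.k_wall, mu=cfg.mu,
                                     casparian=cfg.casparian)
    train_means = {c: float(state.traits[c].mean())
                   for c in state.traits.columns if c != "accession"}
    comp = hydraulics.cluster_composite(state.projection.values,
                                        state.cluster_model.labels,
                                        training_means=train_means, hyd=hyd,
                                        render_dir=state.outdir / "cross_sections")
    write_table(comp, state.outdir / "cluster_hydraulics.csv")
    state.counts["n_clusters"] = len(comp)


def stage_gwas(state: PipelineState) -> None:
    cfg = state.config
    genos = state.genotypes.subset_accessions(
        state.descriptors_target["accession"].tolist())
    state.kinship = assoc.compute_kinship(genos, n_eigen=cfg.n_eigen)
    snp_map = assign_snps_to_genes(genos, state.annotation)
    state.counts["n_genes_with_snps"] = snp_map.pairs["gene_id"].nunique()
    tables = []
    target = state.descriptors_target.set_index("accession")
    for m in state.models:
        y = state.projection.values[m.trait].to_numpy(float)
        design = assoc.make_design(y, state.kinship, analysis="prediction",
                                   trait=m.trait)
        tables.append(assoc.gene_level_test(genos, design, snp_map,
                                            var_keep=cfg.var_keep))
    used = sorted({f for m in state.models for f in m.descriptors})
    for name in used:
        y = target.loc[genos.accessions, name].to_numpy(float)
        design = assoc.make_design(y, state.kinship, analysis="environment",
                                   trait=name)
        tables.append(assoc.gene_level_test(genos, design, snp_map,
                                            var_keep=cfg.var_keep))
    state.gene_tables = tables
    write_table(pd.concat(tables, ignore_index=True),
                state.outdir / "gene_associations.csv")
    state.counts["n_gene_tests"] = sum(len(t) for t in tables)


def stage_pooling(state: PipelineState) -> None:
    cfg = state.config
    sets, overlap = assoc.pool_candidates(state.gene_tables, k=cfg.top_k)
    state.candidate_sets = sets
    rows = [{"analysis": a, "trait": t, "gene_id": g}
            for a, cs in sets.items() for t, genes in cs.per_trait.items()
            for g in genes]
    write_table(pd.DataFrame(rows), state.outdir / "candidate_genes.csv")
    write_table(overlap.counts.reset_index(names="analysis"),
                state.outdir / "overlap_counts.csv")
    write_table(overlap.row_percent.reset_index(names="analysis"),
                state.outdir / "overlap_percent.csv")
    state.counts.update({f"candidates_{a}": len(cs.pooled) for a, cs in sets.items()})


def stage_maf(state: PipelineState) -> None:
    cfg = state.config
    genos = state.genotypes.subset_accessions(
        state.descriptors_target["accession"].tolist())
    pred_tables = [t for t in state.gene_tables
                   if t["analysis"].iloc[0] == "prediction"]
    pooled = pd.concat(pred_tables).sort_values(["p", "gene_id"])
    top_genes = pooled["gene_id"].head(cfg.n_candidate_snps * 3).tolist()
    snp_map = assign_snps_to_genes(genos, state.annotation)
    pairs = snp_map.pairs[snp_map.pairs["gene_id"].isin(top_genes)]
    # best SNP per top gene, by the marginal projected-trait association
    m0 = state.models[0]
    y = state.projection.values[m0.trait].to_numpy(float)
    design = assoc.make_design(y, state.kinship, analysis="prediction", trait=m0.trait)
    snp_stats = assoc.snp_association(design, genos).set_index("snp_id")
    cands = []
    for g in top_genes:
        snps = pairs.loc[pairs["gene_id"] == g, "snp_id"]
        snps = [s for s in snps if s in snp_stats.index]
        if snps:
            best = snp_stats.loc[snps, "p"].idxmin()
            if best not in cands:
                cands.append(best)
        if len(cands) >= cfg.n_candidate_snps:
            break
    if not cands:
        raise DataError("no candidate SNPs found for MAF profiling")
    elev = state.descriptors_target.set_index("accession")["elevation"] \
        if "elevation" in state.descriptors_target.columns else None
    if elev is None:
        raise DataError("target descriptors lack an elevation column")
    prof = assoc.cluster_maf_profile(genos, state.cluster_model.labels, elev,
                                     state.projection.values, cands)
    write_table(prof.profile, state.outdir / "cluster_maf_profile.csv")
    write_table(prof.correlations, state.outdir / "maf_correlations.csv")
    state.counts["n_candidate_snps"] = len(cands)


_STAGE_FUNCS = {
    "features": stage_features, "models": stage_models,
    "projection": stage_projection, "clustering": stage_clustering,
    "hydraulics": stage_hydraulics, "gwas": stage_gwas,
    "pooling": stage_pooling, "maf": stage_maf,
}


def run_full(config: RunConfig) -> dict:
    """Execute every stage in order and write the run manifest.

    On stage failure the manifest is still written under a ``failed``
    marker naming the stage and the error.
    """
    validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config=config, outdir=outdir)
    _load_inputs(state)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
        "counts": state.counts,
        "outputs": {},
    }
    try:
        for name in STAGES:
            t0 = time.time()
            _STAGE_FUNCS[name](state)
            manifest["stages"].append(name)
            logger.info("stage %s done (%.1f s)", name, time.time() - t0)
    except RootclinesError as exc:
        manifest["failed"] = {"stage": name, "error": type(exc).__name__,
                              "message": str(exc), "exit_code": exc.exit_code}
        _write_manifest(manifest, state, outdir)
        raise
    _write_manifest(manifest, state, outdir)
    return manifest


def _write_manifest(manifest: dict, state: PipelineState, outdir: Path) -> None:
    outputs = {}
    for f in sorted(outdir.glob("*.csv")):
        outputs[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    manifest["outputs"] = outputs
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps({k: manifest[k] for k in ("config_hash", "seed", "stages", "outputs")},
                   sort_keys=True).encode()).hexdigest()[:16]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate(sim_config: synthetic.SimConfig, outdir) -> dict:
    """Generate a synthetic study on disk and a matching run config."""
    study = synthetic.simulate_study(sim_config)
    paths = synthetic.write_study(study, outdir)
    run_cfg = RunConfig(
        traits=paths["traits"],
        descriptors_train=paths["descriptors_train"],
        descriptors_target=paths["descriptors_target"],
        genotypes=paths["genotypes_vcf"],
        annotation=paths["annotation"],
        outdir=str(Path(outdir) / "results"),
        seed=sim_config.seed,
    )
    cfg_path = Path(outdir) / "run_config.yaml"
    run_cfg.to_yaml(cfg_path)
    paths["run_config"] = str(cfg_path)
    return paths
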