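"""End-to-end orchestration of the five tissue x phenotype analyses.

A single config (YAML file or dict) names either on-disk CGmap/phenotype/
pedigree inputs or a ``simulate`` block, plus the analysis roster and all
thresholds (coverage 10x, beta percentiles 1/99, p percentile 1, cluster gap
< 40 bp, >= 3 sites for network input, 2 kb promoters, edge confidence 0.7,
BH FDR 0.05 — every one overridable).  ``run_pipeline`` executes QC,
association, DMS selection, clustering, annotation, enrichment, and network
assembly per analysis, writes one output bundle per analysis plus a run
manifest echoing every threshold, and is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_clusters,
    annotate_sites,
    annotation_proportions,
    build_feature_index,
)
from .bmm import AssociationConfig, MethylationAssociation
from .cgmap import (
    conversion_efficiency,
    context_summary,
    filter_coverage,
    methylation_frequency,
    read_cgmap,
    unite,
)
from .dms import call_dmclusters, overlap_sets, select_outliers, write_venn_json
from .enrich import build_network, enrichment_with_fdr, read_edge_list, read_gmt
from .errors import InvalidConfigError, PipelineError
from .pedigree import additive_relationship, read_pedigree
from .qc import pca_methylation, screen_pcs
from .samples import read_samples_table
from .simulate import (
    LAMBDA_CHROM,
    SimulationConfig,
    reference_design,
    simulate_annotation,
    simulate_dataset,
    simulate_gene_sets,
    simulate_interactions,
    simulate_pedigree,
)

logger = logging.getLogger(__name__)

DEFAULT_ANALYSES = [
    {"tissue": "Blood", "predictor": "avg_litter_size"},
    {"tissue": "Testes", "predictor": "avg_litter_size"},
    {"tissue": "Sperm", "predictor": "avg_litter_size"},
    {"tissue": "Sperm", "predictor": "sperm_count_per_ml"},
    {"tissue": "Testes", "predictor": "testes_firmness"},
]

PREDICTOR_TISSUE = {
    "avg_litter_size": {"Blood", "Testes", "Sperm"},
    "sperm_count_per_ml": {"Sperm"},
    "testes_firmness": {"Testes"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings with the study thresholds as defaults."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None
    cgmap_paths: dict[str, str] = field(default_factory=dict)
    samples_table: str | None = None
    pedigree: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    edges: str | None = None
    analyses: list[dict] = field(default_factory=lambda: list(DEFAULT_ANALYSES))
    min_coverage: int = 10
    beta_quantiles: tuple[float, float] = (0.01, 0.99)
    p_quantile: float = 0.01
    max_gap: int = 40
    min_cluster_sites: int = 3
    promoter_length: int = 2000
    min_confidence: float = 0.7
    fdr: float = 0.05
    control_chrom: str = LAMBDA_CHROM
    use_kinship: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.beta_quantiles, list):
            cfg.beta_quantiles = tuple(cfg.beta_quantiles)
        return cfg

    def thresholds(self) -> dict:
        return {
            "min_coverage": self.min_coverage,
            "beta_quantiles": list(self.beta_quantiles),
            "p_quantile": self.p_quantile,
            "max_gap": self.max_gap,
            "min_cluster_sites": self.min_cluster_sites,
            "promoter_length": self.promoter_length,
            "min_confidence": self.min_confidence,
            "fdr": self.fdr,
        }


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of validation errors (empty when the config is usable)."""
    errors: list[str] = []
    simulated = config.simulate is not None
    if not simulated:
        if not config.cgmap_paths:
            errors.append("no CGmap inputs and no simulate block")
        for sid, path in config.cgmap_paths.items():
            if not Path(path).exists():
                errors.append(f"CGmap for {sid} missing: {path}")
        for name in ("samples_table", "pedigree"):
            path = getattr(config, name)
            if path is None:
                errors.append(f"{name} path required without a simulate block")
            elif not Path(path).exists():
                errors.append(f"{name} missing: {path}")
    if config.use_kinship and not simulated and config.pedigree is None:
        errors.append("kinship enabled but no pedigree supplied")
    for item in config.analyses:
        tissue, predictor = item.get("tissue"), item.get("predictor")
        allowed = PREDICTOR_TISSUE.get(predictor)
        if allowed is None:
            errors.append(f"unknown predictor {predictor!r}")
        elif tissue not in allowed:
            errors.append(f"predictor {predictor!r} is undefined for {tissue!r}")
    for name in ("annotation", "gene_sets", "edges"):
        path = getattr(config, name)
        if path is not None and not simulated and not Path(path).exists():
            errors.append(f"{name} missing: {path}")
    if not (0 < config.p_quantile < 1):
        errors.append("p_quantile must be in (0, 1)")
    return errors


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Materialise methylomes, phenotypes, pedigree, and annotation inputs."""
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        ped_spec = sim_kwargs.pop("pedigree", {"n_founders": 4, "n_generations": 2})
        design_name = sim_kwargs.pop("design", None)
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        ped = simulate_pedigree(
            ped_spec.get("n_founders", 4),
            ped_spec.get("n_generations", 2),
            seed=sim_cfg.seed,
            offspring_per_generation=ped_spec.get("offspring_per_generation"),
        )
        design = None
        if design_name == "reference":
            individuals = list(ped["id"])[-sim_cfg.n_individuals:]
            design = reference_design(individuals)
        dataset = simulate_dataset(sim_cfg, ped, design=design)
        methylomes = dataset.methylomes
        phenotypes = dataset.phenotypes
        pedigree = dataset.pedigree
        gff_text, gene_ids = simulate_annotation(sim_cfg)
        ann_path = outdir / "simulated_annotation.gff3"
        ann_path.write_text(gff_text)
        gmt_path = outdir / "simulated_gene_sets.gmt"
        gmt_path.write_text(simulate_gene_sets(gene_ids, 20, sim_cfg.seed))
        edge_path = outdir / "simulated_edges.tsv"
        simulate_interactions(gene_ids, sim_cfg.seed).to_csv(
            edge_path, sep="\t", index=False
        )
        return methylomes, phenotypes, pedigree, str(ann_path), str(gmt_path), str(edge_path)

    methylomes = {sid: read_cgmap(path) for sid, path in config.cgmap_paths.items()}
    phenotypes = read_samples_table(config.samples_table)
    pedigree = read_pedigree(config.pedigree) if config.pedigree else None
    return (
        methylomes,
        phenotypes,
        pedigree,
        config.annotation,
        config.gene_sets,
        config.edges,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured analyses; returns the run manifest."""
    errors = validate_config(config)
    if errors:
        raise InvalidConfigError("; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages": [],
        "analyses": {},
    }

    def stage(name: str, **info):
        manifest["stages"].append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    try:
        methylomes, phenotypes, pedigree, ann_path, gmt_path, edge_path = _load_inputs(
            config, outdir
        )
        stage("load", n_samples=len(methylomes))

        # per-sample conversion efficiency and CG-only coverage filtering
        efficiencies: dict[str, float] = {}
        cg_filtered: dict[str, pd.DataFrame] = {}
        for sid, meth in methylomes.items():
            try:
                efficiencies[sid] = conversion_efficiency(meth, config.control_chrom)
            except ValueError:
                efficiencies[sid] = float("nan")
            summary = context_summary(meth)
            cg = summary["cg_only"]
            cg = cg[cg["chrom"] != config.control_chrom]
            n_before = cg.shape[0]
            cg = filter_coverage(cg, config.min_coverage)
            cg_filtered[sid] = cg
            stage(
                "filter",
                sample=sid,
                sites_in=n_before,
                sites_out=int(cg.shape[0]),
                conversion_efficiency=efficiencies[sid],
            )

        # QC on the full united matrix
        matrix_all = unite(cg_filtered)
        qc_report: dict = {
            "conversion_efficiency": efficiencies,
            "n_united_sites": int(matrix_all.n_sites),
        }
        if matrix_all.n_sites >= 2 and matrix_all.n_samples >= 2:
            mf_all = methylation_frequency(matrix_all)
            pca = pca_methylation(mf_all)
            pheno_idx = phenotypes.set_index("sample_id").loc[matrix_all.samples]
            kinds = {"tissue": "categorical", "age_at_sampling": "continuous"}
            screen = screen_pcs(pca, pheno_idx, kinds)
            qc_report["pc_screen"] = screen.to_dict(orient="records")
            qc_report["explained_variance_ratio"] = [
                float(v) for v in pca.explained_variance_ratio[:5]
            ]
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=2, default=str)
        stage("qc", n_united_sites=int(matrix_all.n_sites))

        index = build_feature_index(
            ann_path, promoter_length=config.promoter_length
        ) if ann_path else None
        collection = read_gmt(gmt_path) if gmt_path else None
        edges = read_edge_list(edge_path) if edge_path else None

        kin = None
        if config.use_kinship and pedigree is not None:
            A = additive_relationship(pedigree)
            kin = A

        dms_by_label: dict[str, set] = {}
        enrich_by_label: dict[str, pd.DataFrame] = {}
        for item in config.analyses:
            tissue, predictor = item["tissue"], item["predictor"]
            label = item.get("label", f"{tissue.lower()}_{predictor}")
            adir = outdir / label
            adir.mkdir(exist_ok=True)

            samples = list(
                phenotypes.loc[phenotypes["tissue"] == tissue, "sample_id"]
            )
            if not samples:
                raise PipelineError(f"analysis {label}: no {tissue} samples")
            matrix = unite({s: cg_filtered[s] for s in samples})
            stage("unite", analysis=label, n_sites=int(matrix.n_sites),
                  n_samples=len(samples))

            sample_kin = None
            if kin is not None:
                ind_of = dict(
                    zip(phenotypes["sample_id"], phenotypes["studbook_no"])
                )
                sample_kin = kin.for_samples(
                    {s: ind_of[s] for s in samples}
                )
            scan = MethylationAssociation(
                matrix,
                phenotypes,
                kinship=sample_kin,
                config=AssociationConfig(
                    predictor=predictor, use_kinship=config.use_kinship
                ),
            ).fit()
            scan.to_tsv(adir / "association.tsv")
            stage("associate", analysis=label,
                  inflation=scan.inflation_factor(),
                  n_fitted=int(scan.fitted.shape[0]))

            dms = select_outliers(
                scan.table, label=label,
                beta_q=config.beta_quantiles, p_q=config.p_quantile,
            )
            dms.to_bed(adir / "dms.bed")
            dms_by_label[label] = dms.site_keys()
            clusters = call_dmclusters(
                dms, max_gap=config.max_gap, min_sites=config.min_cluster_sites
            )
            clusters.to_bed(adir / "clusters.bed")
            stage("select", analysis=label, n_dms=len(dms),
                  n_clusters=len(clusters.clusters),
                  n_network_clusters=len(clusters.network_subset))

            analysis_info = {
                "tissue": tissue,
                "predictor": predictor,
                "n_sites": int(matrix.n_sites),
                "n_dms": len(dms),
                "n_clusters": len(clusters.clusters),
                "n_network_clusters": len(clusters.network_subset),
            }

            if index is not None:
                annotated = annotate_sites(dms.sites, index)
                annotated.to_csv(adir / "annotation.tsv", sep="\t", index=False)
                analysis_info["annotation_proportions"] = annotation_proportions(
                    annotated
                ) if len(annotated) else {}
                cluster_genes, n_excluded = annotate_clusters(
                    clusters.network_subset, index
                )
                seed_genes = sorted({g for _, gs in cluster_genes for g in gs})
                analysis_info["n_intergenic_clusters"] = n_excluded
                analysis_info["n_seed_genes"] = len(seed_genes)

                if collection is not None and seed_genes:
                    usable = [g for g in seed_genes if g in collection.universe]
                    if usable:
                        table = enrichment_with_fdr(usable, collection, fdr=config.fdr)
                        table.to_csv(
                            adir / "enrichment.tsv", sep="\t", index=False,
                            float_format="%.6g",
                        )
                        enrich_by_label[label] = table
                        analysis_info["n_significant_terms"] = int(
                            table["significant"].sum()
                        )
                if edges is not None and seed_genes:
                    net = build_network(
                        edges, seed_genes, min_confidence=config.min_confidence
                    )
                    net.to_json(adir / "network.json")
                    analysis_info["n_interactors"] = len(net.interactors)
            manifest["analyses"][label] = analysis_info

        # cross-analysis overlaps for the litter-size roster
        litter_labels = [
            item.get("label", f"{item['tissue'].lower()}_{item['predictor']}")
            for item in config.analyses
            if item["predictor"] == "avg_litter_size"
        ]
        litter_labels = [lab for lab in litter_labels if lab in dms_by_label]
        if len(litter_labels) >= 2:
            venn = overlap_sets({lab: dms_by_label[lab] for lab in litter_labels[:3]})
            write_venn_json(venn, outdir / "dms_overlap.json")
            manifest["dms_overlap"] = venn
            shared_terms = None
            if all(lab in enrich_by_label for lab in litter_labels[:3]):
                term_sets = {
                    lab: set(
                        enrich_by_label[lab].loc[
                            enrich_by_label[lab]["significant"], "term"
                        ]
                    )
                    for lab in litter_labels[:3]
                }
                shared_terms = overlap_sets(term_sets)
                write_venn_json(shared_terms, outdir / "term_overlap.json")
                manifest["term_overlap"] = shared_terms
            stage("overlap", n_analyses=len(litter_labels))
    except Exception as exc:
        manifest["error"] = {"stage": "run", "message": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
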