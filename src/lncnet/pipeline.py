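"""End-to-end orchestration: preprocess -> DE -> clinical association ->
relevance -> correlation -> cis -> networks -> master regulators ->
phenotype-unique lncRNAs -> enrichment.

``run_pipeline`` works on in-memory objects and returns every
intermediate table plus a count summary; ``run_all`` is the file-based
wrapper that reads a RunConfig, writes one file per stage into a run
directory, and is byte-reproducible for identical inputs and config.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import clinical as clin
from . import coexpression as coexpr
from . import network as net
from .de import run_de
from .enrichment import run_ora
from .errors import ConfigError
from .io import (
    ExpressionMatrix,
    read_bed,
    read_clinical,
    read_expression,
    read_gmt,
    write_expression,
    write_json,
    write_sif,
)
from .preprocessing import filter_detected, quantile_normalize

logger = logging.getLogger("lncnet.pipeline")


@dataclass
class RunConfig:
    expression: str = ""
    design: str = ""
    clinical: str = ""
    annotation: str = ""
    gene_sets: str = ""
    flags: str | None = None

    fc_de: float = 2.0
    fdr_de: float = 0.05
    fc_clin: float = 1.5
    p_clin: float = 0.05
    r_strong: float = 0.9
    r_weak: float = 0.6
    alpha_enrich: float = 0.01
    min_mrna: int = 20
    concordance_min: float = 0.8

    detection_min_fraction: float = 0.5
    detection_strict: bool = False
    normalize: bool = True
    corr_samples: str = "all"  # all | tumor
    seed: int = 0

    def validate(self) -> None:
        for name in ("fc_de", "fdr_de", "fc_clin", "p_clin", "alpha_enrich",
                     "concordance_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("r_strong", "r_weak"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.detection_min_fraction <= 1.0:
            raise ConfigError("detection_min_fraction must be in [0, 1]")
        if self.min_mrna < 1:
            raise ConfigError("min_mrna must be positive")
        if self.corr_samples not in ("all", "tumor"):
            raise ConfigError("corr_samples must be 'all' or 'tumor'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    filtered: ExpressionMatrix
    normalized: ExpressionMatrix
    de: pd.DataFrame
    phenotypes: pd.DataFrame
    assoc: pd.DataFrame
    relevance: pd.DataFrame
    pairs: pd.DataFrame
    components: list
    enrichments: list
    unique_map: dict
    unique_sets: dict
    summary: dict = field(default_factory=dict)


def run_pipeline(
    expression: ExpressionMatrix,
    design: pd.DataFrame,
    clinical_table: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_sets: dict,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and summarize the counts."""
    cfg = config or RunConfig()
    cfg.validate()

    # --- preprocessing
    if expression.flags is not None:
        filtered = filter_detected(
            expression, cfg.detection_min_fraction, strict=cfg.detection_strict
        )
    else:
        logger.info("no detection flags; skipping detection filter")
        filtered = expression
    normalized = quantile_normalize(filtered) if cfg.normalize else filtered
    logger.info("preprocess: %d/%d features kept", len(filtered.feature_ids),
                len(expression.feature_ids))

    biotype = annotation.set_index("feature_id")["biotype"]
    bt = biotype.reindex(normalized.values.index)

    # --- differential expression (joint BH family across biotypes)
    de = run_de(normalized, design, fc_threshold=cfg.fc_de, fdr_threshold=cfg.fdr_de)
    de = de.merge(
        bt.rename("biotype"), left_on="feature_id", right_index=True, how="left"
    )
    de_lnc = de[(de["biotype"] == "lncRNA") & de["is_de"]]
    de_mrna = de[(de["biotype"] == "protein_coding") & de["is_de"]]
    logger.info("DE: %d lncRNAs, %d mRNAs", len(de_lnc), len(de_mrna))

    # --- clinical association on DE features only (tumor samples)
    phenotypes = clin.dichotomize(clinical_table)
    de_ids = pd.concat([de_lnc, de_mrna])["feature_id"].tolist()
    assoc = clin.associate(
        normalized, design, phenotypes, features=de_ids,
        fc_threshold=cfg.fc_clin, p_threshold=cfg.p_clin,
    )
    relevance = clin.classify_relevance(de[de["feature_id"].isin(de_ids)], assoc)

    # --- co-expression and cis annotation
    if cfg.corr_samples == "tumor":
        from .io import tumor_sample_map

        sample_ids = list(tumor_sample_map(design).values())
    else:
        sample_ids = None
    pairs = coexpr.call_pairs(
        normalized, de_lnc, de_mrna, threshold=cfg.r_strong, sample_ids=sample_ids
    )
    pairs = coexpr.annotate_cis(pairs, annotation)

    # --- networks, enrichment, master regulators
    components = net.build_network(pairs, relevance)
    universe = sorted(
        set(normalized.values.index[(bt == "protein_coding").to_numpy()])
        & set().union(*gene_sets.values())
    ) if gene_sets else []
    enrichments = []
    for comp in components:
        enr = (
            run_ora(comp.mrna_ids, gene_sets, universe, alpha=cfg.alpha_enrich)
            if universe
            else pd.DataFrame(columns=["set_name", "k", "K", "n", "N", "p", "significant"])
        )
        comp.enriched_sets = enr.loc[enr["significant"], "set_name"].tolist()
        comp.master_set = net.find_master_regulators(
            comp,
            min_mrna=cfg.min_mrna,
            concordance_min=cfg.concordance_min,
            enrichment=enr if not enr.empty else None,
        )
        enrichments.append(enr)

    # --- phenotype-unique lncRNAs
    lnc_ids = set(annotation.loc[annotation["biotype"] == "lncRNA", "feature_id"])
    unique_map = net.phenotype_unique(relevance, lnc_ids=lnc_ids)
    unique_sets = net.unique_phenotype_gene_sets(unique_map, pairs, de)

    summary = _summarize(
        cfg, expression, filtered, de, de_lnc, de_mrna, relevance, pairs,
        components, unique_map,
    )
    return PipelineResult(
        filtered, normalized, de, phenotypes, assoc, relevance, pairs,
        components, enrichments, unique_map, unique_sets, summary,
    )


def _summarize(cfg, expression, filtered, de, de_lnc, de_mrna, relevance,
               pairs, components, unique_map) -> dict:
    rel_lnc = relevance[relevance["feature_id"].isin(set(de_lnc["feature_id"]))]
    cls_counts = rel_lnc["cls"].value_counts().to_dict()
    comp_cls = pd.Series([c.cls for c in components]).value_counts().to_dict()
    overall = net.overall_concordance(components)
    return {
        "config": asdict(cfg),
        "n_features_input": len(expression.feature_ids),
        "n_features_filtered": len(filtered.feature_ids),
        "n_samples": len(expression.sample_ids),
        "de": {
            "lncRNA": {
                "up": int((de_lnc["direction"] == "up").sum()),
                "down": int((de_lnc["direction"] == "down").sum()),
                "total": int(len(de_lnc)),
            },
            "protein_coding": {
                "up": int((de_mrna["direction"] == "up").sum()),
                "down": int((de_mrna["direction"] == "down").sum()),
                "total": int(len(de_mrna)),
            },
        },
        "n_pairs": int(len(pairs)),
        "n_cis_pairs": int(pairs["is_cis"].fillna(False).astype(bool).sum()) if len(pairs) else 0,
        "relevant_lnc": {
            "oncogenic": int(cls_counts.get("oncogenic", 0)),
            "suppressor": int(cls_counts.get("suppressor", 0)),
            "total": int(cls_counts.get("oncogenic", 0) + cls_counts.get("suppressor", 0)),
        },
        "components": {
            "total": len(components),
            "oncogenic": int(comp_cls.get("oncogenic", 0)),
            "suppressive": int(comp_cls.get("suppressive", 0)),
            "mixed": int(comp_cls.get("mixed", 0)),
            "per_component": [
                {
                    "lnc_ids": c.lnc_ids,
                    "mrna_ids": c.mrna_ids,
                    "cls": c.cls,
                    "n_edges": int(len(c.edges)),
                    "concordance": round(c.concordance, 6),
                    "master_set": c.master_set,
                    "enriched_sets": c.enriched_sets,
                }
                for c in components
            ],
        },
        "overall_concordance": None if pd.isna(overall) else round(overall, 6),
        "phenotype_unique_lnc": {g: v for g, v in unique_map.items()},
    }


def run_all(config: RunConfig, outdir) -> dict:
    """File-based pipeline run; every intermediate is written to ``outdir``."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lncnet")
    root.addHandler(handler)
    try:
        stage = "read_inputs"
        try:
            expression, design = read_expression(
                config.expression, config.design, flags_path=config.flags, paired=True
            )
            clinical_table = read_clinical(config.clinical)
            annotation = read_bed(config.annotation)
            gene_sets = read_gmt(config.gene_sets) if config.gene_sets else {}
            stage = "pipeline"
            result = run_pipeline(
                expression, design, clinical_table, annotation, gene_sets, config
            )
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

        write_expression(result.normalized, os.path.join(outdir, "normalized.tsv"))
        result.de.to_csv(os.path.join(outdir, "de.tsv"), sep="\t", index=False)
        result.phenotypes.to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False)
        result.assoc.to_csv(os.path.join(outdir, "clinical_assoc.tsv"), sep="\t", index=False)
        result.relevance.to_csv(os.path.join(outdir, "relevance.tsv"), sep="\t", index=False)
        result.pairs.to_csv(os.path.join(outdir, "pairs.tsv"), sep="\t", index=False)
        comp_rows = []
        for i, comp in enumerate(result.components):
            for node in comp.lnc_ids + comp.mrna_ids:
                comp_rows.append(
                    {
                        "component": i,
                        "feature_id": node,
                        "role": "lncRNA" if node in comp.lnc_ids else "mRNA",
                        "cls": comp.cls,
                        "concordance": round(comp.concordance, 6),
                    }
                )
            write_sif(
                list(zip(comp.edges["lnc_id"], comp.edges["mrna_id"])),
                os.path.join(outdir, f"component_{i:03d}.sif"),
            )
            result.enrichments[i].to_csv(
                os.path.join(outdir, f"enrichment_{i:03d}.tsv"), sep="\t", index=False
            )
        pd.DataFrame(
            comp_rows,
            columns=["component", "feature_id", "role", "cls", "concordance"],
        ).to_csv(os.path.join(outdir, "components.tsv"), sep="\t", index=False)
        write_json(
            {
                "master_regulators": [
                    {"component": i, "cls": c.cls, "master_set": c.master_set}
                    for i, c in enumerate(result.components)
                ]
            },
            os.path.join(outdir, "master_regulators.json"),
        )
        write_json(result.unique_sets, os.path.join(outdir, "phenotype_unique_genes.json"))
        write_json(result.summary, os.path.join(outdir, "summary.json"))
        return result.summary
    finally:
        root.removeHandler(handler)
        handler.close()
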