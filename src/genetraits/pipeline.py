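"""End-to-end orchestration of the analysis stages.

``run_all`` executes: (optional) simulate -> reference build -> gene traits
-> differential expression -> summaries -> pathway associations, writing
every stage's table under one artifact directory together with a resolved
copy of the configuration and a manifest of input hashes, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, de, io, reference, simulate, traits

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the analysis defaults."""

    outdir: str = "results/pipeline"
    # inputs; empty means "simulate a community first"
    cds_fasta: str = ""
    annotations_tsv: str = ""
    depths_tsv: str = ""
    counts_tsv: str = ""
    design_tsv: str = ""
    # analysis parameters
    reference_rank: str = "species"     # species | phylum (needs taxon->phylum map)
    pseudocount: float = 0.5
    min_codons: int = traits.MIN_GENE_CODONS
    min_taxon_codons: float = reference.MIN_TAXON_CODONS
    fdr_threshold: float = de.FDR_THRESHOLD
    control_level: str = "control"
    treatment_level: str = "treatment"
    weighting: str = "rna"              # rna | dna weighting of community summaries
    pathways: tuple[str, ...] = (simulate.GROWTH, simulate.STRESS)
    predictor: str = "fop"
    seed: int = 0
    simulate_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "inputs": {}, "stages": {}}
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    # --- stage: inputs (simulated or loaded) ------------------------------
    if config.cds_fasta:
        for key in ("cds_fasta", "annotations_tsv", "depths_tsv",
                    "counts_tsv", "design_tsv"):
            p = Path(getattr(config, key))
            if not p.exists():
                raise FileNotFoundError(f"stage inputs: missing {key}: {p}")
            manifest["inputs"][key] = _sha256(p)
        seqs = io.read_fasta(config.cds_fasta)
        ann = io.read_annotations(config.annotations_tsv)
        depths = io.read_depths(config.depths_tsv)
        genes = io.assemble_genes(seqs, ann, depths)
        cm = io.read_counts(config.counts_tsv, config.design_tsv)
        truth = None
    else:
        sim_cfg = simulate.GeneratorConfig(seed=config.seed,
                                           **config.simulate_config)
        genes, truth, cm = simulate.generate_community(sim_cfg)
        simulate.write_community(outdir / "simulated", genes, truth, cm)
        manifest["stages"]["simulate"] = {"n_genes": len(genes)}
    log.info("inputs: %d genes, %d samples", len(genes), cm.counts.shape[1])

    # --- stage: references ------------------------------------------------
    tables = reference.accumulate_counts(genes, depth_weighted=True)
    kept = reference.filter_taxa(tables, config.min_taxon_codons)
    refs = reference.build_references(kept, pseudocount=config.pseudocount)
    reference.reference_table(refs, kept).to_csv(
        outdir / "references.tsv", sep="\t", index=False)
    manifest["stages"]["references"] = {
        "n_taxa_in": len(tables), "n_taxa_kept": len(kept)}

    # --- stage: gene traits -----------------------------------------------
    tt = traits.traits_table(genes, refs, min_codons=config.min_codons)
    tt.to_csv(outdir / "gene_traits.tsv", sep="\t", index=False)
    manifest["stages"]["traits"] = {
        "n_genes_in": len(genes), "n_genes_with_traits": len(tt)}

    # --- stage: differential expression -----------------------------------
    result = de.estimate_de(cm, config.control_level, config.treatment_level,
                            fdr_threshold=config.fdr_threshold)
    result.table.to_csv(outdir / "differential_expression.tsv", sep="\t")
    manifest["stages"]["de"] = {
        "n_features": len(result.table),
        "n_significant": int(result.table["significant"].sum())}

    # --- stage: summaries --------------------------------------------------
    tt_idx = tt.set_index("gene_id")
    sf = de.size_factors(cm.counts)
    norm = cm.counts / sf
    summaries = []
    for sample in norm.columns:
        w = norm[sample].reindex(tt_idx.index).fillna(0.0)
        st = tt_idx.copy()
        st["weight"] = (w if config.weighting == "rna"
                        else tt_idx["depth"]).values
        st["sample_id"] = sample
        st["treatment"] = cm.design.loc[sample, "treatment"]
        summaries.append(st)
    pooled = pd.concat(summaries).reset_index()
    sample_means = association.weighted_summary(
        pooled, ["sample_id", "treatment"], weight_col="weight")
    sample_means.to_csv(outdir / "sample_trait_means.tsv", sep="\t", index=False)
    manifest["stages"]["summaries"] = {"n_samples": len(sample_means)}

    # --- stage: associations -----------------------------------------------
    assoc_rows = []
    for pathway in config.pathways:
        rel = association.pathway_level_relation(
            tt_idx, result.table, pathway_tag=pathway,
            predictor=config.predictor)
        if len(rel.coefficients):
            srow = rel.coefficients[rel.coefficients["predictor"] == config.predictor]
            assoc_rows.append({
                "pathway": pathway, "predictor": config.predictor,
                "slope": float(srow["estimate"].iloc[0]),
                "se": float(srow["se"].iloc[0]),
                "p_value": float(srow["p_value"].iloc[0]),
                "r_squared": rel.r_squared, "n_genomes": rel.n_points})
        else:
            assoc_rows.append({"pathway": pathway, "predictor": config.predictor,
                               "slope": float("nan"), "se": float("nan"),
                               "p_value": float("nan"), "r_squared": float("nan"),
                               "n_genomes": rel.n_points})
    pd.DataFrame(assoc_rows).to_csv(
        outdir / "pathway_associations.tsv", sep="\t", index=False)
    manifest["stages"]["associations"] = {"n_pathways": len(assoc_rows)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
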