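"""End-to-end orchestration of the analysis chain.

The pipeline runs, per contrast: differential expression and signatures;
the four-step master-regulator analysis; KS gene-set enrichment on the
fold-change-ranked list; reaction mapping and pathway Fisher enrichment;
and the logical-model environment report.  Every stage writes plain-text
outputs into the run directory, and a manifest records the configuration,
software version and SHA-256 of every written file, so identical
config + seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as mio
from .containers import DEFAULT_CONTRASTS, ExpressionStudy, TargetDatabaseSet
from .diffexpr import MirnaDECriteria, build_signature, differential_expression
from .enrichment import enrich_collection, map_to_reactions, rank_by_fc, reaction_pathway_enrichment
from .logic import hepatic_environments, hepatic_model, load_model, simulate_environments
from .mmra import MMRAConfig, run_mmra
from .simulate import (
    SimulationConfig,
    generate_pathways_and_reactions,
    generate_study,
    generate_target_databases,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "mirmaster_run"
    #: paths to inputs; when None the synthetic study is generated
    genes_tsv: str | None = None
    mirnas_tsv: str | None = None
    annotation_tsv: str | None = None
    targets_tsv: str | None = None
    pathways_gmt: str | None = None
    reaction_mapping_tsv: str | None = None
    model_json: str | None = None
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    gene_alpha: float = 0.05
    mirna_fc_threshold: float = 0.25
    mirna_p_threshold: float = 0.01
    fisher_alpha: float = 0.05
    mi_p_target: float = 1e-3  # desk-scale default; genome scale: 1e-7
    n_perm: int = 2000
    gsea_raw_p: float = 0.05
    by_alpha: float = 0.05
    min_sources: int = 2
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def mmra_config(self) -> MMRAConfig:
        return MMRAConfig(
            mirna_criteria=MirnaDECriteria(self.mirna_fc_threshold, self.mirna_p_threshold),
            gene_alpha=self.gene_alpha,
            fisher_alpha=self.fisher_alpha,
            mi_p_target=self.mi_p_target,
            n_perm=self.n_perm,
            min_sources=self.min_sources,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str
    hashes: dict[str, str]
    log_path: str
    stage_counts: dict[str, list[int]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionStudy, TargetDatabaseSet, dict, object]:
    sim = config.simulation
    if config.genes_tsv is None:
        sim = dataclasses.replace(sim, seed=config.seed)
        study = generate_study(sim)
        dbset = generate_target_databases(study.truth, sim)
        pathways, mapping = generate_pathways_and_reactions(study, sim)
        return study, dbset, pathways.sets, mapping
    for name in ("mirnas_tsv", "annotation_tsv", "targets_tsv"):
        if getattr(config, name) is None:
            raise FileNotFoundError(f"pipeline input {name} is required when genes_tsv is given")
    study = ExpressionStudy(
        gene_matrix=mio.read_expression_tsv(config.genes_tsv),
        mirna_matrix=mio.read_expression_tsv(config.mirnas_tsv),
        annotation=mio.read_annotation_tsv(config.annotation_tsv),
    )
    study.validate()
    dbset = mio.read_targets_tsv(config.targets_tsv)
    pathway_sets = mio.read_gmt(config.pathways_gmt) if config.pathways_gmt else {}
    mapping = (
        mio.read_reaction_mapping_tsv(config.reaction_mapping_tsv)
        if config.reaction_mapping_tsv
        else None
    )
    return study, dbset, pathway_sets, mapping


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and return the manifest (also written to disk)."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mirmaster")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = []
    stage_counts: dict[str, list[int]] = {}
    try:
        study, dbset, pathway_sets, mapping = _load_inputs(config)
        if study.truth is not None:
            for p in mio.study_to_dir(study, outdir / "study").values():
                written.append(p)
            mio.write_targets_tsv(dbset, outdir / "study" / "targets.tsv")
            written.append(outdir / "study" / "targets.tsv")

        signatures = {}
        for contrast in config.contrasts:
            de = differential_expression(study.gene_matrix, study.annotation, contrast)
            path = outdir / f"de_genes_{contrast}.tsv"
            mio.write_de_table(de, path)
            written.append(path)
            sig = build_signature(de, config.gene_alpha)
            signatures[contrast] = sig
            sig_path = outdir / f"signature_{contrast}.gmt"
            mio.signature_to_gmt(sig, sig_path)
            written.append(sig_path)
            logger.info("%s: signature %d up / %d down", contrast, len(sig.up), len(sig.down))

            result = run_mmra(study, dbset, contrast, config.mmra_config())
            stage_counts[contrast] = result.step_counts
            table_path = outdir / f"mmra_{contrast}.tsv"
            result.to_table().to_csv(table_path, sep="\t", index=False)
            written.append(table_path)
            audit_path = outdir / f"mmra_audit_{contrast}.json"
            audit_path.write_text(
                json.dumps(
                    {"audit": result.audit, "step_counts": result.step_counts}, indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
            written.append(audit_path)

            if pathway_sets:
                ranked = rank_by_fc(de, config.gsea_raw_p)
                gsea = enrich_collection(ranked, pathway_sets, "BY", config.by_alpha)
                gsea_path = outdir / f"gsea_{contrast}.tsv"
                gsea.to_csv(gsea_path, sep="\t", index=False)
                written.append(gsea_path)

        if mapping is not None:
            attributes, unmapped = map_to_reactions(signatures, mapping)
            attr_path = outdir / "reaction_attributes.tsv"
            with open(attr_path, "w") as fh:
                fh.write("reaction_id\tattribute\n")
                for r in sorted(attributes):
                    fh.write(f"{r}\t{attributes[r]}\n")
            written.append(attr_path)
            for subset in (1, 2, 3):
                table = reaction_pathway_enrichment(attributes, mapping, subset)
                path = outdir / f"reaction_enrichment_attr{subset}.tsv"
                table.to_csv(path, sep="\t", index=False)
                written.append(path)
            if unmapped:
                logger.info("%d DE genes had no reaction mapping", len(unmapped))

        model = load_model(config.model_json) if config.model_json else hepatic_model()
        report = simulate_environments(model, hepatic_environments())
        report_path = outdir / "logic_environments.tsv"
        # blank cells for level 0 mirror the published stable-state coding
        report.replace(0, "").to_csv(report_path, sep="\t", index_label="environment")
        written.append(report_path)
    except Exception:
        root.removeHandler(handler)
        handler.close()
        raise
    root.removeHandler(handler)
    handler.close()

    manifest = RunManifest(
        config={
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "simulation"
            },
            "simulation": config.simulation.to_dict(),
        },
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        hashes={str(p.relative_to(outdir)): _sha256(p) for p in written},
        log_path=str(log_path),
        stage_counts=stage_counts,
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
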