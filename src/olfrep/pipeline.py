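"""End-to-end orchestration: simulate -> annotate -> clusters -> expression
-> comparative, from a single YAML-configurable run description.

Every stage writes into the configured output directory only; a manifest
records the configuration hash, per-file checksums and, when simulated
truth is available, annotation recovery statistics. With a fixed seed the
stage outputs are byte-identical across runs (the manifest's wall-clock
timestamps are the only exception).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as olfio
from .annotate import (
    AssemblyStats,
    GeneModel,
    family_counts,
    iterate_annotation,
    qc_assembly,
    subtype_proportions,
)
from .clusters import GeneCluster, call_clusters_genome, filter_for_display, psi_matrix
from .comparative import fan_classify, group_contrast, ob_cell_model
from .expression import (
    cluster_expression,
    drop_coreceptor,
    em_assign_table,
    expression_concentration,
    family_proportions,
    relative_abundance,
)
from .simulate import (
    SimConfig,
    SimTruth,
    TruthGene,
    make_references,
    plant_genome,
    simulate_comparative,
    simulate_expression,
)

ALL_STAGES = ("simulate", "annotate", "clusters", "expression", "comparative")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "olfrep_out"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    comparative: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise PipelineConfigError(f"unknown stage {stage!r}")
        if "simulate" not in self.stages:
            for stage, key in (
                ("annotate", "genome"),
                ("expression", "counts"),
                ("comparative", "traits"),
            ):
                if stage in self.stages:
                    path = self.__getattribute__(stage).get(key)
                    if not path or not Path(path).exists():
                        raise PipelineConfigError(
                            f"stage {stage!r} needs existing input {key!r}"
                        )
        for stage_cfg in (self.annotate, self.expression, self.comparative):
            for key, value in stage_cfg.items():
                if key.endswith(("_score", "iter", "flank")) and value is not None:
                    if float(value) <= 0:
                        raise PipelineConfigError(f"threshold {key} must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def evaluate_recovery(
    models: list[GeneModel], truth: SimTruth, min_overlap: float = 0.5
) -> dict:
    """Sensitivity/precision of intact models against planted truth.

    A truth gene is recovered by a model on the same scaffold and strand
    whose span covers at least ``min_overlap`` of the truth span with the
    correct family. Intact calls at pseudogene or decoy loci are counted
    separately.
    """

    def overlap(m: GeneModel, g: TruthGene) -> float:
        if m.scaffold != g.scaffold or m.strand != g.strand:
            return 0.0
        inter = min(m.end, g.end) - max(m.start, g.start)
        return max(inter, 0) / (g.end - g.start)

    intact_models = [m for m in models if m.intact]
    intact_truth = truth.intact_genes
    recovered = 0
    for g in intact_truth:
        if any(overlap(m, g) >= min_overlap and m.family == g.family
               for m in intact_models):
            recovered += 1
    true_positive = 0
    pseudo_hits = 0
    decoy_hits = 0
    for m in intact_models:
        matches = [g for g in truth.genes if overlap(m, g) >= min_overlap]
        if any(g.intact and not g.is_decoy and g.family == m.family
               for g in matches):
            true_positive += 1
        if any(not g.intact for g in matches):
            pseudo_hits += 1
        if any(g.is_decoy for g in matches):
            decoy_hits += 1
    n_truth = len(intact_truth)
    n_models = len(intact_models)
    return {
        "n_truth_intact": n_truth,
        "n_models_intact": n_models,
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
        "precision": true_positive / n_models if n_models else float("nan"),
        "intact_calls_at_pseudogene_loci": pseudo_hits,
        "intact_calls_at_decoy_loci": decoy_hits,
    }


def map_genes_to_clusters(
    genes: list[TruthGene], clusters: list[GeneCluster]
) -> list[GeneCluster]:
    """Assign gene ids to called cluster spans (midpoint containment).

    Genes falling outside every called cluster become singleton clusters,
    so downstream per-cluster expression conserves the total.
    """
    out: dict[str, list] = {c.id: [] for c in clusters}
    spans = {c.id: c for c in clusters}
    singletons: list[GeneCluster] = []
    for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
        mid = (g.start + g.end) // 2
        hit = None
        for c in clusters:
            if c.scaffold == g.scaffold and c.start <= mid < c.end:
                hit = c.id
                break
        if hit is None:
            singletons.append(
                GeneCluster(
                    id=f"sg{len(singletons) + 1}",
                    scaffold=g.scaffold,
                    members=(g.id,),
                    start=g.start,
                    end=g.end,
                )
            )
        else:
            out[hit].append(g.id)
    mapped = [
        GeneCluster(
            id=c.id,
            scaffold=c.scaffold,
            members=tuple(out[c.id]),
            start=c.start,
            end=c.end,
            family_counts=spans[c.id].family_counts,
        )
        for c in clusters
        if out[c.id]
    ]
    return mapped + singletons


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "olfrep 0.1.0",
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    truth: SimTruth | None = None
    genome = None
    refs = None
    models: list[GeneModel] | None = None
    clusters = None

    sim_cfg = SimConfig(seed=config.seed, **config.simulate)

    if "simulate" in config.stages:
        refs = make_references(sim_cfg.n_templates_per_family, sim_cfg.seed)
        genome, truth = plant_genome(sim_cfg, refs)
        counts, ambig = simulate_expression(truth, sim_cfg)
        tree, traits, comp_truth = simulate_comparative(sim_cfg)
        truth.tree_newick = comp_truth.tree_newick
        truth.comparative = comp_truth.comparative
        olfio.write_fasta(genome, outdir / "genome.fa")
        olfio.write_truth_gff(truth, outdir / "truth.gff3")
        olfio.write_references(refs, outdir / "refs")
        counts.rename_axis("gene").to_csv(outdir / "counts.tsv", sep="\t")
        ambig.to_csv(outdir / "ambig.tsv", sep="\t", index=False)
        truth.proportions.rename_axis("gene").to_csv(
            outdir / "true_proportions.tsv", sep="\t"
        )
        (outdir / "tree.nwk").write_text(truth.tree_newick + "\n")
        traits.to_csv(outdir / "traits.tsv", sep="\t")
        manifest["stages"]["simulate"] = {
            "n_genes": len(truth.genes),
            "n_intact": len(truth.intact_genes),
            "n_clusters": len(truth.clusters),
        }

    if "annotate" in config.stages:
        acfg = config.annotate
        if genome is None:
            genome = olfio.read_fasta(acfg["genome"])
        if refs is None:
            refs = olfio.read_references(acfg.get("refs", outdir / "refs"))
        hits = None
        if acfg.get("hits"):
            hits = olfio.read_hits(
                acfg["hits"], {r.id: r.family for r in refs}
            )
        models, info = iterate_annotation(
            genome,
            refs,
            min_score=acfg.get("min_score", 120.0),
            classify_min_score=acfg.get("classify_min_score", 150.0),
            flank=acfg.get("flank", 3000),
            max_iter=acfg.get("max_iter", 5),
            hsps=hits,
        )
        olfio.write_models_gff(models, outdir / "models.gff3")
        olfio.write_fasta({m.id: m.protein for m in models}, outdir / "proteins.fa")
        stats = AssemblyStats(
            scaffold_lengths=tuple(len(s) for s in genome.values()),
            busco_completeness=acfg.get("busco", 0.95),
            polypteriform=acfg.get("polypteriform", False),
            lineage_wgd=acfg.get("lineage_wgd", False),
        )
        report = qc_assembly(stats, models)
        qc = {
            "n50": stats.n50,
            "genome_length": stats.genome_length,
            "n50_ratio_pass": report.n50_ratio_pass,
            "busco_pass": report.busco_pass,
            "or_scaffold_dispersion_pass": report.or_scaffold_dispersion_pass,
            "overall_pass": report.overall_pass,
        }
        (outdir / "qc.json").write_text(json.dumps(qc, indent=1) + "\n")
        stage = {
            "iterations": info["iterations"],
            "added_per_iteration": info["added_per_iteration"],
            "family_counts": family_counts(models),
            "or_subtype_proportions": subtype_proportions(models, "OR"),
        }
        if truth is not None:
            stage["recovery"] = evaluate_recovery(models, truth)
        manifest["stages"]["annotate"] = stage

    if "clusters" in config.stages:
        if models is None:
            models = olfio.read_models_gff(
                config.clusters["models"],
                olfio.read_fasta(config.clusters["proteins"]),
            )
        intact = [m for m in models if m.intact]
        clusters = call_clusters_genome(intact)
        olfio.write_clusters(clusters, outdir / "clusters.bed",
                             outdir / "clusters.json")
        display = filter_for_display(
            clusters, config.clusters.get("min_display", 5)
        )
        largest = max(clusters, key=lambda c: c.size, default=None)
        if largest is not None and largest.size >= 2:
            proteins = {m.id: m.protein for m in intact}
            ordered = [(g, proteins[g]) for g in largest.members if proteins.get(g)]
            if ordered:
                psi = psi_matrix(ordered)
                psi.to_csv(outdir / "psi_largest_cluster.tsv", sep="\t")
        manifest["stages"]["clusters"] = {
            "n_clusters": len(clusters),
            "n_display_clusters": len(display),
            "largest_cluster_size": largest.size if largest else 0,
        }

    if "expression" in config.stages:
        ecfg = config.expression
        counts_path = ecfg.get("counts", outdir / "counts.tsv")
        ambig_path = ecfg.get("ambig", outdir / "ambig.tsv")
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        ambig = None
        if ambig_path and Path(ambig_path).exists():
            ambig = pd.read_csv(ambig_path, sep="\t")
        expected = em_assign_table(counts, ambig)
        expected = drop_coreceptor(expected, ecfg.get("coreceptors", []))
        abundance = relative_abundance(expected)
        abundance.rename_axis("gene").to_csv(outdir / "abundance.tsv", sep="\t")
        mean = abundance["mean"]
        concentration = expression_concentration(mean)
        summary = {"expression_concentration": concentration}
        if truth is not None:
            fam = pd.Series(
                {g.id: g.family for g in truth.intact_genes}
            ).loc[mean.index]
            fp = family_proportions(mean, fam)
            fp.to_csv(outdir / "family_proportions.tsv", sep="\t")
            if clusters is not None:
                mapped = map_genes_to_clusters(
                    [g for g in truth.intact_genes if g.id in mean.index], clusters
                )
                clexp = cluster_expression(mean, mapped)
                clexp.to_csv(outdir / "cluster_expression.tsv", sep="\t")
                summary["acex_total"] = float(clexp["AcEx"].sum())
        (outdir / "expression_summary.json").write_text(
            json.dumps(summary, indent=1) + "\n"
        )
        manifest["stages"]["expression"] = summary

    if "comparative" in config.stages:
        ccfg = config.comparative
        tree_path = ccfg.get("tree", outdir / "tree.nwk")
        traits_path = ccfg.get("traits", outdir / "traits.tsv")
        tree_newick = Path(tree_path).read_text()
        traits = pd.read_csv(traits_path, sep="\t", index_col=0)
        fit, residual_table, dropped = ob_cell_model(traits, tree_newick)
        fan, excluded = fan_classify(traits)
        results = {
            "ob_cell_model": {
                k: fit.summary_frame().loc[k].to_dict()
                for k in fit.summary_frame().index
            },
            "dropped_species": dropped,
            "fan_species": fan,
            "fan_excluded_unknown_activity": excluded,
        }
        indicator = pd.Series(
            {sp: float(sp in fan) for sp in traits.index}
        )
        if indicator.nunique() > 1:
            contrast = group_contrast(
                traits["olf_total"].astype(float), indicator, tree_newick
            )
            results["fan_contrast_total"] = {
                k: contrast.summary_frame().loc[k].to_dict()
                for k in contrast.summary_frame().index
            }
        residual_table.to_csv(outdir / "ob_residuals.tsv", sep="\t")
        (outdir / "comparative_fits.json").write_text(
            json.dumps(results, indent=1, sort_keys=True) + "\n"
        )
        manifest["stages"]["comparative"] = {
            "n_species": len(traits),
            "n_fan": len(fan),
            "ob_olf_p": results["ob_cell_model"]["log10_olf"]["p"],
        }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
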