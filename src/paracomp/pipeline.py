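"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` either points at on-disk inputs (counts,
sample metadata, gene annotation, optional ontology/associations/
reference list) or carries a ``simulate`` block of
:class:`~paracomp.simdata.SimParams`.  ``run_pipeline`` executes
normalize -> contrast grid -> rescue table + dose slope + compensation
index -> enrichment on rescue classes -> co-expression clustering +
haplotype diagnostics, writing every table plus a manifest that
suffices to re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from paracomp import __version__, coexpression, enrichment, io as pio
from paracomp.compensation import (
    build_rescue_table,
    compensation_index,
    dose_slope,
)
from paracomp.denorm import fit_normalization, log_normalized
from paracomp.simdata import SimParams, simulate_experiment

log = logging.getLogger("paracomp")


@dataclass
class PipelineConfig:
    output_dir: str = "paracomp_out"
    seed: int = 0
    q_threshold: float = 0.05
    r_min: float = 0.7
    inflation: float = 2.2
    min_cluster: int = 3
    corr_min_mean: float = 1.0
    corr_min_var: float = 0.05
    stage: Optional[str] = None
    # either a simulate block ...
    simulate: Optional[SimParams] = None
    # ... or paths to real inputs
    counts: Optional[str] = None
    samples: Optional[str] = None
    genes: Optional[str] = None
    ontology: Optional[str] = None
    associations: Optional[str] = None
    reference_set: Optional[str] = None

    def __post_init__(self) -> None:
        has_inputs = self.counts and self.samples and self.genes
        if self.simulate is None and not has_inputs:
            raise ValueError("config needs either a simulate block or input paths")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            raw["simulate"] = SimParams(**sim)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "q_threshold": config.q_threshold,
            "r_min": config.r_min,
            "inflation": config.inflation,
            "min_cluster": config.min_cluster,
        },
        "stages": [],
        "outputs": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.simulate is not None:
            stage("simulate")
            params = config.simulate.replace(seed=config.seed)
            dataset, truth = simulate_experiment(params)
            truth_path = os.path.join(out, "truth.tsv")
            truth.table.to_csv(truth_path, sep="\t", index=False)
            manifest["outputs"]["truth"] = truth_path
            manifest["inputs"] = {"simulate": dataclasses.asdict(params)}
            # class_proportions keys are fine; make yaml-safe floats
        else:
            stage("load")
            dataset = pio.read_dataset(config.counts, config.samples, config.genes)
            manifest["inputs"] = {
                "counts": config.counts,
                "samples": config.samples,
                "genes": config.genes,
            }
        manifest["outputs"].update(pio.write_dataset(dataset, out))

        stage("normalize")
        norm = fit_normalization(dataset, stage=config.stage)
        norm_path = os.path.join(out, "size_factors.tsv")
        norm.size_factors.to_csv(norm_path, sep="\t")
        manifest["outputs"]["size_factors"] = norm_path

        stage("rescue")
        rescue = build_rescue_table(
            dataset, stage=config.stage, q_threshold=config.q_threshold, norm=norm
        )
        rescue_path = os.path.join(out, "rescue_table.tsv")
        rescue.table.to_csv(rescue_path, sep="\t")
        manifest["outputs"]["rescue_table"] = rescue_path
        for name, res in rescue.results.items():
            p = os.path.join(out, f"de_{name}.tsv")
            pio.write_de_table(res, p)
            manifest["outputs"][f"de_{name}"] = p

        stage("dose_slope")
        try:
            slope = dose_slope(rescue, seed=config.seed)
            slope_path = os.path.join(out, "dose_slope.json")
            with open(slope_path, "w") as fh:
                json.dump(dataclasses.asdict(slope), fh, indent=1)
            manifest["outputs"]["dose_slope"] = slope_path
        except ValueError as exc:
            log.warning("dose_slope skipped: %s", exc)

        stage("compensation_index")
        if "locus_c" in dataset.counts.index:
            fold, p = compensation_index(dataset, "locus_c", stage=config.stage, norm=norm)
            comp_path = os.path.join(out, "compensation_index.json")
            with open(comp_path, "w") as fh:
                json.dump({"gene": "locus_c", "fold_change": fold, "pvalue": p}, fh)
            manifest["outputs"]["compensation_index"] = comp_path

        if config.ontology and config.associations:
            stage("enrichment")
            dag = enrichment.load_obo(config.ontology)
            direct = enrichment.read_associations(config.associations)
            annot = enrichment.propagate_annotations(dag, direct)
            population = list(dataset.counts.index)
            for label in sorted(set(rescue.table["rescue_class"])):
                study = [
                    g for g in rescue.genes_in_class(label) if g in direct or g in annot
                ]
                study = [g for g in study if g in set(population)]
                if not study:
                    continue
                res = enrichment.parent_child_union_test(
                    dag, annot, study, [g for g in population if g in annot]
                )
                p = os.path.join(out, f"enrichment_{label}.tsv")
                res.to_csv(p, sep="\t")
                manifest["outputs"][f"enrichment_{label}"] = p

        stage("coexpression")
        expr = log_normalized(dataset, norm)
        graph = coexpression.correlation_graph(
            expr, r_min=config.r_min, min_mean=config.corr_min_mean,
            min_var=config.corr_min_var,
        )
        edge_path = os.path.join(out, "correlation_edges.tsv")
        with open(edge_path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for u, v, d in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.6f}\n")
        manifest["outputs"]["correlation_edges"] = edge_path
        if graph.number_of_nodes():
            clusters = coexpression.mcl(
                graph, inflation=config.inflation, min_cluster=config.min_cluster
            )
            cl_path = os.path.join(out, "clusters.tsv")
            clusters.labels().to_csv(cl_path, sep="\t", index_label="gene_id")
            manifest["outputs"]["clusters"] = cl_path

            stage("diagnostics")
            l1_sig = sorted(rescue.results["L1_dko_vs_wt"].significant(config.q_threshold))
            chrom = coexpression.chromosome_enrichment(
                l1_sig, dataset.genes, list(dataset.counts.index)
            )
            chrom_path = os.path.join(out, "chromosome_enrichment.tsv")
            chrom.to_csv(chrom_path, sep="\t")
            manifest["outputs"]["chromosome_enrichment"] = chrom_path
            coloc_rows = []
            for label, genes in clusters.clusters.items():
                try:
                    modal, within = coexpression.colocation_score(genes, dataset.genes)
                except ValueError:
                    continue
                coloc_rows.append(
                    {"cluster": label, "modal_chrom_fraction": modal,
                     "within_window_fraction": within}
                )
            coloc_path = os.path.join(out, "colocation.tsv")
            pd.DataFrame(coloc_rows).to_csv(coloc_path, sep="\t", index=False)
            manifest["outputs"]["colocation"] = coloc_path
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str, sort_keys=True)
    manifest["outputs"]["manifest"] = manifest_path
    return manifest
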