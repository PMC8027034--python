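"""End-to-end orchestration: chains DE, module assignment, orthology,
ancestral reconstruction, overlap and enrichment, in memory or on files.

Every stage writes plain TSV outputs plus a JSON run manifest (config,
seed, library versions), and the whole run is deterministic for a fixed
seed: the same inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diffexpr import run_de, standardize_expression
from .enrichment import overlap_all_pairs, term_enrichment
from .evolution import branch_counts, branch_report
from .io import (CountTable, SampleDesign, SpeciesTree, read_annotations,
                 read_count_table, read_newick, read_similarity, write_tsv)
from .modules import assign_modules, module_summary
from .orthology import (OrthologySet, build_orthology, build_similarity_graph,
                        mcl_cluster)

log = logging.getLogger("modevol")


@dataclass
class PipelineResult:
    de: dict[str, pd.DataFrame]
    assignments: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    orthology: OrthologySet
    report: pd.DataFrame
    counts: pd.DataFrame
    overlap: pd.DataFrame
    enrichment: pd.DataFrame
    std_expr: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name: str):
    """Log a stage timer and rewrap failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - self.t0)
    return _Ctx()


def analyze(counts: dict[str, CountTable], tree: SpeciesTree,
            similarity: pd.DataFrame, annotations: pd.DataFrame | None,
            config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    strains = tree.leaf_names
    missing = [s for s in strains if s not in counts]
    if missing:
        raise ValueError(f"no count table for tree leaf/leaves {missing}")

    de, assignments, std = {}, {}, {}
    with _stage("differential_expression"):
        for s in strains:
            de[s] = run_de(counts[s], config.cpm_filter_min,
                           config.cpm_filter_min_samples)
            std[s] = standardize_expression(counts[s], config.prior_count)
    with _stage("module_assignment"):
        for s in strains:
            assignments[s] = assign_modules(de[s], config.fdr_alpha,
                                            config.lfc_min)
        summary = module_summary(assignments)

    with _stage("orthology"):
        gene_strain = {g: s for s in strains for g in counts[s].genes}
        graph = build_similarity_graph(similarity,
                                       config.similarity_evalue_max,
                                       config.percent_match_min)
        unknown = [g for g in graph.nodes if g not in gene_strain]
        if unknown:
            raise ValueError(f"similarity genes absent from counts: "
                             f"{unknown[:5]}")
        clusters = mcl_cluster(graph, inflation=config.mcl_inflation)
        orthology = build_orthology(clusters, gene_strain, strains, graph)

    assign_series = {s: assignments[s].set_index("gene_id")["module"]
                     for s in strains}
    with _stage("module_evolution"):
        report = branch_report(tree, assign_series, orthology)
        counts_table = branch_counts(report)

    with _stage("overlap"):
        overlap = overlap_all_pairs(assign_series, orthology)

    with _stage("enrichment"):
        enrichment = _gain_enrichment(tree, report, orthology, counts,
                                      annotations, config)

    return PipelineResult(de=de, assignments=assignments, summary=summary,
                          orthology=orthology, report=report,
                          counts=counts_table, overlap=overlap,
                          enrichment=enrichment, std_expr=std)


def _gain_enrichment(tree: SpeciesTree, report: pd.DataFrame,
                     orthology: OrthologySet, counts: dict[str, CountTable],
                     annotations: pd.DataFrame | None,
                     config: PipelineConfig) -> pd.DataFrame:
    """Term enrichment of the gained gene sets of every non-root branch."""
    if annotations is None or annotations.empty:
        return pd.DataFrame(columns=["branch", "module", "term", "k", "K",
                                     "n", "N", "p", "fold_enrichment",
                                     "fdr", "enriched"])
    universe = {g for s in counts for g in counts[s].genes}
    frames = []
    for branch in tree.internal_names:
        if branch == tree.root_name:
            continue
        under = tree.leaves_under(branch)
        at = report[(report["branch"] == branch)
                    & (report["status"] == "gained")]
        for module, grp in at.groupby("module"):
            genes: set[str] = set()
            for tid in grp["tuple_id"]:
                for leaf in under:
                    g = orthology.tuples.loc[tid, leaf]
                    if isinstance(g, str):
                        genes.add(g)
            if not genes:
                continue
            res = term_enrichment(genes & universe, universe, annotations,
                                  alpha=config.enrichment_alpha)
            res.insert(0, "module", module)
            res.insert(0, "branch", branch)
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["branch", "module", "term", "k", "K",
                                     "n", "N", "p", "fold_enrichment",
                                     "fdr", "enriched"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, tree_path: str | Path,
                 design_path: str | Path, count_paths: dict[str, str | Path],
                 similarity_path: str | Path,
                 annotation_path: str | Path | None,
                 outdir: str | Path) -> PipelineResult:
    """Load inputs from disk, run :func:`analyze`, write every report TSV
    plus a JSON run manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("load_inputs"):
        tree = read_newick(tree_path)
        counts = {s: read_count_table(p, design_path, strain=s)
                  for s, p in sorted(count_paths.items())}
        similarity = read_similarity(similarity_path)
        annotations = (read_annotations(annotation_path)
                       if annotation_path else None)

    result = analyze(counts, tree, similarity, annotations, config)
    write_results(result, outdir)

    manifest = {
        "package": "modevol", "version": __version__,
        "config": config.to_dict(),
        "fdr_thresholds_reported": {"methods_default": 0.05, "strict": 0.01},
        "orthology_note": ("within-cluster orthology by best-score "
                           "representative; no gene-tree reconciliation"),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "python": sys.version.split()[0]},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s, table in result.de.items():
        write_tsv(table, outdir / f"de_{s}.tsv")
    for s, table in result.assignments.items():
        table = table.copy()
        table.insert(1, "strain", s)
        write_tsv(table, outdir / f"modules_{s}.tsv")
    for s, table in result.std_expr.items():
        write_tsv(table.rename_axis("gene_id").reset_index(),
                  outdir / f"std_expr_{s}.tsv")
    write_tsv(result.summary, outdir / "module_summary.tsv")
    write_tsv(result.orthology.to_cluster_frame(), outdir / "clusters.tsv")
    write_tsv(result.orthology.tuples.reset_index(), outdir / "tuples.tsv")
    write_tsv(result.report, outdir / "branch_report.tsv")
    write_tsv(result.counts, outdir / "branch_counts.tsv")
    write_tsv(result.overlap, outdir / "overlap.tsv")
    write_tsv(result.enrichment, outdir / "enrichment.tsv")


def write_simulated_inputs(dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the exact formats the pipeline reads."""
    from .io import write_count_table, write_similarity

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(
        dataset.tree.tree.as_string(schema="newick").strip() + "\n")
    paths["tree"] = tree_path
    design_path = outdir / "design.tsv"
    write_tsv(dataset.design.table, design_path)
    paths["design"] = design_path
    for s, table in dataset.counts.items():
        p = outdir / f"counts_{s}.tsv"
        write_count_table(table, p)
        paths[f"counts_{s}"] = p
    sim_path = outdir / "similarity.tsv"
    write_similarity(dataset.similarity, sim_path)
    paths["similarity"] = sim_path
    ann_path = outdir / "annotations.tsv"
    write_tsv(dataset.annotations, ann_path)
    paths["annotations"] = ann_path
    truth_path = outdir / "truth_events.tsv"
    write_tsv(dataset.truth.events_frame(), truth_path)
    paths["truth"] = truth_path
    return paths
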